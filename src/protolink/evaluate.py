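"""Inference and evaluation: link mentions by re-ranking candidates with
Euclidean distance; Acc@1, seen/unseen accuracy, and McNemar comparisons.

A mention is linked to the candidate entity whose embedding is nearest to
the mention embedding (smallest dissimilarity).  Entity embeddings are
computed once per distinct entity and cached — the dual encoder's inference
advantage.  Mentions with an empty candidate list are *unlinkable* and are
conservatively scored incorrect.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .encoding import SequenceEncoder, entity_embedding, format_mention_input, mention_embedding
from .kb import EntityRecord, MentionAnnotation
from .retrieval import CandidateList


@dataclass
class LinkingResult:
    """Candidates of one mention ranked by ascending distance."""

    mention_uid: str
    gold_entity_id: str
    ranked: list[tuple[str, float]]  # (entity_id, distance), non-decreasing
    predicted: str | None

    @property
    def correct(self) -> bool:
        return self.predicted is not None and self.predicted == self.gold_entity_id

    @property
    def unlinkable(self) -> bool:
        return self.predicted is None

    @property
    def rank_of_gold(self) -> int:
        """1-based rank of the gold entity among candidates; -1 if absent."""
        for rank, (eid, _) in enumerate(self.ranked, start=1):
            if eid == self.gold_entity_id:
                return rank
        return -1


class EntityEmbeddingCache:
    """Encodes each entity at most once; counts encodings performed."""

    def __init__(self, entities: dict[str, EntityRecord], encoder: SequenceEncoder,
                 max_len: int = 128):
        self.entities = entities
        self.encoder = encoder
        self.max_len = max_len
        self._cache: dict[str, np.ndarray] = {}
        self.encode_count = 0

    def get(self, entity_id: str) -> np.ndarray:
        emb = self._cache.get(entity_id)
        if emb is None:
            emb = entity_embedding(self.entities[entity_id], self.encoder, max_len=self.max_len)
            self._cache[entity_id] = emb
            self.encode_count += 1
        return emb


def link_mention(
    mention: MentionAnnotation,
    candidates: CandidateList,
    mention_encoder: SequenceEncoder,
    entity_cache: EntityEmbeddingCache,
    max_len: int = 128,
) -> LinkingResult:
    """Rank candidates by Euclidean distance to the mention embedding.

    Ties break toward the lexicographically smaller entity_id, so the ranking
    is a total order independent of candidate input order.
    """
    if not candidates.candidates:
        return LinkingResult(mention.uid, mention.gold_entity_id, [], None)
    minput = format_mention_input(mention, mention_encoder, max_len=max_len)
    m_emb = mention_embedding(minput, mention_encoder)
    scored = [
        (eid, float(np.linalg.norm(m_emb - entity_cache.get(eid))))
        for eid in candidates.entity_ids
    ]
    scored.sort(key=lambda t: (t[1], t[0]))
    return LinkingResult(mention.uid, mention.gold_entity_id, scored, scored[0][0])


def link_corpus(
    mentions: Sequence[MentionAnnotation],
    candidates: dict[str, CandidateList],
    mention_encoder: SequenceEncoder,
    entities: dict[str, EntityRecord],
    entity_encoder: SequenceEncoder,
    max_len: int = 128,
) -> list[LinkingResult]:
    """Link every mention; entity embeddings are shared across mentions."""
    cache = EntityEmbeddingCache(entities, entity_encoder, max_len=max_len)
    results = []
    for m in mentions:
        cl = candidates.get(m.uid, CandidateList(m.uid, [], k=1))
        results.append(link_mention(m, cl, mention_encoder, cache, max_len=max_len))
    return results


def acc_at_1(results: Sequence[LinkingResult]) -> float:
    """Fraction of mentions whose top-1 prediction is the gold entity.

    Unlinkable mentions (and retrieval misses ranked away from the top) count
    as incorrect.
    """
    if not results:
        raise ValueError("acc_at_1 of an empty result set is undefined")
    return sum(r.correct for r in results) / len(results)


def seen_unseen_split(
    results: Sequence[LinkingResult], train_entity_ids: set[str]
) -> tuple[float | None, float | None]:
    """Acc@1 over mentions whose gold entity was / was not seen in training.

    An empty partition yields None for that side.
    """
    seen = [r for r in results if r.gold_entity_id in train_entity_ids]
    unseen = [r for r in results if r.gold_entity_id not in train_entity_ids]
    acc_seen = acc_at_1(seen) if seen else None
    acc_unseen = acc_at_1(unseen) if unseen else None
    return acc_seen, acc_unseen


def mcnemar_compare(
    results_a: Sequence[LinkingResult], results_b: Sequence[LinkingResult]
) -> tuple[float, float]:
    """McNemar's test on two systems' per-mention correctness.

    Chi-square form with continuity correction: statistic
    (|b − c| − 1)² / (b + c) over the discordant counts.  Identical result
    vectors (no discordant pairs) return statistic 0 and p = 1 by convention.
    """
    uids_a = [r.mention_uid for r in results_a]
    uids_b = [r.mention_uid for r in results_b]
    if uids_a != uids_b:
        raise ValueError("results must cover the same mentions in the same order")
    a_flags = np.array([r.correct for r in results_a])
    b_flags = np.array([r.correct for r in results_b])
    n11 = int(np.sum(a_flags & b_flags))
    n10 = int(np.sum(a_flags & ~b_flags))
    n01 = int(np.sum(~a_flags & b_flags))
    n00 = int(np.sum(~a_flags & ~b_flags))
    if n10 + n01 == 0:
        return 0.0, 1.0
    res = _sm_mcnemar([[n11, n10], [n01, n00]], exact=False, correction=True)
    return float(res.statistic), float(res.pvalue)


def write_predictions_tsv(results: Sequence[LinkingResult], path: str | Path) -> None:
    """Predictions file: mention_uid, gold, predicted, distance, rank_of_gold."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mention_uid\tgold\tpredicted\tdistance\trank_of_gold\n")
        for r in results:
            dist = f"{r.ranked[0][1]:.6f}" if r.ranked else "nan"
            fh.write(
                f"{r.mention_uid}\t{r.gold_entity_id}\t{r.predicted or '-'}\t"
                f"{dist}\t{r.rank_of_gold}\n"
            )
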