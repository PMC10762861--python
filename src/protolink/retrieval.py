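"""Candidate retrieval: top-k entity candidates per mention.

All synonyms in the KB are scored against a mention by cosine similarity —
either sparse tf-idf (character 2–5-grams, or word unigrams with stop words
removed) or a dense encoder — sorted in descending order, and their entities
appended to the candidate list until k distinct entities are collected.
Candidate lists from different representations are merged round-robin with
duplicates removed.

The tf-idf variant is the smoothed one: idf = ln((1+N)/(1+df)) + 1, raw term
counts, L2 normalization (so cosine similarity is a plain dot product).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer

from .kb import SynonymIndex
from .stopwords import ENGLISH_STOP_WORDS

_WORD_RE = re.compile(r"[0-9a-zA-Z]+")

FORMAT_VERSION = 1


def _word_tokenize(text: str) -> list[str]:
    """Split on any non-alphanumeric character and drop stop words."""
    return [t for t in _WORD_RE.findall(text.lower()) if t not in ENGLISH_STOP_WORDS]


@dataclass
class CandidateList:
    """Ordered distinct entity candidates with scores for one mention."""

    mention_uid: str
    candidates: list[tuple[str, float]]
    k: int
    source: str = "char"

    def __post_init__(self) -> None:
        ids = [e for e, _ in self.candidates]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate entity_ids in candidate list")
        if len(self.candidates) > self.k:
            raise ValueError("candidate list longer than k")

    @property
    def entity_ids(self) -> list[str]:
        return [e for e, _ in self.candidates]


class SparseVectorizer:
    """Tf-idf vectorizer in one of two modes.

    ``char_ngram``: character n-grams with n in {2..5} (the full string,
    spaces included, contributes n-grams).  ``word_unigram``: word-level
    unigrams, tokens split on non-alphanumeric characters, stop words removed.
    """

    def __init__(self, mode: str = "char_ngram"):
        if mode not in ("char_ngram", "word_unigram"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        if mode == "char_ngram":
            self._tfidf = TfidfVectorizer(analyzer="char", ngram_range=(2, 5), lowercase=True)
        else:
            self._tfidf = TfidfVectorizer(analyzer=_word_tokenize, lowercase=False)
        self.fitted = False

    def fit(self, synonyms: Sequence[str]) -> "SparseVectorizer":
        if not synonyms:
            raise ValueError("cannot fit a tf-idf vectorizer on an empty synonym list")
        self._tfidf.fit(synonyms)
        self.fitted = True
        return self

    def transform(self, texts: Sequence[str]) -> sp.csr_matrix:
        """L2-normalized tf-idf rows; out-of-vocabulary text maps to a zero row."""
        if not self.fitted:
            raise RuntimeError("vectorizer not fitted")
        return self._tfidf.transform(texts)

    @property
    def vocabulary(self) -> dict[str, int]:
        return dict(self._tfidf.vocabulary_)

    @property
    def idf(self) -> np.ndarray:
        return np.asarray(self._tfidf.idf_)

    def save(self, path: str | Path) -> None:
        obj = {
            "format_version": FORMAT_VERSION,
            "mode": self.mode,
            "vocabulary": {t: int(i) for t, i in self._tfidf.vocabulary_.items()},
            "idf": [float(x) for x in self._tfidf.idf_],
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def load(cls, path: str | Path) -> "SparseVectorizer":
        obj = json.loads(Path(path).read_text())
        if obj.get("format_version") != FORMAT_VERSION:
            raise ValueError("unsupported vectorizer file version")
        vec = cls(obj["mode"])
        vocab = {t: int(i) for t, i in obj["vocabulary"].items()}
        if vec.mode == "char_ngram":
            vec._tfidf = TfidfVectorizer(
                analyzer="char", ngram_range=(2, 5), lowercase=True, vocabulary=vocab
            )
        else:
            vec._tfidf = TfidfVectorizer(analyzer=_word_tokenize, lowercase=False, vocabulary=vocab)
        # Rebuild the fitted state from the persisted vocabulary and idf.
        vec._tfidf.fit([" "])
        vec._tfidf.idf_ = np.asarray(obj["idf"], dtype=float)
        vec.fitted = True
        return vec


def fit_sparse(synonyms: Sequence[str], mode: str = "char_ngram") -> SparseVectorizer:
    """Fit a tf-idf vectorizer on the KB synonym strings."""
    return SparseVectorizer(mode).fit(synonyms)


def score_synonyms(
    mention: str, vectorizer: SparseVectorizer, synonym_matrix: sp.csr_matrix
) -> np.ndarray:
    """Cosine similarity of a mention against every synonym row (in [0, 1])."""
    vec = vectorizer.transform([mention])
    return np.asarray((synonym_matrix @ vec.T).todense()).ravel()


def _iterate_candidates(
    index: SynonymIndex, synonym_order: Sequence[int], scores: np.ndarray, k: int
) -> list[tuple[str, float]]:
    """Visit synonyms in score order, appending their entities until k collected.

    Entities of one synonym are appended in lexicographic entity_id order;
    entities already collected are skipped.
    """
    synonyms = index.synonyms
    out: list[tuple[str, float]] = []
    seen: set[str] = set()
    for idx in synonym_order:
        for eid in sorted(index.entities_for(synonyms[idx])):
            if eid not in seen:
                seen.add(eid)
                out.append((eid, float(scores[idx])))
                if len(out) == k:
                    return out
    return out


def retrieve_candidates(
    mention_uid: str,
    index: SynonymIndex,
    scores: np.ndarray,
    k: int,
    source: str = "char",
) -> CandidateList:
    """Build a top-k candidate list from per-synonym scores.

    ``scores`` is aligned with ``index.synonyms``.  Synonyms are visited in
    non-increasing score order (ties broken by synonym string, ascending);
    each synonym's entities are appended until k distinct entities are
    collected or synonyms are exhausted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    synonyms = index.synonyms
    if len(scores) != len(synonyms):
        raise ValueError("scores not aligned with index synonyms")
    if not synonyms:
        return CandidateList(mention_uid, [], k, source)
    order = sorted(range(len(synonyms)), key=lambda i: (-scores[i], synonyms[i]))
    return CandidateList(mention_uid, _iterate_candidates(index, order, scores, k), k, source)


class DenseSynonymIndex:
    """Exact nearest-neighbor index over dense synonym embeddings.

    Every KB synonym is pre-encoded once (inputs truncated to ``max_tokens``
    encoder tokens); queries are scored by cosine similarity with an
    exhaustive scan, so the k nearest are exact.
    """

    def __init__(self, index: SynonymIndex, encoder, max_tokens: int = 50):
        self.index = index
        self.encoder = encoder
        self.max_tokens = max_tokens
        self._matrix = self._encode_rows(index.synonyms)

    def _encode_rows(self, texts: Sequence[str]) -> np.ndarray:
        rows = np.stack([self.encoder.embed_text(t, max_tokens=self.max_tokens) for t in texts])
        norms = np.linalg.norm(rows, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return rows / norms

    def score(self, mention: str) -> np.ndarray:
        q = self.encoder.embed_text(mention, max_tokens=self.max_tokens)
        n = np.linalg.norm(q)
        if n == 0:
            raise ValueError(f"mention {mention!r} encoded to a zero vector")
        return self._matrix @ (q / n)

    def save(self, path: str | Path) -> None:
        np.savez(path, matrix=self._matrix, synonyms=np.array(self.index.synonyms, dtype=object))


def dense_retrieve(
    mention_uid: str,
    mention: str,
    dense_index: DenseSynonymIndex,
    k: int,
) -> CandidateList:
    """Top-k candidates by dense cosine similarity (exact exhaustive search)."""
    scores = dense_index.score(mention)
    return retrieve_candidates(mention_uid, dense_index.index, scores, k, source="dense")


def merge_candidate_lists(lists: Sequence[CandidateList], k: int) -> CandidateList:
    """Round-robin interleave candidate lists, drop duplicates, truncate to k.

    Interleaving starts from the first list (character n-gram tf-idf by
    convention); the first occurrence of an entity keeps its score.
    """
    if not lists:
        raise ValueError("need at least one candidate list")
    merged: list[tuple[str, float]] = []
    seen: set[str] = set()
    longest = max(len(cl.candidates) for cl in lists)
    for rank in range(longest):
        for cl in lists:
            if rank < len(cl.candidates):
                eid, score = cl.candidates[rank]
                if eid not in seen:
                    seen.add(eid)
                    merged.append((eid, score))
        if len(merged) >= k:
            break
    return CandidateList(lists[0].mention_uid, merged[:k], k, source="merged")


def recall_at_k(
    candidate_lists: Sequence[CandidateList], gold_ids: Sequence[str], k: int
) -> float:
    """Fraction of mentions whose gold entity is among the first k candidates."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(candidate_lists) != len(gold_ids):
        raise ValueError("candidate lists and gold ids differ in length")
    hits = sum(
        1 for cl, gold in zip(candidate_lists, gold_ids) if gold in cl.entity_ids[:k]
    )
    return hits / len(gold_ids)


def write_candidates_tsv(lists: Sequence[CandidateList], path: str | Path) -> None:
    """Candidate file: mention_uid, rank, entity_id, score, source."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mention_uid\trank\tentity_id\tscore\tsource\n")
        for cl in lists:
            for rank, (eid, score) in enumerate(cl.candidates, start=1):
                fh.write(f"{cl.mention_uid}\t{rank}\t{eid}\t{score:.6f}\t{cl.source}\n")


def read_candidates_tsv(path: str | Path) -> dict[str, CandidateList]:
    """Read a candidate TSV back into per-mention CandidateLists."""
    by_uid: dict[str, list[tuple[str, float]]] = {}
    source: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("mention_uid"):
            raise ValueError("not a candidate TSV")
        for line in fh:
            uid, _rank, eid, score, src = line.rstrip("\n").split("\t")
            by_uid.setdefault(uid, []).append((eid, float(score)))
            source[uid] = src
    return {
        uid: CandidateList(uid, cands, k=len(cands), source=source[uid])
        for uid, cands in by_uid.items()
    }
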