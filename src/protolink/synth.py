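"""Synthetic KBs and annotated corpora with the statistics the method targets.

Real biomedical linking corpora are heavily imbalanced: most entities carry
only 2–3 mentions while a few carry dozens.  The generator emulates this with
a shifted geometric mention-count distribution (mode at 2–3) plus a small
fraction of heavy "head" entities, concentrates each entity's mentions in one
or two home documents (so documents contain multi-mention classes, the
situation prototype clustering exploits), injects ambiguous synonyms shared
between entities, and perturbs mention surfaces with character-level edits to
emulate surface-form diversity.

Filler sentences come from a small template bank that places the entity's
semantic-type word near the mention, so context carries a weak entity signal
a desk-scale encoder can pick up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kb import Document, EntityRecord, MentionAnnotation

SEMANTIC_TYPES = ["disease", "chemical", "gene", "anatomy", "procedure", "organism"]

_CONSONANTS = "bcdfghklmnprstvz"
_VOWELS = "aeiou"
_ALPHABET = "abcdefghijklmnopqrstuvwxyz"

_TEMPLATES = [
    ("patients with the {type} ", " showed marked improvement ."),
    ("we observed the {type} ", " in a majority of the cohort ."),
    ("treatment targeting ", " , a known {type} , was initiated early ."),
    ("the study reports ", " as a relevant {type} in this population ."),
    ("analysis confirmed that the {type} ", " was present at baseline ."),
]


@dataclass
class SynthConfig:
    """Generator settings; defaults give a strongly imbalanced desk-scale corpus."""

    n_entities: int = 200
    n_documents: int = 250
    synonyms_per_entity: tuple[int, int] = (1, 4)  # UMLS/MeSH average ~2-3 per entity
    ambiguity_rate: float = 0.1
    variant_noise: float = 0.05
    mention_geom_p: float = 0.3  # shifted geometric => mode at 2-3 mentions/entity
    head_fraction: float = 0.05  # heavy entities with tail counts up to the cap
    head_range: tuple[int, int] = (20, 50)
    max_mentions_per_entity: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_entities < 1 or self.n_documents < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.ambiguity_rate < 1:
            raise ValueError("ambiguity_rate must be in [0, 1)")
        if not 0 <= self.variant_noise < 1:
            raise ValueError("variant_noise must be in [0, 1)")


def _pronounceable_word(rng: np.random.Generator) -> str:
    n_syllables = int(rng.integers(2, 5))
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syllables)
    )


def _synonym_string(rng: np.random.Generator) -> str:
    n_words = 1 if rng.random() < 0.6 else 2
    return " ".join(_pronounceable_word(rng) for _ in range(n_words))


def generate_kb(config: SynthConfig) -> list[EntityRecord]:
    """Entities E000.. with random pronounceable synonyms and injected ambiguity.

    After generation, an ``ambiguity_rate`` fraction of synonym strings is
    copied into a second randomly chosen entity's list, so the synonym
    dictionary contains keys mapping to more than one entity.
    """
    rng = np.random.default_rng(config.seed)
    width = max(3, len(str(config.n_entities - 1)))
    lo, hi = config.synonyms_per_entity
    used: set[str] = set()
    records: list[EntityRecord] = []
    for i in range(config.n_entities):
        n_syn = int(rng.integers(lo, hi + 1))
        syns: list[str] = []
        while len(syns) < n_syn:
            s = _synonym_string(rng)
            if s not in used:
                used.add(s)
                syns.append(s)
        records.append(
            EntityRecord(
                entity_id=f"E{i:0{width}d}",
                semantic_type=SEMANTIC_TYPES[int(rng.integers(len(SEMANTIC_TYPES)))],
                synonyms=syns,
            )
        )
    if config.n_entities > 1 and config.ambiguity_rate > 0:
        all_syns = [(i, s) for i, rec in enumerate(records) for s in rec.synonyms]
        for i, s in all_syns:
            if rng.random() < config.ambiguity_rate:
                j = int(rng.integers(config.n_entities - 1))
                if j >= i:
                    j += 1
                if s not in records[j].synonyms:
                    records[j].synonyms.append(s)
    return records


def _perturb(surface: str, noise: float, rng: np.random.Generator) -> str:
    """Character-level substitute/insert/delete edits, each char w.p. ``noise``."""
    if noise == 0:
        return surface
    out: list[str] = []
    for ch in surface:
        if rng.random() < noise:
            op = rng.integers(3)
            if op == 0:  # substitute
                out.append(_ALPHABET[rng.integers(26)])
            elif op == 1:  # insert
                out.append(ch)
                out.append(_ALPHABET[rng.integers(26)])
            # op == 2: delete
        else:
            out.append(ch)
    edited = "".join(out).strip()
    return edited if edited else surface


def _mention_count(config: SynthConfig, rng: np.random.Generator) -> int:
    if rng.random() < config.head_fraction:
        lo, hi = config.head_range
        return int(rng.integers(lo, hi + 1))
    return min(1 + int(rng.geometric(config.mention_geom_p)), config.max_mentions_per_entity)


def generate_corpus(kb: list[EntityRecord], config: SynthConfig) -> list[Document]:
    """Documents with imbalanced, per-document-clustered gold mentions.

    Each entity draws a mention count from the skewed distribution and places
    its mentions in one or two home documents; surfaces are noisy copies of
    KB synonyms; filler sentences embed the semantic type near the mention.
    Documents that end up empty are dropped.
    """
    rng = np.random.default_rng(config.seed + 1)
    per_doc: dict[int, list[tuple[EntityRecord, str]]] = {i: [] for i in range(config.n_documents)}
    for rec in kb:
        count = _mention_count(config, rng)
        n_homes = 1 if count <= 3 or rng.random() < 0.5 else 2
        homes = rng.choice(config.n_documents, size=min(n_homes, config.n_documents), replace=False)
        for _ in range(count):
            doc_i = int(homes[rng.integers(len(homes))])
            syn = rec.synonyms[int(rng.integers(len(rec.synonyms)))]
            per_doc[doc_i].append((rec, _perturb(syn, config.variant_noise, rng)))
    docs: list[Document] = []
    width = max(3, len(str(config.n_documents - 1)))
    for doc_i in range(config.n_documents):
        items = per_doc[doc_i]
        if not items:
            continue
        rng.shuffle(items)
        doc_id = f"D{doc_i:0{width}d}"
        text_parts: list[str] = []
        pos = 0
        mentions: list[MentionAnnotation] = []
        for rec, surface in items:
            before, after = _TEMPLATES[int(rng.integers(len(_TEMPLATES)))]
            before = before.format(type=rec.semantic_type)
            after = after.format(type=rec.semantic_type)
            start = pos + len(before)
            sentence = before + surface + after + " "
            text_parts.append(sentence)
            mentions.append((rec.entity_id, start, start + len(surface), surface))
            pos += len(sentence)
        text = "".join(text_parts).rstrip()
        full = [
            MentionAnnotation(
                doc_id=doc_id,
                start=s,
                end=e,
                surface=surf,
                left_context=text[:s],
                right_context=text[e:],
                gold_entity_id=eid,
            )
            for eid, s, e, surf in mentions
        ]
        full.sort(key=lambda m: (m.start, m.end))
        docs.append(Document(doc_id=doc_id, text=text, mentions=full))
    return docs


def train_dev_test_split(
    corpus: list[Document], seen_fraction: float, seed: int
) -> tuple[list[Document], list[Document], list[Document]]:
    """Partition documents so ~(1 − seen_fraction) of dev/test entities are unseen.

    Documents are first split 60/20/20 at random, which already leaves some
    entities without any training occurrence (documents mix entities, so an
    entity is unseen only when every document it occurs in landed outside
    train).  The split is then adjusted greedily: dev/test documents are
    pulled into train to reduce the unseen-entity fraction, or train
    documents pushed out to raise it, until the fraction of distinct dev/test
    gold entities that never occur in train matches the target within one
    entity (or no single move improves it).  Deterministic under ``seed``.
    """
    if not 0 < seen_fraction <= 1:
        raise ValueError("seen_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    docs = sorted(corpus, key=lambda d: d.doc_id)
    order = rng.permutation(len(docs))
    n = len(docs)
    n_train, n_dev = round(0.6 * n), round(0.2 * n)
    split: dict[str, str] = {}
    for rank, idx in enumerate(order):
        split[docs[idx].doc_id] = (
            "train" if rank < n_train else "dev" if rank < n_train + n_dev else "test"
        )
    doc_entities = {d.doc_id: {m.gold_entity_id for m in d.mentions} for d in docs}

    def status() -> tuple[set[str], set[str]]:
        train_ents: set[str] = set()
        devtest_ents: set[str] = set()
        for d in docs:
            (train_ents if split[d.doc_id] == "train" else devtest_ents).update(
                doc_entities[d.doc_id]
            )
        return devtest_ents, devtest_ents - train_ents

    for _ in range(4 * n):
        devtest_ents, unseen = status()
        target = round((1 - seen_fraction) * len(devtest_ents))
        if abs(len(unseen) - target) <= (0 if seen_fraction == 1.0 else 1):
            break
        if len(unseen) > target:
            # Pull a dev/test document resolving unseen entities into train,
            # preferring the larger of dev/test so the ratio survives.
            n_dev_now = sum(1 for s in split.values() if s == "dev")
            n_test_now = sum(1 for s in split.values() if s == "test")
            prefer = "dev" if n_dev_now >= n_test_now else "test"
            best = None
            for d in docs:
                if split[d.doc_id] == "train":
                    continue
                gain = len(doc_entities[d.doc_id] & unseen)
                if gain:
                    key = (split[d.doc_id] != prefer, -gain, d.doc_id)
                    if best is None or key < best[0]:
                        best = (key, d.doc_id)
            if best is None:
                break
            split[best[1]] = "train"
        else:
            # Push out the train document creating the fewest (but >0)
            # newly unseen entities; alternate dev/test to keep the ratio.
            only_here: dict[str, set[str]] = {}
            counts: dict[str, int] = {}
            for d in docs:
                if split[d.doc_id] == "train":
                    for e in doc_entities[d.doc_id]:
                        counts[e] = counts.get(e, 0) + 1
            for d in docs:
                if split[d.doc_id] == "train":
                    only_here[d.doc_id] = {
                        e for e in doc_entities[d.doc_id] if counts[e] == 1
                    }
            best = None
            for doc_id, ents in only_here.items():
                if ents and (best is None or len(ents) < best[0]):
                    best = (len(ents), doc_id)
            if best is None:
                break
            n_dev_now = sum(1 for s in split.values() if s == "dev")
            n_test_now = sum(1 for s in split.values() if s == "test")
            split[best[1]] = "dev" if n_dev_now <= n_test_now else "test"

    out = {"train": [], "dev": [], "test": []}
    for d in docs:
        out[split[d.doc_id]].append(d)
    return out["train"], out["dev"], out["test"]
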