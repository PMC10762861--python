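"""Knowledge-base and corpus I/O.

A knowledge base is a collection of entities (concepts), each identified by an
opaque ID such as a UMLS CUI or a MeSH descriptor, carrying a semantic type and
a list of synonym strings.  Candidate retrieval works against the *synonym
dictionary*: an inverted map from synonym string to the set of entities the
string may denote.  Ambiguous synonyms map to more than one entity.

Two KB sources are supported: UMLS-style pipe-delimited ``MRCONSO.RRF`` /
``MRSTY.RRF`` files, and a simple JSONL dialect
``{"entity_id": ..., "semantic_type": ..., "synonyms": [...]}``.

The corpus dialect is JSONL, one document per line::

    {"doc_id": ..., "text": ..., "mentions": [{"start", "end", "surface",
                                               "entity_id"}, ...]}

Offsets are 0-based half-open character offsets into ``text``; ``surface``
must equal ``text[start:end]`` before lowercasing.  All dictionary and mention
text is lowercased at load time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class MalformedRowError(ValueError):
    """A pipe-delimited row had too few fields (carries the 1-based line number)."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class CorpusFormatError(ValueError):
    """A corpus document failed validation (carries the offending doc_id)."""

    def __init__(self, doc_id: str, message: str):
        self.doc_id = doc_id
        super().__init__(f"document {doc_id!r}: {message}")


@dataclass
class EntityRecord:
    """One KB concept: ID, semantic type, and its synonym strings.

    Synonyms are lowercased and de-duplicated (first occurrence kept) at
    construction; empty synonyms are rejected.
    """

    entity_id: str
    semantic_type: str
    synonyms: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        cleaned: list[str] = []
        for s in self.synonyms:
            if not s:
                raise ValueError(f"entity {self.entity_id}: empty synonym")
            low = s.lower()
            if low not in seen:
                seen.add(low)
                cleaned.append(low)
        self.synonyms = cleaned


@dataclass(frozen=True)
class MentionAnnotation:
    """A mention span in a document with its gold entity.

    ``left_context`` / ``right_context`` are the document text before/after the
    span (lowercased, like ``surface``).
    """

    doc_id: str
    start: int
    end: int
    surface: str
    left_context: str
    right_context: str
    gold_entity_id: str

    @property
    def uid(self) -> str:
        return f"{self.doc_id}:{self.start}-{self.end}"


@dataclass
class Document:
    doc_id: str
    text: str
    mentions: list[MentionAnnotation] = field(default_factory=list)


class SynonymIndex:
    """Inverted map synonym string -> set of entity IDs (the dictionary S).

    Also keeps the entity records so downstream stages can template entities.
    """

    def __init__(self, entities: Sequence[EntityRecord]):
        ids = [e.entity_id for e in entities]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate entity_id in KB")
        # Sort for order-independence: permuting the input entity list must
        # yield an identical index.
        self.entities: dict[str, EntityRecord] = {
            e.entity_id: e for e in sorted(entities, key=lambda e: e.entity_id)
        }
        self.entries: dict[str, set[str]] = {}
        for e in self.entities.values():
            for s in e.synonyms:
                self.entries.setdefault(s, set()).add(e.entity_id)

    @property
    def synonyms(self) -> list[str]:
        """All distinct synonym strings, sorted (deterministic row order)."""
        return sorted(self.entries)

    def entities_for(self, synonym: str) -> set[str]:
        return self.entries.get(synonym, set())

    def __len__(self) -> int:
        return len(self.entries)


def build_synonym_index(entities: Sequence[EntityRecord]) -> SynonymIndex:
    """Build the synonym dictionary from entity records."""
    return SynonymIndex(entities)


def read_mrconso(path: str | Path, language_filter: str = "ENG") -> list[tuple[str, str]]:
    """Read (entity_id, synonym) pairs from a pipe-delimited MRCONSO.RRF file.

    Field 1 is the CUI, field 2 the language code, field 15 the string.  Only
    rows whose language matches ``language_filter`` are kept; strings are
    lowercased and exact duplicate pairs collapsed (first occurrence kept).
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("|")
            if len(fields) < 15:
                raise MalformedRowError(lineno, f"expected >=15 fields, got {len(fields)}")
            cui, lang, string = fields[0], fields[1], fields[14]
            if lang != language_filter or not string:
                continue
            pair = (cui, string.lower())
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    return pairs


def read_mrsty(path: str | Path) -> dict[str, str]:
    """Read entity_id -> semantic type from a pipe-delimited MRSTY.RRF file.

    Field 1 is the CUI, field 4 the type name.  An entity with several type
    rows keeps all types, joined with a single space in first-seen order (the
    entity template has one type slot).
    """
    types: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("|")
            if len(fields) < 4:
                raise MalformedRowError(lineno, f"expected >=4 fields, got {len(fields)}")
            cui, type_name = fields[0], fields[3]
            bucket = types.setdefault(cui, [])
            if type_name not in bucket:
                bucket.append(type_name)
    return {cui: " ".join(names) for cui, names in types.items()}


def entities_from_umls(
    conso_pairs: Iterable[tuple[str, str]],
    semantic_types: dict[str, str],
    default_type: str = "unknown",
) -> list[EntityRecord]:
    """Assemble EntityRecords from MRCONSO pairs and MRSTY types."""
    synonyms: dict[str, list[str]] = {}
    for cui, syn in conso_pairs:
        synonyms.setdefault(cui, []).append(syn)
    return [
        EntityRecord(cui, semantic_types.get(cui, default_type), syns)
        for cui, syns in synonyms.items()
    ]


def read_kb_jsonl(path: str | Path) -> list[EntityRecord]:
    """Read the simple KB JSONL dialect."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            records.append(
                EntityRecord(obj["entity_id"], obj["semantic_type"], list(obj["synonyms"]))
            )
    return records


def write_kb_jsonl(entities: Sequence[EntityRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in entities:
            fh.write(
                json.dumps(
                    {
                        "entity_id": e.entity_id,
                        "semantic_type": e.semantic_type,
                        "synonyms": e.synonyms,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def _make_mention(doc_id: str, text: str, obj: dict) -> MentionAnnotation:
    start, end = int(obj["start"]), int(obj["end"])
    surface = obj["surface"]
    if not (0 <= start < end <= len(text)):
        raise CorpusFormatError(doc_id, f"span ({start},{end}) out of bounds for text of length {len(text)}")
    if text[start:end] != surface:
        raise CorpusFormatError(
            doc_id,
            f"span ({start},{end}) reads {text[start:end]!r}, annotation says {surface!r}",
        )
    return MentionAnnotation(
        doc_id=doc_id,
        start=start,
        end=end,
        surface=surface.lower(),
        left_context=text[:start].lower(),
        right_context=text[end:].lower(),
        gold_entity_id=obj["entity_id"],
    )


def read_corpus(path: str | Path) -> list[Document]:
    """Read the JSONL corpus dialect, validating spans against the text.

    Upstream preprocessing (abbreviation expansion, sentence splitting) is
    assumed already applied; the reader consumes whatever text is given.
    """
    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            doc_id, text = obj["doc_id"], obj["text"]
            mentions = [_make_mention(doc_id, text, m) for m in obj.get("mentions", [])]
            mentions.sort(key=lambda m: (m.start, m.end))
            docs.append(Document(doc_id=doc_id, text=text, mentions=mentions))
    return docs


def write_corpus(docs: Sequence[Document], path: str | Path) -> None:
    """Write documents in the corpus JSONL dialect (round-trips read_corpus)."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            obj = {
                "doc_id": d.doc_id,
                "text": d.text,
                "mentions": [
                    {
                        "start": m.start,
                        "end": m.end,
                        "surface": d.text[m.start : m.end],
                        "entity_id": m.gold_entity_id,
                    }
                    for m in d.mentions
                ],
            }
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def remove_overlapping_mentions(mentions: Sequence[MentionAnnotation]) -> list[MentionAnnotation]:
    """Drop overlapping spans, keeping the longest (ties: earlier start).

    Input must be sorted by start offset.  Deterministic: candidates are
    considered in order of decreasing length, then increasing start, and a
    span is kept iff it overlaps no previously kept span.
    """
    order = sorted(mentions, key=lambda m: (-(m.end - m.start), m.start, m.end))
    kept: list[MentionAnnotation] = []
    for m in order:
        if all(m.end <= k.start or m.start >= k.end for k in kept):
            kept.append(m)
    kept.sort(key=lambda m: (m.start, m.end))
    return kept
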