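import numpy as np
import pytest

from protolink.kb import Document, EntityRecord, MentionAnnotation, build_synonym_index


def make_mention(doc_id, text, start, end, gold, lowered=True):
    surface = text[start:end]
    return MentionAnnotation(
        doc_id=doc_id,
        start=start,
        end=end,
        surface=surface.lower() if lowered else surface,
        left_context=text[:start].lower(),
        right_context=text[end:].lower(),
        gold_entity_id=gold,
    )


def make_document(doc_id, text, spans):
    """spans: list of (start, end, gold_entity_id)."""
    mentions = [make_mention(doc_id, text, s, e, g) for s, e, g in spans]
    mentions.sort(key=lambda m: (m.start, m.end))
    return Document(doc_id=doc_id, text=text, mentions=mentions)


@pytest.fixture
def tiny_kb():
    """Three entities, seven synonym strings, one shared ('cold')."""
    return [
        EntityRecord("C01", "disease", ["common cold", "cold", "acute rhinitis"]),
        EntityRecord("C02", "finding", ["cold", "cold sensation"]),
        EntityRecord("C03", "chemical", ["aspirin", "acetylsalicylic acid"]),
    ]


@pytest.fixture
def tiny_index(tiny_kb):
    return build_synonym_index(tiny_kb)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
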