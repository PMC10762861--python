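"""Input templates and the sequence-encoder contract for the dual encoder.

The re-ranker is a dual encoder: a *mention encoder* over the template

    [CLS] left-context [START] mention [END] right-context [SEP]

whose mention representation is the average of the output rows at the
``[START]`` and ``[END]`` marker tokens, and an *entity encoder* over

    [CLS] semantic-type [SEP] synonym1 [SEP] synonym2 [SEP] ...

whose entity representation is the output row at ``[CLS]``.

Any encoder honoring :class:`SequenceEncoder` (one output row per input
token, special tokens atomic) can back these templates; a pre-trained
transformer is one such backend.  :class:`ToyEncoder` is a deterministic,
CPU-sized stand-in built on fixed random projections of hashed character
n-gram counts.  Content-token rows are purely local; special-token rows
additionally pool the mean feature vector of their adjacent content
segment(s) — [END] pools the mention span, [START] pools the span plus a
down-weighted left context, [SEP] pools the synonym it terminates, and
[CLS] pools every content segment of its sequence — so the rows the
templates extract actually summarize the relevant content.  A trainable d×d
linear head sits on top: embeddings are linear in the head weights, so
triplet-loss gradients are closed form and metric learning is exercisable
without a GPU.
"""

from __future__ import annotations

import re
import zlib
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

from .kb import EntityRecord, MentionAnnotation

CLS, SEP, START, END = "[CLS]", "[SEP]", "[START]", "[END]"

_TOKEN_RE = re.compile(r"\[[A-Z]+\]|[0-9a-z]+")


class SequenceEncoder(ABC):
    """Contract: tokenize text; encode a token sequence to one d-vector per token."""

    d: int
    trainable: bool

    @abstractmethod
    def tokenize(self, text: str) -> list[str]: ...

    @abstractmethod
    def encode(self, tokens: list[str]) -> np.ndarray:
        """(n_tokens, d) matrix, one row per input token."""


@dataclass
class MentionInput:
    """Token layout [CLS] c_l [START] m [END] c_r [SEP] with marker positions."""

    tokens: list[str]
    start_pos: int
    end_pos: int

    def __post_init__(self) -> None:
        if self.tokens.count(START) != 1 or self.tokens.count(END) != 1:
            raise ValueError("mention input must contain exactly one [START] and one [END]")
        if not self.start_pos < self.end_pos:
            raise ValueError("[START] must precede [END]")

    @property
    def mention_tokens(self) -> list[str]:
        return self.tokens[self.start_pos + 1 : self.end_pos]


@dataclass
class EntityInput:
    """Token layout [CLS] type [SEP] syn1 [SEP] syn2 [SEP] ..."""

    tokens: list[str]
    n_synonyms: int

    def __post_init__(self) -> None:
        if self.n_synonyms < 1:
            raise ValueError("entity input must contain at least one synonym")


def format_mention_input(
    mention: MentionAnnotation, encoder: SequenceEncoder, max_len: int = 128
) -> MentionInput:
    """Build the mention template, trimming context when over ``max_len``.

    Context tokens are trimmed alternately from the far ends (leftmost of the
    left context first, then rightmost of the right context), never from the
    mention itself, so both sides lose an equal number of tokens (±1).
    """
    m = encoder.tokenize(mention.surface)
    cl = encoder.tokenize(mention.left_context)
    cr = encoder.tokenize(mention.right_context)
    core = len(m) + 4  # [CLS] [START] [END] [SEP]
    if core > max_len:
        raise ValueError(
            f"mention {mention.uid}: {len(m)} mention tokens cannot fit in max_len={max_len}"
        )
    budget = max_len - core
    trim_left = True
    while len(cl) + len(cr) > budget:
        if trim_left and cl:
            cl = cl[1:]
        elif cr:
            cr = cr[:-1]
        elif cl:
            cl = cl[1:]
        trim_left = not trim_left
    tokens = [CLS, *cl, START, *m, END, *cr, SEP]
    start_pos = 1 + len(cl)
    end_pos = start_pos + 1 + len(m)
    return MentionInput(tokens=tokens, start_pos=start_pos, end_pos=end_pos)


def format_entity_input(
    entity: EntityRecord, encoder: SequenceEncoder, max_len: int = 128
) -> EntityInput:
    """Build the entity template; over-length input drops whole trailing synonyms."""
    if not entity.synonyms:
        raise ValueError(f"entity {entity.entity_id} has no synonyms")
    tokens = [CLS, *encoder.tokenize(entity.semantic_type), SEP]
    n_syn = 0
    for syn in entity.synonyms:
        syn_tokens = encoder.tokenize(syn)
        if len(tokens) + len(syn_tokens) + 1 > max_len and n_syn >= 1:
            break
        if len(tokens) + len(syn_tokens) + 1 > max_len:
            raise ValueError(
                f"entity {entity.entity_id}: first synonym does not fit in max_len={max_len}"
            )
        tokens.extend([*syn_tokens, SEP])
        n_syn += 1
    return EntityInput(tokens=tokens, n_synonyms=n_syn)


def mention_embedding(minput: MentionInput, encoder: SequenceEncoder) -> np.ndarray:
    """Average of the output rows at the [START] and [END] markers."""
    rows = encoder.encode(minput.tokens)
    return (rows[minput.start_pos] + rows[minput.end_pos]) / 2.0


def entity_embedding(
    entity: EntityRecord, encoder: SequenceEncoder, max_len: int = 128
) -> np.ndarray:
    """Output row at [CLS] of the entity template."""
    einput = format_entity_input(entity, encoder, max_len=max_len)
    return encoder.encode(einput.tokens)[0]


class _FeatureMap:
    """Fixed random projection of hashed character n-gram (n=2,3) counts,
    shared between the two toy encoders (the dual encoders start from one
    feature space, as dual BERT encoders start from one pre-trained model)."""

    def __init__(self, d: int, n_features: int, seed: int):
        rng = np.random.default_rng(seed)
        self.n_features = n_features
        self.projection = rng.standard_normal((n_features, d)) / np.sqrt(d)
        self._cache: dict[str, np.ndarray] = {}

    def token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            padded = f"#{token}#"
            counts = np.zeros(self.n_features)
            for n in (2, 3):
                for i in range(len(padded) - n + 1):
                    counts[zlib.crc32(padded[i : i + n].encode("utf-8")) % self.n_features] += 1.0
            norm = np.linalg.norm(counts)
            if norm > 0:
                counts /= norm
            vec = counts @ self.projection
            self._cache[token] = vec
        return vec


_SPECIALS = {CLS, SEP, START, END}


class ToyEncoder(SequenceEncoder):
    """Deterministic toy sequence encoder with a trainable linear head.

    Pre-activation rows: a content token's row is its fixed feature vector
    b_i.  Special-token rows are pooled summaries of adjacent content (as a
    transformer's special-token outputs summarize context rather than the
    marker string itself).  With a *segment* being a maximal run of content
    tokens between special tokens and its bag the mean of its feature
    vectors:

    * ``[END]`` and ``[SEP]`` are the bag of the segment they terminate
      (the mention span / the preceding synonym);
    * ``[START]`` is the bag of the following segment (the mention span)
      plus ``ctx_weight`` times the bag of the preceding one (left context);
    * ``[CLS]`` is the mean feature vector of all content tokens.

    The rows the templates extract therefore summarize the relevant content
    (and the mention representation is invariant to the right context).
    Output row i = W @ u_i with W the trainable d×d head, initialized to the
    identity; embeddings are linear in W.
    """

    trainable = True

    def __init__(
        self,
        d: int = 32,
        seed: int = 0,
        ctx_weight: float = 0.5,
        n_features: int = 4096,
        feature_map: _FeatureMap | None = None,
    ):
        if d < 2:
            raise ValueError("d must be >= 2")
        self.d = d
        self.ctx_weight = ctx_weight
        self.features_map = feature_map or _FeatureMap(d, n_features, seed)
        self.W = np.eye(d)

    def tokenize(self, text: str) -> list[str]:
        """Lowercase alphanumeric tokens; bracketed special tokens stay atomic."""
        return _TOKEN_RE.findall(text.lower() if "[" not in text else _lower_keep_special(text))

    def features(self, tokens: list[str]) -> np.ndarray:
        """Pre-activation matrix U (before the trainable head)."""
        fm = self.features_map
        base = np.stack([fm.token_vector(t) for t in tokens]) if tokens else np.zeros((0, self.d))
        zero = np.zeros(self.d)
        # Content segments: maximal runs of non-special tokens, as
        # (start, end) half-open position spans with their mean bag.
        segments: list[tuple[int, int, np.ndarray]] = []
        run_start: int | None = None
        for i, t in enumerate(tokens):
            if t in _SPECIALS:
                if run_start is not None:
                    segments.append((run_start, i, base[run_start:i].mean(axis=0)))
                    run_start = None
            elif run_start is None:
                run_start = i
        if run_start is not None:
            segments.append((run_start, len(tokens), base[run_start:].mean(axis=0)))
        content = [i for i, t in enumerate(tokens) if t not in _SPECIALS]
        token_mean = base[content].mean(axis=0) if content else zero
        ends_at = {end: bag for _, end, bag in segments}
        starts_at = {start: bag for start, _, bag in segments}

        out = base.copy()
        for i, t in enumerate(tokens):
            if t == CLS:
                out[i] = token_mean
            elif t in (END, SEP):
                out[i] = ends_at.get(i, zero)
            elif t == START:
                out[i] = starts_at.get(i + 1, zero) + self.ctx_weight * ends_at.get(i, zero)
        return out

    def encode(self, tokens: list[str]) -> np.ndarray:
        return self.features(tokens) @ self.W.T

    def embed_text(self, text: str, max_tokens: int | None = None) -> np.ndarray:
        """Summary vector for a bare string (used by dense retrieval).

        The string is wrapped as [CLS] tokens [SEP] and the [CLS] row is
        returned.  Truncation keeps the first ``max_tokens - 2`` tokens.
        """
        body = self.tokenize(text)
        if max_tokens is not None:
            body = body[: max(max_tokens - 2, 0)]
        return self.encode([CLS, *body, SEP])[0]


def _lower_keep_special(text: str) -> str:
    # Lowercase everything except bracketed special tokens.
    parts = re.split(r"(\[[A-Z]+\])", text)
    return "".join(p if re.fullmatch(r"\[[A-Z]+\]", p) else p.lower() for p in parts)


def toy_encoder(d: int = 32, seed: int = 0) -> ToyEncoder:
    """A single deterministic toy encoder (see :class:`ToyEncoder`)."""
    return ToyEncoder(d=d, seed=seed)


def toy_dual_encoder(
    d: int = 32, seed: int = 0, ctx_weight: float = 0.5
) -> tuple[ToyEncoder, ToyEncoder]:
    """Mention and entity toy encoders sharing one token feature space,
    with independent trainable heads."""
    fmap = _FeatureMap(d, 4096, seed)
    mention_enc = ToyEncoder(d=d, seed=seed, ctx_weight=ctx_weight, feature_map=fmap)
    entity_enc = ToyEncoder(d=d, seed=seed, ctx_weight=ctx_weight, feature_map=fmap)
    return mention_enc, entity_enc
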