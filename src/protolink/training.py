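"""Training loop for the re-ranker under the four regimes.

Regimes:

* ``triplet_all`` — standard triplet loss, one training unit per mention.
* ``triplet_downsample`` — standard triplet loss after down-sampling to one
  mention per class (entity) per document.
* ``proto`` — prototype-based triplet loss, one unit per class: the whole
  class is the cluster.
* ``proto_srn`` — prototype-based triplet loss over soft-radius-neighbor
  clusters around a randomly chosen anchor; the radius threshold λ is updated
  per batch toward the mean observed cluster radius.

Negatives come from each anchor mention's precomputed retrieval candidates
(frozen lists); "online" hardest-negative mining re-measures candidate
distances under the current encoder state every time a unit is visited.  The
positive is always the gold entity's KB record, whether or not retrieval
found it.

Training requires encoders whose trainable part is a linear head (the toy
encoder): embeddings are then linear in the head weights and the hinge-loss
gradients are closed form.  A batch counts clusters (units), not mentions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .encoding import ToyEncoder, format_entity_input, format_mention_input
from .kb import Document, EntityRecord, MentionAnnotation
from .metric import RadiusState, form_cluster, update_radius
from .retrieval import CandidateList

REGIMES = ("triplet_all", "triplet_downsample", "proto", "proto_srn")


@dataclass
class TrainingConfig:
    """Hyperparameters; defaults follow the reference configuration
    (α=1.2, k=64 candidates, batch of 32 clusters, λ0=11.0, ϵ=1.0,
    lr_λ=0.005, encoder learning rate 1e-5, 3 epochs)."""

    regime: str = "proto_srn"
    alpha: float = 1.2
    k_candidates: int = 64
    batch_size: int = 32
    learning_rate: float = 1e-5
    epochs: int = 3
    lam0: float = 11.0
    eps: float = 1.0
    lr_lam: float = 0.005
    seed: int = 0
    max_len: int = 128
    squared_prototype_loss: bool = False
    hard_negative_reference: str = "prototype"  # or "anchor"

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainingConfig":
        """Defaults sized for the toy linear-head encoder: Adam needs a step
        size matched to the head's parameter scale, far larger than the
        fine-tuning rate appropriate for a transformer backend."""
        overrides.setdefault("learning_rate", 1e-3)
        overrides.setdefault("epochs", 5)
        return cls(**overrides)

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if min(self.alpha, self.k_candidates, self.batch_size, self.learning_rate,
               self.epochs, self.eps + 1, self.lr_lam) <= 0:
            raise ValueError("all numeric settings must be positive")
        if self.hard_negative_reference not in ("prototype", "anchor"):
            raise ValueError("hard_negative_reference must be 'prototype' or 'anchor'")


def build_document_classes(doc: Document) -> dict[str, list[MentionAnnotation]]:
    """Group a document's mentions by gold entity, first-occurrence order."""
    classes: dict[str, list[MentionAnnotation]] = {}
    for m in doc.mentions:
        classes.setdefault(m.gold_entity_id, []).append(m)
    return classes


def downsample_classes(
    classes: dict[str, list[MentionAnnotation]], rng: np.random.Generator
) -> dict[str, list[MentionAnnotation]]:
    """Keep exactly one randomly chosen mention per class (document level)."""
    return {eid: [ms[int(rng.integers(len(ms)))]] for eid, ms in classes.items()}


def negatives_from_candidates(candidate_list: CandidateList, gold_id: str) -> list[str]:
    """Candidate entities minus the gold entity; empty means skip the unit."""
    return [eid for eid in candidate_list.entity_ids if eid != gold_id]


class Adam:
    """Adam on a list of numpy arrays (first-order stochastic optimizer
    honoring the configured learning rate)."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class EpochStats:
    mean_loss: float
    loss_evaluations: int
    skipped_clusters: int
    lam: float


@dataclass
class TrainResult:
    mention_encoder: ToyEncoder
    entity_encoder: ToyEncoder
    radius_state: RadiusState
    history: list[EpochStats] = field(default_factory=list)

    @property
    def loss_history(self) -> list[float]:
        return [h.mean_loss for h in self.history]


@dataclass
class _Unit:
    """One training unit: an anchor mention and its co-referent pool."""

    anchor: MentionAnnotation
    pool: list[MentionAnnotation]  # candidates for cluster membership (incl. anchor)
    gold_id: str
    use_srn: bool


class Trainer:
    """Runs the configured regime over a corpus with precomputed candidates."""

    def __init__(
        self,
        corpus: Sequence[Document],
        entities: dict[str, EntityRecord],
        candidates: dict[str, CandidateList],
        mention_encoder: ToyEncoder,
        entity_encoder: ToyEncoder,
        config: TrainingConfig,
    ):
        if not corpus or all(not d.mentions for d in corpus):
            raise ValueError("training corpus has no mentions")
        self.corpus = sorted(corpus, key=lambda d: d.doc_id)
        self.entities = entities
        self.candidates = candidates
        self.menc = mention_encoder
        self.eenc = entity_encoder
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.radius_state = RadiusState(lam=config.lam0, eps=config.eps, lr_lam=config.lr_lam)
        self.optimizer = Adam([self.menc.W, self.eenc.W], lr=config.learning_rate)
        self._mention_pre: dict[str, np.ndarray] = {}
        self._entity_pre: dict[str, np.ndarray] = {}
        self._precompute()

    # -- fixed pre-activation vectors (embeddings are W @ these) -----------

    def _precompute(self) -> None:
        needed: set[str] = set()
        for doc in self.corpus:
            for m in doc.mentions:
                minput = format_mention_input(m, self.menc, max_len=self.config.max_len)
                feats = self.menc.features(minput.tokens)
                self._mention_pre[m.uid] = (feats[minput.start_pos] + feats[minput.end_pos]) / 2.0
                needed.add(m.gold_entity_id)
                cl = self.candidates.get(m.uid)
                if cl is not None:
                    needed.update(cl.entity_ids)
        for eid in sorted(needed):
            rec = self.entities.get(eid)
            if rec is None:
                continue
            einput = format_entity_input(rec, self.eenc, max_len=self.config.max_len)
            self._entity_pre[eid] = self.eenc.features(einput.tokens)[0]

    def _mention_emb(self, uid: str) -> np.ndarray:
        return self.menc.W @ self._mention_pre[uid]

    def _entity_emb(self, eid: str) -> np.ndarray:
        return self.eenc.W @ self._entity_pre[eid]

    # -- units --------------------------------------------------------------

    def _epoch_units(self) -> list[_Unit]:
        regime = self.config.regime
        units: list[_Unit] = []
        for doc in self.corpus:
            classes = build_document_classes(doc)
            if regime == "triplet_downsample":
                classes = downsample_classes(classes, self.rng)
            if regime in ("triplet_all", "triplet_downsample"):
                for eid, members in classes.items():
                    for m in members:
                        units.append(_Unit(anchor=m, pool=[m], gold_id=eid, use_srn=False))
            else:
                for eid, members in classes.items():
                    anchor = members[int(self.rng.integers(len(members)))]
                    units.append(
                        _Unit(anchor=anchor, pool=members, gold_id=eid,
                              use_srn=(regime == "proto_srn"))
                    )
        order = self.rng.permutation(len(units))
        return [units[i] for i in order]

    # -- one unit: loss + gradients -----------------------------------------

    def _unit_loss(self, unit: _Unit) -> tuple[float, np.ndarray, np.ndarray, float] | None:
        """Returns (loss, dW_m, dW_e, observed_radius) or None when skipped."""
        cl = self.candidates.get(unit.anchor.uid)
        if cl is None or unit.gold_id not in self._entity_pre:
            return None
        neg_ids = negatives_from_candidates(cl, unit.gold_id)
        neg_ids = [e for e in neg_ids if e in self._entity_pre]
        if not neg_ids:
            return None

        if unit.use_srn:
            embeddings = {m.uid: self._mention_emb(m.uid) for m in unit.pool}
            cluster = form_cluster(
                unit.anchor.uid, [m.uid for m in unit.pool], embeddings, self.radius_state
            )
            member_uids = cluster.members
            radius = cluster.radius_observed
        else:
            member_uids = [m.uid for m in unit.pool]
            radius = 0.0

        proto_pre = np.mean([self._mention_pre[u] for u in member_uids], axis=0)
        proto_emb = self.menc.W @ proto_pre

        # Hardest negative under the current model, measured from the
        # prototype (or the anchor mention, if configured).
        if self.config.hard_negative_reference == "prototype":
            ref = proto_emb
        else:
            ref = self._mention_emb(unit.anchor.uid)
        best: tuple[float, str] | None = None
        for eid in neg_ids:
            dist = float(np.linalg.norm(ref - self._entity_emb(eid)))
            if best is None or (dist, eid) < best:
                best = (dist, eid)
        neg_id = best[1]

        v_pos = self._entity_pre[unit.gold_id]
        v_neg = self._entity_pre[neg_id]
        z_pos = proto_emb - self.eenc.W @ v_pos
        z_neg = proto_emb - self.eenc.W @ v_neg
        if self.config.regime in ("triplet_all", "triplet_downsample"):
            squared = True  # printed with squared norms for the standard loss
        else:
            squared = self.config.squared_prototype_loss
        d_pos = float(np.linalg.norm(z_pos))
        d_neg = float(np.linalg.norm(z_neg))
        if squared:
            loss = d_pos**2 - d_neg**2 + self.config.alpha
        else:
            loss = d_pos - d_neg + self.config.alpha
        if loss <= 0:
            return (0.0, np.zeros_like(self.menc.W), np.zeros_like(self.eenc.W), radius)
        if squared:
            g_pos, g_neg = 2.0 * z_pos, 2.0 * z_neg
        else:
            g_pos = z_pos / d_pos if d_pos > 0 else np.zeros_like(z_pos)
            g_neg = z_neg / d_neg if d_neg > 0 else np.zeros_like(z_neg)
        dW_m = np.outer(g_pos - g_neg, proto_pre)
        dW_e = -np.outer(g_pos, v_pos) + np.outer(g_neg, v_neg)
        return (float(loss), dW_m, dW_e, radius)

    # -- epochs --------------------------------------------------------------

    def train_epoch(self) -> EpochStats:
        units = self._epoch_units()
        losses: list[float] = []
        skipped = 0
        bs = self.config.batch_size
        for i in range(0, len(units), bs):
            batch = units[i : i + bs]
            grads_m = np.zeros_like(self.menc.W)
            grads_e = np.zeros_like(self.eenc.W)
            radii: list[float] = []
            n_eval = 0
            for unit in batch:
                result = self._unit_loss(unit)
                if result is None:
                    skipped += 1
                    continue
                loss, dW_m, dW_e, radius = result
                losses.append(loss)
                grads_m += dW_m
                grads_e += dW_e
                n_eval += 1
                if unit.use_srn:
                    radii.append(radius)
            if n_eval:
                self.optimizer.step([grads_m / n_eval, grads_e / n_eval])
            if self.config.regime == "proto_srn":
                self.radius_state = update_radius(self.radius_state, radii)
        mean_loss = float(np.mean(losses)) if losses else 0.0
        return EpochStats(
            mean_loss=mean_loss,
            loss_evaluations=len(losses),
            skipped_clusters=skipped,
            lam=self.radius_state.lam,
        )

    def train(self) -> TrainResult:
        result = TrainResult(self.menc, self.eenc, self.radius_state)
        for _ in range(self.config.epochs):
            stats = self.train_epoch()
            result.history.append(stats)
        result.radius_state = self.radius_state
        return result


def train(
    corpus: Sequence[Document],
    entities: dict[str, EntityRecord],
    candidates: dict[str, CandidateList],
    mention_encoder: ToyEncoder,
    entity_encoder: ToyEncoder,
    config: TrainingConfig,
) -> TrainResult:
    """Train the dual encoder under ``config.regime``; see module docstring."""
    return Trainer(corpus, entities, candidates, mention_encoder, entity_encoder, config).train()
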