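"""Metric-learning primitives: triplet losses, prototypes, soft-radius
neighbor (SRN) clustering, and hardest-negative mining.

The standard triplet loss over mention anchor m, positive entity e+ and
negative entity e- is the hinge

    [ ||f_m(m) - f_e(e+)||^2 - ||f_m(m) - f_e(e-)||^2 + alpha ]_+

with squared Euclidean distances.  The prototype-based variant replaces the
anchor by the *prototype* — the arithmetic mean of the embeddings of all
mentions in a cluster that co-refer to one entity within a document — and is
defined with unsquared Euclidean distances (a ``squared`` switch selects the
squared variant).

SRN clustering picks an anchor mention and includes every co-referent
mention of the same document whose embedding lies strictly within the
learnable radius threshold λ plus a fixed slack ϵ of the anchor.  λ is
updated toward the mean observed cluster radius with its own learning rate,
so it tracks the shrinking within-cluster distances during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Hashable, Sequence

import numpy as np


def _check_dims(*vecs: np.ndarray) -> None:
    dims = {np.asarray(v).shape for v in vecs}
    if len(dims) != 1 or any(len(s) != 1 for s in dims):
        raise ValueError(f"vectors must share one dimension, got shapes {sorted(dims)}")


def triplet_loss(a: np.ndarray, p: np.ndarray, n: np.ndarray, alpha: float) -> float:
    """Standard triplet hinge with squared Euclidean distances."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    _check_dims(a, p, n)
    a, p, n = np.asarray(a, float), np.asarray(p, float), np.asarray(n, float)
    d_pos = float(np.sum((a - p) ** 2))
    d_neg = float(np.sum((a - n) ** 2))
    return max(0.0, d_pos - d_neg + alpha)


def prototype(member_embeddings: Sequence[np.ndarray]) -> np.ndarray:
    """Coordinate-wise mean of the cluster members' embeddings."""
    if len(member_embeddings) == 0:
        raise ValueError("prototype of an empty cluster is undefined")
    _check_dims(*member_embeddings)
    return np.mean(np.asarray(member_embeddings, dtype=float), axis=0)


def prototype_triplet_loss(
    proto: np.ndarray,
    e_pos: np.ndarray,
    e_neg: np.ndarray,
    alpha: float,
    squared: bool = False,
) -> float:
    """Prototype-based triplet hinge (unsquared Euclidean distances by default)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    _check_dims(proto, e_pos, e_neg)
    proto = np.asarray(proto, float)
    d_pos = float(np.linalg.norm(proto - np.asarray(e_pos, float)))
    d_neg = float(np.linalg.norm(proto - np.asarray(e_neg, float)))
    if squared:
        d_pos, d_neg = d_pos**2, d_neg**2
    return max(0.0, d_pos - d_neg + alpha)


@dataclass(frozen=True)
class RadiusState:
    """Learnable radius threshold λ with fixed slack ϵ and its learning rate.

    The effective clustering threshold is λ + ϵ.  Defaults follow the
    reference configuration: λ0 = 11.0, ϵ = 1.0, lr = 0.005.
    """

    lam: float = 11.0
    eps: float = 1.0
    lr_lam: float = 0.005

    def __post_init__(self) -> None:
        if not np.isfinite(self.lam) or self.lam < 0:
            raise ValueError("lam must be finite and non-negative")
        if self.eps < 0 or self.lr_lam <= 0:
            raise ValueError("eps must be >= 0 and lr_lam > 0")

    @property
    def threshold(self) -> float:
        return self.lam + self.eps


@dataclass
class ClusterState:
    """An SRN cluster: anchor, members (anchor included), prototype, and the
    observed radius (max anchor-to-member distance; 0 for a singleton)."""

    anchor: Hashable
    members: list[Hashable]
    prototype: np.ndarray
    radius_observed: float
    excluded: list[Hashable] = field(default_factory=list)


def form_cluster(
    anchor: Hashable,
    coreferent: Sequence[Hashable],
    embeddings: dict[Hashable, np.ndarray],
    radius: RadiusState,
) -> ClusterState:
    """Form the SRN cluster of ``anchor`` among its co-referent mentions.

    A co-referent mention joins the cluster iff its Euclidean distance to the
    anchor is strictly below λ + ϵ.  The prototype is the mean embedding of
    the included members; the observed radius is the largest anchor-to-member
    distance among them.
    """
    anchor_emb = np.asarray(embeddings[anchor], float)
    members = [anchor]
    excluded = []
    radius_observed = 0.0
    for m in coreferent:
        if m == anchor:
            continue
        dist = float(np.linalg.norm(anchor_emb - np.asarray(embeddings[m], float)))
        if dist < radius.threshold:
            members.append(m)
            radius_observed = max(radius_observed, dist)
        else:
            excluded.append(m)
    proto = prototype([embeddings[m] for m in members])
    return ClusterState(
        anchor=anchor,
        members=members,
        prototype=proto,
        radius_observed=radius_observed,
        excluded=excluded,
    )


def update_radius(state: RadiusState, observed_radii: Sequence[float]) -> RadiusState:
    """Move λ toward the mean observed cluster radius: λ += lr·(mean − λ).

    An empty batch leaves the state unchanged; the result is clipped at 0.
    """
    if len(observed_radii) == 0:
        return state
    radii = np.asarray(observed_radii, dtype=float)
    if np.any(radii < 0):
        raise ValueError("observed radii must be non-negative")
    new_lam = state.lam + state.lr_lam * (float(radii.mean()) - state.lam)
    return replace(state, lam=max(new_lam, 0.0))


class NoUsableNegative(Exception):
    """Every candidate of this cluster is the gold entity — skip it."""


def hardest_negative(
    proto: np.ndarray,
    candidate_entities: Sequence[tuple[str, np.ndarray]],
    gold_id: str,
) -> tuple[str, np.ndarray]:
    """The non-gold candidate nearest to the reference point in feature space.

    Distance is measured from the quantity being optimized (the prototype, or
    the anchor embedding for the standard triplet loss).  Ties break toward
    the lexicographically smaller entity_id.

    Raises :class:`NoUsableNegative` when no non-gold candidate exists.
    """
    proto = np.asarray(proto, float)
    best: tuple[float, str, np.ndarray] | None = None
    for eid, emb in candidate_entities:
        if eid == gold_id:
            continue
        dist = float(np.linalg.norm(proto - np.asarray(emb, float)))
        if best is None or (dist, eid) < (best[0], best[1]):
            best = (dist, eid, emb)
    if best is None:
        raise NoUsableNegative(f"all candidates equal gold entity {gold_id}")
    return best[1], best[2]
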