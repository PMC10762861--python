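"""Training loop: classes, down-sampling, regimes, gradients, determinism."""

import numpy as np
import pytest

from protolink.encoding import ToyEncoder, _FeatureMap
from protolink.kb import EntityRecord
from protolink.retrieval import CandidateList
from protolink.synth import SynthConfig, generate_corpus, generate_kb
from protolink.training import (
    Trainer,
    TrainingConfig,
    build_document_classes,
    downsample_classes,
    negatives_from_candidates,
    train,
)
from tests.conftest import make_document


def small_world(seed=0, n_entities=30, n_documents=40):
    config = SynthConfig(n_entities=n_entities, n_documents=n_documents, seed=seed)
    kb = generate_kb(config)
    corpus = generate_corpus(kb, config)
    entities = {e.entity_id: e for e in kb}
    # Frozen candidate lists: gold plus a few lexicographic neighbors.
    ids = sorted(entities)
    candidates = {}
    for doc in corpus:
        for m in doc.mentions:
            pos = ids.index(m.gold_entity_id)
            picked = [m.gold_entity_id] + [ids[(pos + j) % len(ids)] for j in (1, 2, 3)]
            candidates[m.uid] = CandidateList(
                m.uid, [(e, 1.0 - 0.1 * r) for r, e in enumerate(picked)], k=4
            )
    return kb, corpus, entities, candidates


class TestDocumentClasses:
    def test_grouping_by_gold_entity(self):
        doc = make_document("d", "aa bb cc", [(0, 2, "e1"), (3, 5, "e1"), (6, 8, "e2")])
        classes = build_document_classes(doc)
        assert [m.start for m in classes["e1"]] == [0, 3]
        assert len(classes["e2"]) == 1

    def test_empty_document(self):
        assert build_document_classes(make_document("d", "x", [])) == {}

    def test_class_counts_partition_mentions(self):
        spans = [(i * 3, i * 3 + 2, f"e{i % 3}") for i in range(7)]
        doc = make_document("d", "ab " * 7, spans)
        classes = build_document_classes(doc)
        assert len(classes) == 3
        assert sum(len(v) for v in classes.values()) == 7


class TestDownsampling:
    def test_every_class_reduced_to_one(self, rng):
        doc = make_document("d", "ab " * 6, [(i * 3, i * 3 + 2, f"e{i % 2}") for i in range(6)])
        classes = downsample_classes(build_document_classes(doc), rng)
        assert all(len(v) == 1 for v in classes.values())
        assert sum(len(v) for v in classes.values()) == 2

    def test_deterministic_under_seed(self):
        doc = make_document("d", "ab " * 6, [(i * 3, i * 3 + 2, "e0") for i in range(6)])
        classes = build_document_classes(doc)
        a = downsample_classes(classes, np.random.default_rng(5))
        b = downsample_classes(classes, np.random.default_rng(5))
        assert a == b


class TestNegatives:
    def test_gold_absent_all_are_negatives(self):
        cl = CandidateList("m", [("e1", 0.9), ("e2", 0.8)], k=2)
        assert negatives_from_candidates(cl, "gold") == ["e1", "e2"]

    def test_gold_present_excluded(self):
        cl = CandidateList("m", [("gold", 0.9), ("e2", 0.8)], k=2)
        assert negatives_from_candidates(cl, "gold") == ["e2"]

    def test_single_gold_candidate_empty(self):
        cl = CandidateList("m", [("gold", 0.9)], k=1)
        assert negatives_from_candidates(cl, "gold") == []


class _GeometryEncoder(ToyEncoder):
    """Feature map replaced by a lookup of handcrafted token vectors."""

    def __init__(self, table, d=4):
        super().__init__(d=d, seed=0)
        self._table = {k: np.asarray(v, float) for k, v in table.items()}
        self.features_map.token_vector = lambda t: self._table.get(t, np.zeros(d))


class TestIterationCounts:
    @pytest.mark.parametrize("regime,expected", [
        ("proto", "classes"),
        ("proto_srn", "classes"),
        ("triplet_all", "mentions"),
        ("triplet_downsample", "classes"),
    ])
    def test_loss_evaluations_per_regime(self, regime, expected):
        kb, corpus, entities, candidates = small_world(seed=3)
        config = TrainingConfig(regime=regime, epochs=1, seed=0, learning_rate=1e-3)
        trainer = Trainer(corpus, entities, candidates, *_encoders(), config)
        stats = trainer.train_epoch()
        n_mentions = sum(len(d.mentions) for d in corpus)
        n_classes = sum(len(build_document_classes(d)) for d in corpus)
        assert stats.skipped_clusters == 0
        assert stats.loss_evaluations == (n_mentions if expected == "mentions" else n_classes)

    def test_downsample_never_exceeds_all_samples(self):
        kb, corpus, entities, candidates = small_world(seed=4)
        counts = {}
        for regime in ("triplet_all", "triplet_downsample"):
            config = TrainingConfig(regime=regime, epochs=1, seed=0, learning_rate=1e-3)
            trainer = Trainer(corpus, entities, candidates, *_encoders(), config)
            counts[regime] = trainer.train_epoch().loss_evaluations
        assert counts["triplet_downsample"] <= counts["triplet_all"]


def _encoders(seed=0, d=16):
    fmap = _FeatureMap(d, 512, seed)
    return ToyEncoder(d, seed, feature_map=fmap), ToyEncoder(d, seed, feature_map=fmap)


class TestTrainEpoch:
    def test_zero_loss_fixed_point_leaves_parameters_unchanged(self):
        # Geometry where gold is near and the negative far beyond the margin:
        # mention 'aa' at 10*e1; gold entity CLS = mean('tt','aa') = 5*e1;
        # negative CLS = mean('tt','bb') = 5*e2.  Squared distances: 25 vs 125.
        table = {"aa": [10, 0, 0, 0], "bb": [0, 10, 0, 0]}
        menc = _GeometryEncoder(table)
        eenc = _GeometryEncoder(table)
        doc = make_document("d", "aa", [(0, 2, "G")])
        entities = {
            "G": EntityRecord("G", "tt", ["aa"]),
            "N": EntityRecord("N", "tt", ["bb"]),
        }
        candidates = {doc.mentions[0].uid: CandidateList(
            doc.mentions[0].uid, [("G", 1.0), ("N", 0.5)], k=2)}
        config = TrainingConfig(regime="triplet_all", epochs=1, alpha=1.2, seed=0)
        trainer = Trainer([doc], entities, candidates, menc, eenc, config)
        w_before = (menc.W.copy(), eenc.W.copy())
        stats = trainer.train_epoch()
        assert stats.mean_loss == 0.0
        assert np.array_equal(menc.W, w_before[0])
        assert np.array_equal(eenc.W, w_before[1])

    def test_proto_regime_three_classes_three_evaluations(self):
        kb, corpus, entities, candidates = small_world(seed=5)
        doc = next(d for d in corpus if len(build_document_classes(d)) >= 3)
        classes = build_document_classes(doc)
        config = TrainingConfig(regime="proto", epochs=1, seed=0, learning_rate=1e-3)
        trainer = Trainer([doc], entities, candidates, *_encoders(), config)
        stats = trainer.train_epoch()
        assert stats.loss_evaluations == len(classes)

    def test_fixed_seed_reproduces_loss_trajectory(self):
        kb, corpus, entities, candidates = small_world(seed=6)
        runs = []
        for _ in range(2):
            config = TrainingConfig(regime="proto_srn", epochs=3, seed=11, learning_rate=1e-3)
            result = train(corpus, entities, candidates, *_encoders(seed=11), config)
            runs.append(result.loss_history)
        assert runs[0] == runs[1]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            Trainer([], {}, {}, *_encoders(), TrainingConfig())

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(regime="contrastive")


class TestGradients:
    def finite_difference(self, trainer, unit, which, h=1e-6):
        enc = trainer.menc if which == "m" else trainer.eenc
        grad = np.zeros_like(enc.W)
        for i in range(enc.W.shape[0]):
            for j in range(enc.W.shape[1]):
                enc.W[i, j] += h
                up = trainer._unit_loss(unit)[0]
                enc.W[i, j] -= 2 * h
                down = trainer._unit_loss(unit)[0]
                enc.W[i, j] += h
                grad[i, j] = (up - down) / (2 * h)
        return grad

    def test_analytic_gradient_matches_finite_difference(self):
        kb, corpus, entities, candidates = small_world(seed=7, n_entities=10, n_documents=10)
        config = TrainingConfig(regime="proto", epochs=1, seed=0, learning_rate=1e-3, alpha=5.0)
        menc, eenc = _encoders(d=6)
        trainer = Trainer(corpus, entities, candidates, menc, eenc, config)
        unit = trainer._epoch_units()[0]
        loss, dW_m, dW_e, _ = trainer._unit_loss(unit)
        assert loss > 0  # alpha=5 guarantees an active hinge
        assert np.linalg.norm(dW_m) > 0 and np.linalg.norm(dW_e) > 0
        assert np.allclose(dW_m, self.finite_difference(trainer, unit, "m"), atol=1e-4)
        assert np.allclose(dW_e, self.finite_difference(trainer, unit, "e"), atol=1e-4)

    def test_gradient_step_reduces_margin_violation(self):
        kb, corpus, entities, candidates = small_world(seed=8, n_entities=10, n_documents=10)
        config = TrainingConfig(regime="proto", epochs=1, seed=0, alpha=5.0)
        menc, eenc = _encoders(d=6)
        trainer = Trainer(corpus, entities, candidates, menc, eenc, config)
        unit = trainer._epoch_units()[0]
        loss0, dW_m, dW_e, _ = trainer._unit_loss(unit)
        step = 1e-3
        menc.W -= step * dW_m
        eenc.W -= step * dW_e
        loss1 = trainer._unit_loss(unit)[0]
        assert loss1 < loss0
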