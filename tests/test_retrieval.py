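"""Sparse/dense candidate retrieval, list merging, recall@k."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protolink.encoding import toy_encoder
from protolink.stopwords import ENGLISH_STOP_WORDS
from protolink.kb import EntityRecord, build_synonym_index
from protolink.retrieval import (
    CandidateList,
    DenseSynonymIndex,
    SparseVectorizer,
    dense_retrieve,
    fit_sparse,
    merge_candidate_lists,
    recall_at_k,
    retrieve_candidates,
    score_synonyms,
    write_candidates_tsv,
    read_candidates_tsv,
)


def tfidf_oracle(corpus, queries, analyzer):
    """Independent dense tf-idf cosine: smoothed idf ln((1+N)/(1+df))+1,
    raw counts, L2 rows; cosine by explicit dot product."""
    vocab = sorted({t for doc in corpus for t in analyzer(doc)})
    col = {t: j for j, t in enumerate(vocab)}
    N = len(corpus)

    def counts(text):
        row = np.zeros(len(vocab))
        for t in analyzer(text):
            if t in col:
                row[col[t]] += 1
        return row

    X = np.stack([counts(doc) for doc in corpus])
    df = (X > 0).sum(axis=0)
    idf = np.log((1 + N) / (1 + df)) + 1
    def normalize(M):
        norms = np.linalg.norm(M, axis=1, keepdims=True)
        norms[norms == 0] = 1
        return M / norms
    Xn = normalize(X * idf)
    Q = normalize(np.stack([counts(q) for q in queries]) * idf)
    return Q @ Xn.T


def char_ngrams(text, lo=2, hi=5):
    text = text.lower()
    return [text[i : i + n] for n in range(lo, hi + 1) for i in range(len(text) - n + 1)]


class TestSparseVectorizer:
    def test_char_vocabulary_enumerates_ngrams(self):
        vec = fit_sparse(["abc"], mode="char_ngram")
        assert set(vec.vocabulary) == {"ab", "bc", "abc"}

    def test_word_mode_splits_on_non_alphanumeric_and_drops_stopwords(self):
        vec = fit_sparse(["heart-attack risk", "the fever"], mode="word_unigram")
        assert set(vec.vocabulary) == {"heart", "attack", "risk", "fever"}

    def test_out_of_vocabulary_transforms_to_zero_vector(self):
        vec = fit_sparse(["abc"], mode="char_ngram")
        assert vec.transform(["zzzzzz"]).nnz == 0

    def test_empty_corpus_fatal(self):
        with pytest.raises(ValueError):
            fit_sparse([], mode="char_ngram")

    def test_identical_string_scores_one(self, tiny_index):
        vec = fit_sparse(tiny_index.synonyms, mode="char_ngram")
        matrix = vec.transform(tiny_index.synonyms)
        scores = score_synonyms("aspirin", vec, matrix)
        assert scores[tiny_index.synonyms.index("aspirin")] == pytest.approx(1.0)

    def test_disjoint_ngrams_score_zero(self, tiny_index):
        vec = fit_sparse(tiny_index.synonyms, mode="char_ngram")
        matrix = vec.transform(tiny_index.synonyms)
        assert np.all(score_synonyms("zzzz", vec, matrix) == 0)

    @pytest.mark.parametrize("mode,analyzer", [
        ("char_ngram", char_ngrams),
        ("word_unigram", lambda t: [w for w in re.findall(r"[0-9a-z]+", t.lower())
                                    if w not in ENGLISH_STOP_WORDS]),
    ])
    def test_scores_match_dense_bruteforce_oracle(self, mode, analyzer, tiny_index):
        synonyms = tiny_index.synonyms
        vec = fit_sparse(synonyms, mode=mode)
        matrix = vec.transform(synonyms)
        queries = ["cold", "acetylsalicylic", "common chills", "aspirin tablet"]
        expected = tfidf_oracle(synonyms, queries, analyzer)
        for qi, q in enumerate(queries):
            got = score_synonyms(q, vec, matrix)
            assert np.allclose(got, expected[qi], atol=1e-9)

    def test_save_load_round_trip(self, tmp_path, tiny_index):
        vec = fit_sparse(tiny_index.synonyms, mode="char_ngram")
        vec.save(tmp_path / "v.json")
        loaded = SparseVectorizer.load(tmp_path / "v.json")
        q = ["cold drink"]
        assert np.allclose(vec.transform(q).toarray(), loaded.transform(q).toarray())


class TestRetrieveCandidates:
    def test_shared_synonym_appends_both_entities_lexicographically(self, tiny_index):
        scores = np.array([1.0 if s == "cold" else 0.0 for s in tiny_index.synonyms])
        cl = retrieve_candidates("m1", tiny_index, scores, k=2)
        assert cl.entity_ids == ["C01", "C02"]

    def test_k_larger_than_kb_returns_all(self, tiny_index):
        scores = np.linspace(1, 0.1, len(tiny_index.synonyms))
        cl = retrieve_candidates("m1", tiny_index, scores, k=50)
        assert sorted(cl.entity_ids) == ["C01", "C02", "C03"]

    def test_candidate_order_matches_hand_trace(self):
        kb = [
            EntityRecord("E1", "t", ["alpha"]),
            EntityRecord("E2", "t", ["beta", "gamma"]),
            EntityRecord("E3", "t", ["delta"]),
            EntityRecord("E4", "t", ["epsilon"]),
        ]
        index = build_synonym_index(kb)
        # synonyms sorted: alpha beta delta epsilon gamma
        scores = np.array([0.2, 0.9, 0.5, 0.1, 0.9])
        # visit order: beta(.9) gamma(.9, tie broken by string) delta(.5) alpha(.2) epsilon(.1)
        cl = retrieve_candidates("m1", index, scores, k=3)
        assert cl.entity_ids == ["E2", "E3", "E1"]

    def test_no_duplicate_entities_and_length_bounded(self, tiny_index, rng):
        for _ in range(20):
            scores = rng.random(len(tiny_index.synonyms))
            for k in (1, 2, 3, 10):
                cl = retrieve_candidates("m", tiny_index, scores, k)
                assert len(set(cl.entity_ids)) == len(cl.entity_ids)
                assert len(cl.candidates) <= k

    def test_k_below_one_rejected(self, tiny_index):
        with pytest.raises(ValueError):
            retrieve_candidates("m", tiny_index, np.zeros(len(tiny_index.synonyms)), k=0)


class TestDenseRetrieve:
    def test_identical_unique_synonym_ranks_first(self, tiny_index):
        enc = toy_encoder(d=16, seed=0)
        dense = DenseSynonymIndex(tiny_index, enc, max_tokens=50)
        cl = dense_retrieve("m", "acetylsalicylic acid", dense, k=1)
        assert cl.entity_ids == ["C03"]

    def test_matches_bruteforce_cosine_scan(self, tiny_index):
        enc = toy_encoder(d=16, seed=0)
        dense = DenseSynonymIndex(tiny_index, enc, max_tokens=50)
        query = "cold sensation"
        scores = dense.score(query)
        q = enc.embed_text(query, max_tokens=50)
        expected = []
        for s in tiny_index.synonyms:
            v = enc.embed_text(s, max_tokens=50)
            expected.append(float(q @ v / (np.linalg.norm(q) * np.linalg.norm(v))))
        assert np.allclose(scores, expected, atol=1e-9)


class TestMerge:
    def test_round_robin_with_dedup(self):
        a = CandidateList("m", [("e1", 0.9), ("e2", 0.8)], k=2, source="char")
        b = CandidateList("m", [("e2", 0.7), ("e3", 0.6)], k=2, source="word")
        merged = merge_candidate_lists([a, b], k=3)
        assert merged.entity_ids == ["e1", "e2", "e3"]

    def test_merging_with_itself_is_identity(self):
        a = CandidateList("m", [("e1", 0.9), ("e2", 0.8)], k=2, source="char")
        assert merge_candidate_lists([a, a], k=2).entity_ids == a.entity_ids

    def test_empty_list_merges_to_other_truncated(self):
        a = CandidateList("m", [], k=3, source="char")
        b = CandidateList("m", [("e1", 0.5), ("e2", 0.4), ("e3", 0.3)], k=3, source="word")
        assert merge_candidate_lists([a, b], k=2).entity_ids == ["e1", "e2"]


class TestRecallAtK:
    def test_gold_always_first_gives_one(self):
        lists = [CandidateList(f"m{i}", [("g", 1.0)], k=1) for i in range(4)]
        assert recall_at_k(lists, ["g"] * 4, 1) == 1.0

    def test_hand_counted_fraction(self):
        lists = [
            CandidateList("m0", [("g", 1.0), ("x", 0.5)], k=2),
            CandidateList("m1", [("x", 1.0), ("g", 0.5)], k=2),
            CandidateList("m2", [("x", 1.0), ("y", 0.5)], k=2),
            CandidateList("m3", [("g", 1.0)], k=2),
        ]
        assert recall_at_k(lists, ["g"] * 4, 2) == 0.75

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_k(self, data):
        n = data.draw(st.integers(1, 8))
        lists, gold = [], []
        for i in range(n):
            ids = data.draw(
                st.lists(st.sampled_from([f"e{j}" for j in range(10)]), min_size=1,
                         max_size=6, unique=True)
            )
            lists.append(CandidateList(f"m{i}", [(e, 1.0) for e in ids], k=6))
            gold.append(data.draw(st.sampled_from([f"e{j}" for j in range(10)])))
        values = [recall_at_k(lists, gold, k) for k in range(1, 7)]
        assert all(a <= b for a, b in zip(values, values[1:]))


def test_candidates_tsv_round_trip(tmp_path):
    lists = [
        CandidateList("m0", [("e1", 0.5), ("e2", 0.25)], k=2, source="merged"),
        CandidateList("m1", [("e3", 1.0)], k=2, source="merged"),
    ]
    path = tmp_path / "cand.tsv"
    write_candidates_tsv(lists, path)
    loaded = read_candidates_tsv(path)
    assert loaded["m0"].entity_ids == ["e1", "e2"]
    assert loaded["m1"].candidates == [("e3", 1.0)]
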