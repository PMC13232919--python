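"""Topic stage: clustering, c-TF-IDF, MMR, coherence, k selection, outliers."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ipts_text.embed import HashedEmbedder
from ipts_text.synth import gen_themed_corpus
from ipts_text.topics import (assign_outliers, class_tfidf, cluster_documents,
                              fit_topic_model, mmr_keywords, select_k, spherical_kmeans,
                              topic_coherence, topic_ipts_prevalence)

EMB = HashedEmbedder(1024)


class TestClustering:
    def test_two_separated_clusters_recovered(self):
        docs = (["river forest mountain hiking trail"] * 10
                + ["oven recipe dinner kitchen spoon"] * 10)
        labels = cluster_documents(EMB.embed_texts(docs), k=2, seed=0)
        assert adjusted_rand_score([0] * 10 + [1] * 10, labels) == 1.0

    def test_k_one_single_topic(self):
        docs = ["alpha beta", "gamma delta", "epsilon zeta"]
        labels = cluster_documents(EMB.embed_texts(docs), k=1, seed=0)
        assert set(labels) == {0}

    def test_deterministic(self):
        docs, _ = gen_themed_corpus(n_themes=3, docs_per_theme=15, seed=2)
        X = EMB.embed_texts(docs)
        np.testing.assert_array_equal(cluster_documents(X, 3, seed=7),
                                      cluster_documents(X, 3, seed=7))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            spherical_kmeans(np.eye(3), k=4)

    def test_centroids_unit_norm(self):
        docs, _ = gen_themed_corpus(n_themes=2, docs_per_theme=10, seed=0)
        _, centroids = spherical_kmeans(EMB.embed_texts(docs), 2, seed=0)
        np.testing.assert_allclose(np.linalg.norm(centroids, axis=1), 1.0)


class TestClassTfidf:
    def test_exclusive_term_weighted_only_in_its_topic(self):
        docs = ["quartz quartz shale", "shale basalt basalt"]
        vocab, weights = class_tfidf([0, 1], docs, reduce_frequent=False)
        i = vocab.index("quartz")
        assert weights[0, i] > 0 and weights[1, i] == 0

    def test_identical_documents_symmetric_rows(self):
        docs = ["copper zinc tin", "copper zinc tin"]
        _, weights = class_tfidf([0, 1], docs)
        np.testing.assert_allclose(weights[0], weights[1])

    def test_matches_hand_computed_values(self):
        # topic 0: "ash oak oak"; topic 1: "ash elm"
        docs = ["ash oak oak", "ash elm"]
        vocab, weights = class_tfidf([0, 1], docs, reduce_frequent=True)
        a_mean = (3 + 2) / 2  # mean tokens per class
        expect = {
            (0, "ash"): math.sqrt(1) * math.log1p(a_mean / 2),
            (0, "oak"): math.sqrt(2) * math.log1p(a_mean / 2),
            (0, "elm"): 0.0,
            (1, "ash"): math.sqrt(1) * math.log1p(a_mean / 2),
            (1, "elm"): math.sqrt(1) * math.log1p(a_mean / 1),
        }
        for (row, term), value in expect.items():
            assert weights[row, vocab.index(term)] == pytest.approx(value)

    def test_outlier_documents_excluded(self):
        docs = ["gold silver", "gold silver", "platinum platinum"]
        vocab, weights = class_tfidf([0, 0, -1], docs)
        assert "platinum" not in vocab


class TestMMR:
    def test_diversity_zero_reduces_to_weight_sort(self):
        vocab = ["a", "b", "c"]
        weights = np.array([1.0, 3.0, 2.0])
        vectors = np.eye(3)
        assert mmr_keywords(weights, vocab, vectors, top_n=3, diversity=0.0) == ["b", "c", "a"]

    def test_duplicate_vector_skipped_for_distinct_term(self):
        vocab = ["first", "twin", "other"]
        # hand trace at diversity 0.2: twin scores .8*2.9 - .2*1 = 2.12,
        # other scores .8*2.8 - 0 = 2.24 -> the duplicate is skipped
        weights = np.array([3.0, 2.9, 2.8])
        vectors = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])  # twin == first
        picked = mmr_keywords(weights, vocab, vectors, top_n=2, diversity=0.2)
        assert picked == ["first", "other"]

    def test_top_n_one_is_max_weight_term(self):
        vocab = ["x", "y"]
        assert mmr_keywords(np.array([0.5, 2.0]), vocab, np.eye(2), top_n=1) == ["y"]

    def test_top_n_beyond_vocabulary_returns_all(self):
        vocab = ["x", "y"]
        out = mmr_keywords(np.array([1.0, 2.0]), vocab, np.eye(2), top_n=10)
        assert sorted(out) == ["x", "y"]


class TestCoherence:
    def test_perfect_cooccurrence_is_one(self):
        docs = ["sun moon", "sun moon", "sun moon star"]
        overall, per_topic = topic_coherence([["sun", "moon"]], docs, top_m=2)
        assert overall == pytest.approx(1.0)

    def test_never_cooccurring_tends_to_minus_one(self):
        docs = ["sun", "moon", "sun", "moon"]
        overall, _ = topic_coherence([["sun", "moon"]], docs, top_m=2)
        assert overall == pytest.approx(-1.0, abs=1e-6)

    def test_matches_brute_force_npmi(self):
        docs = ["ant bee cat", "ant bee", "cat dog", "ant dog"]
        keywords = ["ant", "bee", "cat"]
        overall, _ = topic_coherence([keywords], docs, top_m=3)
        n = len(docs)
        doc_sets = [set(d.split()) for d in docs]

        def p(*ws):
            return sum(1 for s in doc_sets if all(w in s for w in ws)) / n

        expected = []
        for i in range(3):
            for j in range(i + 1, 3):
                p12 = max(p(keywords[i], keywords[j]), 1e-12)
                expected.append(math.log(p12 / (p(keywords[i]) * p(keywords[j])))
                                / -math.log(p12))
        assert overall == pytest.approx(float(np.mean(expected)))

    def test_absent_keyword_skipped(self):
        overall, per_topic = topic_coherence([["sun", "phantom"]], ["sun sun"], top_m=2)
        assert per_topic == [0.0]  # no scorable pair left

    def test_top_m_must_be_at_least_two(self):
        with pytest.raises(ValueError):
            topic_coherence([["a", "b"]], ["a b"], top_m=1)


class TestSelectK:
    def test_recovers_six_planted_themes(self):
        docs, labels = gen_themed_corpus(n_themes=6, docs_per_theme=60, seed=0)
        result = select_k(EMB.embed_texts(docs), docs, range(5, 15), seed=0)
        assert result.k == 6
        assert adjusted_rand_score(labels, result.assignments) >= 0.9

    def test_coherence_by_k_has_full_sweep(self):
        docs, _ = gen_themed_corpus(n_themes=3, docs_per_theme=12, seed=1)
        result = select_k(EMB.embed_texts(docs), docs, range(2, 6), seed=1)
        assert sorted(result.coherence_by_k) == [2, 3, 4, 5]

    def test_single_theme_corpus_selects_low_end(self):
        docs, _ = gen_themed_corpus(n_themes=1, docs_per_theme=40, seed=3)
        result = select_k(EMB.embed_texts(docs), docs, range(2, 7), seed=3)
        assert result.k <= 3


class TestOutliers:
    def test_min_similarity_minus_one_keeps_everything(self):
        docs, _ = gen_themed_corpus(n_themes=2, docs_per_theme=10, seed=0)
        X = EMB.embed_texts(docs)
        labels, centroids = spherical_kmeans(X, 2, seed=0)
        updated = assign_outliers(X, centroids, labels, min_similarity=-1.0)
        assert (updated >= 0).all()

    def test_noise_document_sent_to_outlier_topic(self):
        docs, _ = gen_themed_corpus(n_themes=2, docs_per_theme=15, seed=0,
                                    rare_words_per_doc=(0, 0))
        noise = "zzzz qqqq jjjj wwww xxxx"
        X = EMB.embed_texts(docs + [noise])
        labels, centroids = spherical_kmeans(X[:-1], 2, seed=0)
        all_labels = np.append(labels, 0)
        updated = assign_outliers(X, centroids, all_labels, min_similarity=0.3)
        assert updated[-1] == -1
        assert (updated[:-1] >= 0).mean() > 0.9

    def test_min_similarity_one_marks_nearly_all(self):
        docs, _ = gen_themed_corpus(n_themes=2, docs_per_theme=10, seed=0)
        X = EMB.embed_texts(docs)
        labels, centroids = spherical_kmeans(X, 2, seed=0)
        updated = assign_outliers(X, centroids, labels, min_similarity=1.0)
        assert (updated == -1).mean() > 0.9


class TestPrevalence:
    def test_one_hot_when_category_concentrated(self):
        labels = pd.DataFrame({"lethal": [True, True, False]},
                              index=["a", "b", "c"])
        prevalence = topic_ipts_prevalence({"a": 3, "b": 3, "c": 1}, labels)
        assert prevalence.loc["lethal", 3] == 1.0

    def test_empty_category_zero_row_with_warning(self):
        labels = pd.DataFrame({"lethal": [False, False]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="no posts"):
            prevalence = topic_ipts_prevalence({"a": 0, "b": 1}, labels)
        assert (prevalence.loc["lethal"] == 0.0).all()

    def test_matches_hand_count(self):
        labels = pd.DataFrame({
            "loneliness": [True, True, True, False, True],
            "lethal": [False, True, False, False, False],
        }, index=list("abcde"))
        assignments = {"a": 0, "b": 0, "c": 1, "d": 1, "e": -1}
        prevalence = topic_ipts_prevalence(assignments, labels)
        assert prevalence.loc["loneliness", 0] == pytest.approx(2 / 4)
        assert prevalence.loc["loneliness", 1] == pytest.approx(1 / 4)
        assert prevalence.loc["loneliness", -1] == pytest.approx(1 / 4)
        assert prevalence.loc["lethal", 0] == 1.0


def test_whole_stage_deterministic_given_seed():
    docs, _ = gen_themed_corpus(n_themes=3, docs_per_theme=20, seed=4)
    X = EMB.embed_texts(docs)
    r1 = fit_topic_model(X, docs, k=3, seed=9)
    r2 = fit_topic_model(X, docs, k=3, seed=9)
    np.testing.assert_array_equal(r1.assignments, r2.assignments)
    assert r1.topic_keywords == r2.topic_keywords
    assert r1.coherence == r2.coherence
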