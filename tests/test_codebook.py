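"""RAKE, similarity labeling and fixed-point codebook expansion."""

from collections import Counter

import numpy as np
import pytest

from ipts_text.codebook import (Codebook, NearestPhraseVetting, iterate_to_fixed_point,
                                label_by_similarity, load_seed_codebooks, rake_extract,
                                reject_all, similarity_to_codebook)
from ipts_text.embed import cosine_similarity

STOPS = frozenset({"the", "a", "and", "of", "is", "in", "very"})


def brute_force_rake(texts, stopwords, max_len):
    """Independent oracle: literal degree/frequency arithmetic."""
    phrases = []
    for text in texts:
        token_runs, run = [], []
        for ch_run in "".join(c if c.isalnum() or c in "' " else "|" for c in text.lower()).split("|"):
            for tok in ch_run.split():
                if tok in stopwords:
                    if run:
                        token_runs.append(tuple(run[:max_len]))
                        run = []
                else:
                    run.append(tok)
            if run:
                token_runs.append(tuple(run[:max_len]))
                run = []
        phrases.extend(token_runs)
    freq, deg = Counter(), Counter()
    for ph in phrases:
        for w in ph:
            freq[w] += 1
            deg[w] += len(ph)
    return {ph: sum(deg[w] / freq[w] for w in ph) for ph in set(phrases)}, Counter(phrases)


class TestRake:
    def test_isolated_word_scores_one(self):
        [sp] = rake_extract(["pain"], STOPS, min_freq=1)
        assert sp.phrase == "pain" and sp.rake_score == 1.0

    def test_two_word_phrase_scores_four(self):
        [sp] = rake_extract(["physical pain"], STOPS, min_freq=1)
        assert sp.phrase == "physical pain" and sp.rake_score == 4.0

    def test_matches_brute_force_oracle(self):
        texts = ["deep physical pain", "physical pain", "the pain is deep and very real"]
        result = {sp.phrase: sp.rake_score for sp in rake_extract(texts, STOPS, min_freq=1)}
        oracle_scores, oracle_freq = brute_force_rake(texts, STOPS, max_len=4)
        assert result == {" ".join(ph): s for ph, s in oracle_scores.items()}
        freqs = {sp.phrase: sp.frequency for sp in rake_extract(texts, STOPS, min_freq=1)}
        assert freqs == {" ".join(ph): c for ph, c in oracle_freq.items()}

    def test_min_freq_filter_and_ordering(self):
        texts = ["alpha beta", "alpha beta", "gamma"]
        out = rake_extract(texts, STOPS, min_freq=2)
        assert [sp.phrase for sp in out] == ["alpha beta"]
        scored = rake_extract(texts, STOPS, min_freq=1)
        assert sorted(scored, key=lambda s: (-s.rake_score, s.phrase)) == scored

    def test_max_phrase_len_truncates(self):
        out = rake_extract(["one two three four five six"], STOPS, max_phrase_len=4, min_freq=1)
        assert out[0].phrase == "one two three four"


class TestSimilarityToCodebook:
    def test_identical_phrase_max_is_one(self, hashed_embedder):
        v = hashed_embedder.embed("physical pain")
        book = hashed_embedder.embed_texts(["physical pain", "other words"])
        assert similarity_to_codebook(v, book, "max") == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        v = np.array([1.0, 0.0, 0.0])
        book = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        assert similarity_to_codebook(v, book) == 0.0

    def test_max_and_mean_aggregators(self):
        # phrase vectors engineered to cosines (0.2, 0.7, 0.4) against the post
        post = np.array([1.0, 0.0])
        book = np.array([[c, np.sqrt(1 - c * c)] for c in (0.2, 0.7, 0.4)])
        assert similarity_to_codebook(post, book, "max") == pytest.approx(0.7)
        assert similarity_to_codebook(post, book, "mean") == pytest.approx(0.43333, abs=1e-4)

    def test_empty_codebook_raises(self):
        with pytest.raises(ValueError, match="empty codebook"):
            similarity_to_codebook(np.ones(2), np.empty((0, 2)))


class TestLabelBySimilarity:
    def test_strict_threshold_boundary(self, stub_embedder_factory):
        # engineered cosines 0.61, 0.60, 0.59 against the single codebook phrase
        mapping = {"seed": np.array([1.0, 0.0])}
        for name, c in (("hi", 0.61), ("edge", 0.60), ("lo", 0.59)):
            mapping[name] = np.array([c, np.sqrt(1 - c * c)])
        emb = stub_embedder_factory(mapping)
        labeled, scores = label_by_similarity(
            {"hi": "hi", "edge": "edge", "lo": "lo"},
            Codebook("d", ["seed"]), emb, threshold=0.60)
        assert labeled == {"hi"}
        assert scores["edge"] == pytest.approx(0.60)

    def test_threshold_zero_labels_all_positive_similarity(self, hashed_embedder):
        texts = {"a": "physical pain today", "b": "unrelated words entirely"}
        labeled, _ = label_by_similarity(texts, Codebook("d", ["physical pain"]),
                                         hashed_embedder, threshold=0.0)
        assert "a" in labeled

    def test_agrees_with_brute_force_oracle(self, hashed_embedder):
        rng = np.random.default_rng(0)
        vocab = ["river", "garden", "pain", "physical", "window", "coffee"]
        texts = {f"p{i}": " ".join(rng.choice(vocab, size=rng.integers(1, 6)))
                 for i in range(100)}
        book = Codebook("d", ["physical pain", "river garden"])
        labeled, scores = label_by_similarity(texts, book, hashed_embedder, 0.6)
        phrase_vecs = [hashed_embedder.embed(p) for p in book.phrases]
        for pid, text in texts.items():
            v = hashed_embedder.embed(text)
            oracle = max(cosine_similarity(v, pv) for pv in phrase_vecs)
            assert scores[pid] == pytest.approx(oracle, abs=1e-12)
            assert (pid in labeled) == (oracle > 0.6)


class TestIterateToFixedPoint:
    def make_candidates(self):
        return {
            "seeded1": "physical pain, physical pain, coffee garden",
            "seeded2": "physical pain, physical pain, river window",
            # bridge posts carry both the seed and a paraphrase
            "bridge1": "physical pain, physical pain, burning pain",
            "bridge2": "physical pain, physical pain, burning pain, coffee",
            # reachable only after the paraphrase joins the codebook
            "para1": "burning pain, burning pain, garden window",
            "para2": "burning pain, burning pain, river coffee",
            "noise": "coffee garden river window morning",
        }

    def test_reject_all_vetting_terminates_with_seeds(self, hashed_embedder):
        seed = Codebook("cap", ["physical pain"])
        result = iterate_to_fixed_point(self.make_candidates(), seed, hashed_embedder,
                                        vetting=reject_all)
        assert result.iterations == 1
        assert result.converged
        assert result.codebook.phrases == ["physical pain"]

    def test_expansion_grows_labeled_set(self, hashed_embedder):
        candidates = self.make_candidates()
        seed = Codebook("cap", ["physical pain"])
        first_pass, _ = label_by_similarity(candidates, seed, hashed_embedder, 0.6)
        result = iterate_to_fixed_point(candidates, seed, hashed_embedder, 0.6,
                                        NearestPhraseVetting(0.3))
        assert result.converged
        assert "burning pain" in result.codebook
        assert result.labeled > first_pass
        assert {"para1", "para2"} <= result.labeled
        assert "noise" not in result.labeled

    def test_codebook_growth_is_monotone_and_seeds_retained(self, hashed_embedder):
        seed = Codebook("cap", ["physical pain"])
        result = iterate_to_fixed_point(self.make_candidates(), seed, hashed_embedder,
                                        0.6, NearestPhraseVetting(0.3))
        sizes = [1]
        for entry in result.codebook.iteration_log:
            sizes.append(sizes[-1] + len(entry["added"]))
        assert sizes == sorted(sizes)
        assert "physical pain" in result.codebook

    def test_deterministic_iteration_log(self, hashed_embedder):
        seed = Codebook("cap", ["physical pain"])
        r1 = iterate_to_fixed_point(self.make_candidates(), seed, hashed_embedder,
                                    0.6, NearestPhraseVetting(0.3))
        r2 = iterate_to_fixed_point(self.make_candidates(), seed, hashed_embedder,
                                    0.6, NearestPhraseVetting(0.3))
        assert r1.codebook.iteration_log == r2.codebook.iteration_log
        assert r1.labeled == r2.labeled

    def test_empty_seed_codebook_rejected(self, hashed_embedder):
        with pytest.raises(ValueError, match="nonempty"):
            iterate_to_fixed_point({}, Codebook("d", []), hashed_embedder)


class TestSeedCodebooks:
    def test_shipped_codebooks_cover_all_dimensions(self):
        books = load_seed_codebooks()
        assert set(books) == {"loneliness", "lack_love", "self_hate", "liability",
                              "capability"}
        assert all(len(cb) > 0 for cb in books.values())

    def test_case_folded_uniqueness(self):
        cb = Codebook("d", ["Pain", "pain", "PAIN", "ache"])
        assert cb.phrases == ["Pain", "ache"]
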