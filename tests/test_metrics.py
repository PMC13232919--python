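"""Response metric suite and its comparison statistics."""

import numpy as np
import pandas as pd
import pytest

from ipts_text.metrics import (ResponseRecord, TextStats, bh_adjust, cdi, coleman_liau,
                               compare_modalities, complexity, diversity,
                               kruskal_eta_squared, paired_cohen_d, profile_records,
                               repeatability, register_scorer, score_with_model,
                               semantic_similarity, style_accommodation, verbosity)


class TestVerbosity:
    def test_two_sentences(self):
        assert verbosity("I hear you. Stay safe.") == (5, 2.5)

    def test_empty(self):
        assert verbosity("") == (0, 0.0)

    def test_single_sentence_levels_agree(self):
        words, per_sentence = verbosity("five plain words right here")
        assert words == per_sentence == 5

    def test_trailing_whitespace_and_line_endings_ignored(self):
        assert verbosity("I hear you. Stay safe.\r\n  ") == (5, 2.5)


class TestColemanLiau:
    @pytest.mark.parametrize("L, S, expected", [
        (500.0, 5.0, 12.12),
        (450.0, 10.0, 7.70),
    ])
    def test_formula_on_rates(self, L, S, expected):
        words = 100
        stats = TextStats(letters=int(L), words=words, sentences=int(S))
        assert coleman_liau(stats) == pytest.approx(expected, abs=1e-10)

    def test_full_trace_from_raw_counts(self):
        stats = TextStats(letters=425, words=100, sentences=8)
        assert stats.L == 425 and stats.S == 8
        assert coleman_liau(stats) == pytest.approx(6.822, abs=1e-3)

    def test_zero_words_flagged(self):
        with pytest.raises(ValueError, match="zero words"):
            coleman_liau(TextStats(letters=0, words=0, sentences=0))


class TestRepeatabilityComplexity:
    def test_repeatability_forced_by_definition(self):
        assert repeatability("pain pain pain") == pytest.approx(2 / 3)

    def test_all_distinct_zero(self):
        assert repeatability("one two three") == 0.0

    def test_repeatability_matches_type_token_count(self):
        text = "a b a c b a d e f a"
        tokens = text.split()
        assert repeatability(text) == pytest.approx(1 - len(set(tokens)) / len(tokens))

    def test_complexity_uniform_word_length(self):
        assert complexity("aa bb. cc dd.") == 2.0

    def test_complexity_single_long_word(self):
        assert complexity("understanding") == 13.0

    def test_complexity_mixed_two_sentences(self):
        # sentence means: (2+4)/2 = 3 and (6+2)/2 = 4 -> 3.5
        assert complexity("ab abcd. abcdef ab.") == pytest.approx(3.5)


class TestCDI:
    BASE = {"article": 0.0, "prep": 0.0, "ppron": 0.0, "ipron": 0.0,
            "auxverb": 0.0, "conj": 0.0, "adverb": 0.0, "negate": 0.0}

    def test_positive_when_only_categorical_mass(self):
        props = dict(self.BASE, article=0.1, prep=0.1)
        assert cdi(props) > 0

    def test_zero_on_symmetric_mass(self):
        props = dict(self.BASE, article=0.2, ppron=0.2)
        assert cdi(props) == pytest.approx(0.0)

    def test_monotone_decreasing_in_adverbs(self):
        values = []
        for adverb in (0.0, 0.05, 0.1, 0.2):
            values.append(cdi(dict(self.BASE, article=0.2, adverb=adverb)))
        assert values == sorted(values, reverse=True)
        assert len(set(values)) == len(values)

    def test_missing_category_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            cdi({"article": 0.1})


class TestSimilarityMetrics:
    def test_verbatim_response_full_similarity(self):
        assert semantic_similarity("the same words", "the same words") == pytest.approx(1.0)

    def test_disjoint_vocabulary_zero(self):
        assert semantic_similarity("alpha beta", "gamma delta") == pytest.approx(0.0)

    def test_template_copy_beats_unrelated(self):
        post = "my garden flooded after the storm"
        assert (semantic_similarity(post, "I hear you about the garden and the storm")
                > semantic_similarity(post, "totally unrelated reply text"))

    def test_style_accommodation_identical_texts(self, fixture_lexicon):
        text = "i don't think the garden is mine"
        assert style_accommodation(text, text, fixture_lexicon) == pytest.approx(1.0)

    def test_style_accommodation_disjoint_categories(self, fixture_lexicon):
        assert style_accommodation("the a an", "not never no",
                                   fixture_lexicon) == pytest.approx(0.0)

    def test_style_accommodation_zero_profile_flagged(self, fixture_lexicon):
        with pytest.warns(UserWarning, match="zero function-word"):
            assert style_accommodation("garden window", "the a an", fixture_lexicon) == 0.0

    def test_style_accommodation_two_category_hand_cosine(self, fixture_lexicon):
        # post: 1 article + 1 negation of 2 tokens -> (.5, .5); response: all articles
        value = style_accommodation("the not", "a an the", fixture_lexicon,
                                    categories=("article", "negate"))
        assert value == pytest.approx(1 / np.sqrt(2))


class TestDiversity:
    def test_identical_responses_zero(self):
        distances, mean = diversity(["same text here"] * 4)
        np.testing.assert_allclose(distances, 0.0, atol=1e-12)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_one_hot_closed_form(self, stub_embedder_factory):
        emb = stub_embedder_factory({"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])})
        distances, mean = diversity(["a", "b"], emb)
        np.testing.assert_allclose(distances, 1 - 1 / np.sqrt(2), atol=1e-12)

    def test_template_pool_less_diverse_than_varied_pool(self):
        template = [f"I hear you about {w}." for w in ("rivers", "gardens", "storms")]
        varied = ["honestly my winter was the worst time",
                  "talking to my sister helped a lot",
                  "the hospital visit changed everything for me"]
        _, mean_template = diversity(template)
        _, mean_varied = diversity(varied)
        assert mean_template < mean_varied

    def test_input_validation(self):
        with pytest.raises(ValueError):
            diversity(["only one"])
        with pytest.raises(ValueError, match="empty"):
            diversity(["", ""])


class TestScorers:
    def test_fixture_formality_ordering(self):
        formal = "I would appreciate guidance regarding this matter."
        informal = "idk lol gonna wing it, don't care"
        assert (score_with_model("fixture_formality", formal)
                > score_with_model("fixture_formality", informal))

    def test_bounded_and_deterministic(self):
        for text in ("", "lol " * 50, "measured and calm prose"):
            a = score_with_model("fixture_empathy", text)
            assert 0.0 <= a <= 1.0
            assert a == score_with_model("fixture_empathy", text)

    def test_unregistered_scorer_is_configuration_error(self):
        with pytest.raises(KeyError, match="no scorer registered"):
            score_with_model("roberta-formality", "text")

    def test_registered_scorer_clamped(self):
        register_scorer("loud", lambda text: 7.5)
        assert score_with_model("loud", "anything") == 1.0


class TestComparisonStatistics:
    def test_paired_cohen_d_hand_value(self):
        assert paired_cohen_d(np.array([1.0, 1.0, 4.0])) == pytest.approx(1.1547, abs=1e-4)

    def test_paired_cohen_d_zero_variance_nan(self):
        assert np.isnan(paired_cohen_d(np.array([2.0, 2.0, 2.0])))

    def test_eta_squared_formula(self):
        assert kruskal_eta_squared(4.5714, 3, 6) == pytest.approx(0.8571, abs=1e-3)

    def test_bh_all_adjusted_to_point_04(self):
        adjusted = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adjusted, 0.04)

    def test_bh_monotone_and_at_least_raw(self):
        raw = np.array([0.001, 0.01, 0.2, 0.04, 0.5])
        adjusted = bh_adjust(raw)
        assert (adjusted >= raw - 1e-15).all()
        order = np.argsort(raw)
        assert (np.diff(adjusted[order]) >= -1e-15).all()


class TestCompareModalities:
    def make_profiles(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(40):
            base = rng.normal(10, 2)
            rows.append({"post_id": f"p{i}", "modality": "OC",
                         "verbosity_response": base, "repeatability": 0.1})
            for m in ("AI-1", "AI-2", "AI-3"):
                rows.append({"post_id": f"p{i}", "modality": m,
                             "verbosity_response": base + 5 + rng.normal(0, 0.5),
                             "repeatability": 0.1})
        return pd.DataFrame(rows)

    def test_direction_and_significance(self):
        table = compare_modalities(self.make_profiles(),
                                   metrics=["verbosity_response"])
        row = table.loc["verbosity_response"]
        assert row["direction"] == "AI>OC"
        assert row["p_AI-1"] < 0.001 and row["d_AI-1"] > 1
        assert row["eta_squared"] > 0

    def test_identical_paired_samples_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            table = compare_modalities(self.make_profiles(), metrics=["repeatability"])
        assert np.isnan(table.loc["repeatability", "d_AI-1"])

    def test_adjusted_p_columns_present_and_bounded(self):
        table = compare_modalities(self.make_profiles())
        q_cols = [c for c in table.columns if c.startswith("q_")]
        assert q_cols
        q = table[q_cols].to_numpy()
        assert np.nanmax(q) <= 1.0

    def test_requires_two_modalities(self):
        profiles = self.make_profiles()
        with pytest.raises(ValueError):
            compare_modalities(profiles[profiles["modality"] == "OC"])


def test_profile_records_end_to_end(fixture_lexicon):
    records = [
        ResponseRecord("my garden flooded", "I hear you about the garden.", "AI-1", "p1"),
        ResponseRecord("my garden flooded", "honestly that's rough, idk", "OC", "p1"),
        ResponseRecord("work is exhausting", "I hear you about the work.", "AI-1", "p2"),
        ResponseRecord("work is exhausting", "my winter was worse lol", "OC", "p2"),
    ]
    frame = profile_records(records, fixture_lexicon)
    assert len(frame) == 4
    assert frame["diversity"].notna().all()
    ai = frame[frame["modality"] == "AI-1"]
    oc = frame[frame["modality"] == "OC"]
    assert ai["semantic_similarity"].mean() > oc["semantic_similarity"].mean()
    assert ai["formality"].mean() > oc["formality"].mean()
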