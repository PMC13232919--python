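"""Lexico-semantic metrics for supportive responses and their statistics.

Implements the response-quality suite used to compare community (OC)
responses with automated (AI-1/2/3) responses: verbosity at response and
sentence level, Coleman-Liau readability, repeatability (word reuse),
complexity (mean word length per sentence), the categorical-dynamic index,
formality/empathy through pluggable scorer contracts, post-response
semantic similarity, function-word style accommodation, and pool
diversity. The comparison table reports paired t tests with paired Cohen
d against OC, a Kruskal-Wallis H across all modalities with eta-squared,
and Benjamini-Hochberg adjustment across the whole family of tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._text import split_sentences, whitespace_count, word_tokens
from .embed import Embedder, HashedEmbedder, cosine_similarity
from .lexicon import CategoryLexicon, category_proportions, kruskal_wallis

MODALITIES = ("OC", "AI-1", "AI-2", "AI-3")

FUNCTION_CATEGORIES = ("article", "prep", "ppron", "ipron", "auxverb",
                       "conj", "adverb", "negate")
CDI_CATEGORICAL = ("article", "prep")
CDI_DYNAMIC = ("ppron", "ipron", "auxverb", "conj", "adverb", "negate")


@dataclass(frozen=True)
class ResponseRecord:
    post_text: str
    response_text: str
    modality: str
    post_id: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")


@dataclass(frozen=True)
class TextStats:
    letters: int
    words: int
    sentences: int

    @property
    def L(self) -> float:
        """Letters per 100 words."""
        return 100.0 * self.letters / self.words

    @property
    def S(self) -> float:
        """Sentences per 100 words."""
        return 100.0 * self.sentences / self.words


def text_stats(text: str) -> TextStats:
    return TextStats(
        letters=sum(1 for ch in text if ch.isalpha()),
        words=whitespace_count(text),
        sentences=len(split_sentences(text)),
    )


def verbosity(text: str) -> tuple[int, float]:
    """(words per response, mean words per sentence); empty text -> (0, 0)."""
    words = whitespace_count(text)
    if words == 0:
        return 0, 0.0
    sentences = split_sentences(text) or [text]
    return words, float(np.mean([whitespace_count(s) for s in sentences]))


def coleman_liau(stats_or_text: TextStats | str) -> float:
    """CLI = 0.0588 L - 0.296 S - 15.8 (L, S per 100 words)."""
    st = text_stats(stats_or_text) if isinstance(stats_or_text, str) else stats_or_text
    if st.words == 0:
        raise ValueError("Coleman-Liau undefined for zero words")
    return 0.0588 * st.L - 0.296 * st.S - 15.8


def repeatability(text: str) -> float:
    """Word-reuse rate: 1 - distinct/total tokens; empty -> 0."""
    tokens = word_tokens(text)
    if not tokens:
        return 0.0
    return 1.0 - len(set(tokens)) / len(tokens)


def complexity(text: str) -> float:
    """Mean word length per sentence, averaged over sentences; empty -> 0."""
    sentences = split_sentences(text)
    per_sentence = []
    for s in sentences:
        toks = word_tokens(s)
        if toks:
            per_sentence.append(float(np.mean([len(t) for t in toks])))
    return float(np.mean(per_sentence)) if per_sentence else 0.0


def cdi(proportions: Mapping[str, float], scale: float = 100.0,
        offset: float = 0.0) -> float:
    """Categorical-dynamic index from function-word category proportions.

    (articles + prepositions) minus (personal + impersonal pronouns +
    auxiliary verbs + conjunctions + adverbs + negations), scaled; higher
    is a more categorical/analytic style, lower a more dynamic/narrative
    one. Offset and scale are configuration, not theory.
    """
    missing = [c for c in CDI_CATEGORICAL + CDI_DYNAMIC if c not in proportions]
    if missing:
        raise ValueError(f"missing required category proportion(s): {missing}")
    categorical = sum(proportions[c] for c in CDI_CATEGORICAL)
    dynamic = sum(proportions[c] for c in CDI_DYNAMIC)
    return offset + scale * (categorical - dynamic)


def semantic_similarity(post: str, response: str,
                        embedder: Embedder | None = None) -> float:
    embedder = embedder or HashedEmbedder()
    return cosine_similarity(embedder.embed(post), embedder.embed(response))


def style_accommodation(post: str, response: str, lexicon: CategoryLexicon,
                        categories: Sequence[str] = FUNCTION_CATEGORIES) -> float:
    """Cosine of the two texts' function-word category profiles; 0 if a
    profile is empty (flagged by warning)."""
    pp = category_proportions(post, lexicon)
    rp = category_proportions(response, lexicon)
    u = np.array([pp.get(c, 0.0) for c in categories])
    v = np.array([rp.get(c, 0.0) for c in categories])
    if not u.any() or not v.any():
        warnings.warn("zero function-word profile; style accommodation set to 0",
                      stacklevel=2)
        return 0.0
    return cosine_similarity(u, v)


def diversity(responses: Sequence[str],
              embedder: Embedder | None = None) -> tuple[np.ndarray, float]:
    """Cosine distance of each response from the pool centroid, plus mean."""
    if len(responses) < 2:
        raise ValueError("diversity needs at least two responses")
    embedder = embedder or HashedEmbedder()
    vectors = embedder.embed_texts(responses)
    if not np.any(np.linalg.norm(vectors, axis=1) > 0):
        raise ValueError("all responses are empty")
    centroid = vectors.mean(axis=0)
    distances = np.array([max(0.0, 1.0 - cosine_similarity(v, centroid))
                          for v in vectors])
    return distances, float(distances.mean())


# ---------------------------------------------------------------------------
# Pluggable scorers (formality / empathy)

ScorerFn = Callable[[str], float]
_SCORERS: dict[str, ScorerFn] = {}


def register_scorer(name: str, fn: ScorerFn) -> None:
    _SCORERS[name] = fn


def score_with_model(scorer: str, text: str) -> float:
    """Run a registered scorer; output clamped to [0, 1]."""
    if scorer not in _SCORERS:
        raise KeyError(
            f"no scorer registered under {scorer!r}; available: {sorted(_SCORERS)}")
    return float(np.clip(_SCORERS[scorer](text), 0.0, 1.0))


_INFORMAL_MARKERS = {"lol", "omg", "gonna", "wanna", "gotta", "kinda", "yeah",
                     "nah", "btw", "idk", "can't", "don't", "won't", "isn't",
                     "didn't", "ain't", "u", "ur", "lmao"}
_EMPATHY_MARKERS = {"sorry", "hear", "feel", "feelings", "understand", "imagine",
                    "hard", "difficult", "valid", "care", "support", "hope",
                    "matter", "deserve", "gentle", "safe", "alone", "with"}


def fixture_formality_scorer(text: str) -> float:
    """Deterministic lexicon-ratio formality stand-in: 1 minus the share of
    informal markers among tokens (scaled), so contraction/slang-free text
    scores higher."""
    tokens = word_tokens(text)
    if not tokens:
        return 0.0
    informal = sum(1 for t in tokens if t in _INFORMAL_MARKERS)
    return max(0.0, 1.0 - 5.0 * informal / len(tokens))


def fixture_empathy_scorer(text: str) -> float:
    """Deterministic lexicon-ratio empathy stand-in (share of empathic
    markers, scaled into [0, 1])."""
    tokens = word_tokens(text)
    if not tokens:
        return 0.0
    return min(1.0, 8.0 * sum(1 for t in tokens if t in _EMPATHY_MARKERS) / len(tokens))


register_scorer("fixture_formality", fixture_formality_scorer)
register_scorer("fixture_empathy", fixture_empathy_scorer)


# ---------------------------------------------------------------------------
# Metric profiles and modality comparison


def metric_profile(record: ResponseRecord, lexicon: CategoryLexicon,
                   embedder: Embedder | None = None,
                   formality_scorer: str = "fixture_formality",
                   empathy_scorer: str = "fixture_empathy") -> dict[str, float]:
    """All per-response metrics for one record (diversity is pool-level)."""
    embedder = embedder or HashedEmbedder()
    words, per_sentence = verbosity(record.response_text)
    props = category_proportions(record.response_text, lexicon)
    try:
        cli = coleman_liau(record.response_text)
    except ValueError:
        cli = float("nan")
    return {
        "verbosity_response": float(words),
        "verbosity_sentence": per_sentence,
        "readability_cli": cli,
        "repeatability": repeatability(record.response_text),
        "complexity": complexity(record.response_text),
        "cdi": cdi(props),
        "formality": score_with_model(formality_scorer, record.response_text),
        "empathy": score_with_model(empathy_scorer, record.response_text),
        "semantic_similarity": semantic_similarity(
            record.post_text, record.response_text, embedder),
        "style_accommodation": style_accommodation(
            record.post_text, record.response_text, lexicon),
    }


def profile_records(records: Sequence[ResponseRecord], lexicon: CategoryLexicon,
                    embedder: Embedder | None = None, **scorers) -> pd.DataFrame:
    """Per-record metric table plus within-modality diversity distances."""
    embedder = embedder or HashedEmbedder()
    rows = []
    for rec in records:
        row = {"post_id": rec.post_id, "modality": rec.modality}
        row.update(metric_profile(rec, lexicon, embedder, **scorers))
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame["diversity"] = np.nan
    for modality, sub in frame.groupby("modality"):
        texts = [r.response_text for r in records if r.modality == modality]
        if len(texts) >= 2:
            distances, _ = diversity(texts, embedder)
            frame.loc[sub.index, "diversity"] = distances
    return frame


def paired_cohen_d(differences: np.ndarray) -> float:
    """Cohen d for paired samples: mean(diff) / sd(diff)."""
    differences = np.asarray(differences, dtype=float)
    sd = differences.std(ddof=1)
    if sd == 0.0:
        return float("nan")
    return float(differences.mean() / sd)


def kruskal_eta_squared(h: float, k: int, n: int) -> float:
    """Eta-squared effect size for a Kruskal-Wallis test: (H - k + 1)/(n - k)."""
    if n <= k:
        raise ValueError("need more observations than groups")
    return (h - k + 1) / (n - k)


def compare_modalities(profiles: pd.DataFrame,
                       metrics: Sequence[str] | None = None,
                       reference: str = "OC") -> pd.DataFrame:
    """Modality comparison table mirroring the metric-suite layout.

    For each metric: modality means; paired t and paired Cohen d for every
    AI setting against the reference (paired on post_id); Kruskal-Wallis H
    with eta-squared across all modalities; Benjamini-Hochberg adjustment
    applied jointly to every p in the table; direction from group means.
    """
    present = [m for m in MODALITIES if m in set(profiles["modality"])]
    if len(present) < 2:
        raise ValueError("need at least two modalities to compare")
    if reference not in present:
        raise ValueError(f"reference modality {reference!r} not present")
    if metrics is None:
        metrics = [c for c in profiles.columns
                   if c not in ("post_id", "modality", "group")]

    rows: list[dict] = []
    p_slots: list[tuple[int, str]] = []
    for metric in metrics:
        sub = profiles.pivot_table(index="post_id", columns="modality",
                                   values=metric, aggfunc="first")
        row: dict = {"metric": metric}
        for modality in present:
            vals = profiles.loc[profiles["modality"] == modality, metric].dropna()
            row[f"mean_{modality}"] = float(vals.mean()) if len(vals) else float("nan")
        for modality in present:
            if modality == reference:
                continue
            paired = sub[[reference, modality]].dropna()
            diffs = (paired[modality] - paired[reference]).to_numpy()
            if len(diffs) < 2:
                t = p = d = float("nan")
            else:
                t, p = stats.ttest_rel(paired[modality], paired[reference])
                d = paired_cohen_d(diffs)
                if np.isnan(d):
                    warnings.warn(
                        f"zero-variance paired differences for {metric} "
                        f"({modality} vs {reference}); d undefined", stacklevel=2)
            row[f"t_{modality}"] = float(t)
            row[f"p_{modality}"] = float(p)
            row[f"d_{modality}"] = d
        groups = [profiles.loc[profiles["modality"] == m, metric].dropna().to_numpy()
                  for m in present]
        if all(len(g) for g in groups):
            h, hp = kruskal_wallis(groups)
            n = int(sum(len(g) for g in groups))
            row["H"] = h
            row["p_kw"] = hp
            row["eta_squared"] = kruskal_eta_squared(h, len(present), n)
        ai_means = [row[f"mean_{m}"] for m in present if m != reference]
        ref_mean = row[f"mean_{reference}"]
        if all(np.isfinite(ai_means)) and np.isfinite(ref_mean):
            if all(m > ref_mean for m in ai_means):
                row["direction"] = f"AI>{reference}"
            elif all(m < ref_mean for m in ai_means):
                row["direction"] = f"{reference}>AI"
            else:
                row["direction"] = "mixed"
        rows.append(row)

    table = pd.DataFrame(rows).set_index("metric")
    p_cols = [c for c in table.columns if c.startswith("p_")]
    raw = table[p_cols].to_numpy().ravel()
    mask = np.isfinite(raw)
    adjusted = np.full_like(raw, np.nan)
    if mask.any():
        adjusted[mask] = multipletests(raw[mask], method="fdr_bh")[1]
    adj = pd.DataFrame(adjusted.reshape(table[p_cols].shape),
                       index=table.index,
                       columns=[c.replace("p_", "q_") for c in p_cols])
    return pd.concat([table, adj], axis=1)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (monotone, >= raw)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
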