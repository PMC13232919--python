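"""Composition of dimension scores into risk factors and lethal labels.

Four dimension similarity scores compose pairwise into the first two risk
factors — thwarted belongingness (TB) from loneliness + lack of reciprocal
love, perceived burdensomeness (PB) from self-hate + liability — by simple
averaging of the cosine scores; acquired capability (AC) is scored directly
from its own codebook. A post whose averaged (or direct, for AC) score
strictly exceeds the labeling threshold carries that risk factor; a post
carrying all three is flagged lethally suicidal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .codebook import DEFAULT_SIMILARITY_THRESHOLD

DIMENSIONS = ("loneliness", "lack_love", "self_hate", "liability", "capability")
RISK_FACTOR_COMPOSITION = {
    "thwarted_belongingness": ("loneliness", "lack_love"),
    "perceived_burdensomeness": ("self_hate", "liability"),
}
RISK_FACTORS = ("thwarted_belongingness", "perceived_burdensomeness", "acquired_capability")
CATEGORY_ORDER = (
    "loneliness", "lack_love", "self_hate", "liability",
    "thwarted_belongingness", "perceived_burdensomeness", "acquired_capability",
    "lethal",
)


@dataclass(frozen=True)
class DimensionScores:
    post_id: str
    loneliness: float = 0.0
    lack_love: float = 0.0
    self_hate: float = 0.0
    liability: float = 0.0
    capability: float = 0.0


@dataclass(frozen=True)
class IPTSLabel:
    post_id: str
    loneliness: bool
    lack_love: bool
    self_hate: bool
    liability: bool
    tb_score: float
    pb_score: float
    ac_score: float
    thwarted_belongingness: bool
    perceived_burdensomeness: bool
    acquired_capability: bool
    lethal: bool


def risk_factor_score(s1: float, s2: float) -> float:
    """Average the two constituent dimension similarities."""
    return (s1 + s2) / 2.0


def _coerce(value, name: str, post_id: str) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        warnings.warn(f"missing {name} score for post {post_id}; treating as 0", stacklevel=3)
        return 0.0
    return float(value)


def assign_risk_factors(scores: DimensionScores,
                        threshold: float = DEFAULT_SIMILARITY_THRESHOLD) -> IPTSLabel:
    """Flags from strict '>' comparisons at the shared labeling threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    s = {d: _coerce(getattr(scores, d), d, scores.post_id) for d in DIMENSIONS}
    tb_score = risk_factor_score(s["loneliness"], s["lack_love"])
    pb_score = risk_factor_score(s["self_hate"], s["liability"])
    ac_score = s["capability"]
    tb = tb_score > threshold
    pb = pb_score > threshold
    ac = ac_score > threshold
    return IPTSLabel(
        post_id=scores.post_id,
        loneliness=s["loneliness"] > threshold,
        lack_love=s["lack_love"] > threshold,
        self_hate=s["self_hate"] > threshold,
        liability=s["liability"] > threshold,
        tb_score=tb_score, pb_score=pb_score, ac_score=ac_score,
        thwarted_belongingness=tb, perceived_burdensomeness=pb,
        acquired_capability=ac, lethal=tb and pb and ac,
    )


def scores_frame(score_maps: Mapping[str, Mapping[str, float]],
                 post_ids: Iterable[str]) -> pd.DataFrame:
    """Assemble per-dimension score maps into one table (missing -> 0)."""
    idx = pd.Index(list(post_ids), name="post_id")
    df = pd.DataFrame(index=idx)
    for dim in DIMENSIONS:
        mapping = score_maps.get(dim, {})
        df[dim] = [float(mapping.get(pid, 0.0)) for pid in idx]
    return df


def label_table(scores: pd.DataFrame,
                threshold: float = DEFAULT_SIMILARITY_THRESHOLD) -> pd.DataFrame:
    """Vectorised :func:`assign_risk_factors` over a score table.

    ``scores`` is indexed by post id with one column per dimension.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    missing = [d for d in DIMENSIONS if d not in scores.columns]
    if missing:
        warnings.warn(f"missing score column(s) {missing}; treating as 0", stacklevel=2)
    s = scores.reindex(columns=list(DIMENSIONS)).fillna(0.0)
    out = pd.DataFrame(index=s.index)
    for d in DIMENSIONS:
        out[d] = s[d] > threshold
    out["tb_score"] = (s["loneliness"] + s["lack_love"]) / 2.0
    out["pb_score"] = (s["self_hate"] + s["liability"]) / 2.0
    out["ac_score"] = s["capability"]
    out["thwarted_belongingness"] = out["tb_score"] > threshold
    out["perceived_burdensomeness"] = out["pb_score"] > threshold
    out["acquired_capability"] = out["ac_score"] > threshold
    out["lethal"] = (out["thwarted_belongingness"]
                     & out["perceived_burdensomeness"]
                     & out["acquired_capability"])
    return out


def wilson_interval(count: int, n_total: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a proportion, returned as percent bounds."""
    lo, hi = proportion_confint(count, n_total, alpha=alpha, method="wilson")
    return 100.0 * float(lo), 100.0 * float(hi)


def distribution_from_counts(counts: Mapping[str, int], n_total: int,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Category counts -> percent of corpus with 95% Wilson CI bounds."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    rows = []
    for category, count in counts.items():
        if count > n_total:
            raise ValueError(f"count for {category!r} exceeds n_total")
        pct = 100.0 * count / n_total
        lo, hi = wilson_interval(count, n_total, alpha)
        rows.append({
            "category": category,
            "count": int(count),
            "percent": round(pct, 2),
            "ci_low": round(lo, 2),
            "ci_high": round(hi, 2),
        })
    return pd.DataFrame(rows)


def distribution_table(labels: pd.DataFrame, n_total: int | None = None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Distribution of posts across dimensions, risk factors and lethal.

    ``labels`` is a flag table as produced by :func:`label_table`.
    """
    if n_total is None:
        n_total = len(labels)
    counts = {cat: int(labels[cat].sum()) for cat in CATEGORY_ORDER if cat in labels.columns}
    return distribution_from_counts(counts, n_total, alpha)
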