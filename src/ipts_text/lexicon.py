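"""Category-lexicon counting and rank-based group comparison.

Reads the de-facto standard %-delimited ``.dic`` category-lexicon format
(a header of id<->name pairs between two ``%`` lines, then word rows
listing category ids; a trailing ``*`` marks a stem pattern). The analyses
are lexicon-agnostic: a small synthetic open fixture lexicon ships for
tests, and any user-supplied ``.dic`` (including proprietary ones the user
licenses) drops in unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._text import word_tokens

logger = logging.getLogger(__name__)


class DicFormatError(ValueError):
    """Malformed .dic file; message carries the offending line number."""


@dataclass
class CategoryLexicon:
    """Map of category -> literal words and trailing-wildcard stems."""

    words: dict[str, set[str]] = field(default_factory=dict)
    stems: dict[str, list[str]] = field(default_factory=dict)

    @property
    def categories(self) -> list[str]:
        return sorted(set(self.words) | set(self.stems))

    def add(self, pattern: str, category: str) -> None:
        pattern = pattern.lower()
        if pattern.endswith("*"):
            self.stems.setdefault(category, [])
            stem = pattern[:-1]
            if stem not in self.stems[category]:
                self.stems[category].append(stem)
        else:
            self.words.setdefault(category, set()).add(pattern)
        self.words.setdefault(category, set())
        self.stems.setdefault(category, [])

    def match(self, token: str) -> list[str]:
        """Categories a token belongs to (a word may count in several)."""
        token = token.lower()
        hits = [c for c, ws in self.words.items() if token in ws]
        for c, stems in self.stems.items():
            if c not in hits and any(token.startswith(s) for s in stems):
                hits.append(c)
        return hits


def load_liwc_dic(path: str | Path) -> CategoryLexicon:
    """Parse a %-delimited .dic lexicon."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    lex = CategoryLexicon()
    id_to_name: dict[str, str] = {}
    in_header = False
    header_done = False
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line:
            continue
        if line == "%":
            if not in_header and not header_done:
                in_header = True
            elif in_header:
                in_header = False
                header_done = True
            else:
                raise DicFormatError(f"line {lineno}: unexpected '%'")
            continue
        parts = line.split()
        if in_header:
            if len(parts) != 2 or not parts[0].isdigit():
                raise DicFormatError(
                    f"line {lineno}: header rows must be '<id> <name>', got {line!r}")
            id_to_name[parts[0]] = parts[1]
        else:
            if not header_done:
                raise DicFormatError(f"line {lineno}: word row before '%' header")
            if len(parts) < 2:
                raise DicFormatError(f"line {lineno}: word row without category ids")
            word, ids = parts[0], parts[1:]
            for cid in ids:
                if cid not in id_to_name:
                    raise DicFormatError(f"line {lineno}: unknown category id {cid!r}")
                lex.add(word, id_to_name[cid])
    if not header_done:
        raise DicFormatError("no %-delimited category header found")
    return lex


def load_fixture_lexicon() -> CategoryLexicon:
    """The shipped synthetic open lexicon (function words + a few affect
    categories); suitable for tests and for the CDI / style-accommodation
    metrics, not a substitute for a licensed research lexicon."""
    with resources.as_file(
            resources.files("ipts_text.data") / "synthetic_liwc_fixture.dic") as p:
        return load_liwc_dic(p)


def category_proportions(text: str, lexicon: CategoryLexicon) -> dict[str, float]:
    """Matched tokens / total tokens per category; empty text -> zeros."""
    if not lexicon.categories:
        raise ValueError("empty lexicon")
    tokens = word_tokens(text)
    props = {c: 0.0 for c in lexicon.categories}
    if not tokens:
        return props
    for tok in tokens:
        for c in lexicon.match(tok):
            props[c] += 1.0
    return {c: v / len(tokens) for c, v in props.items()}


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (k-1 df).

    All-identical input, which the underlying routine treats as degenerate,
    is returned as (H=0, p=1).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("each group must be nonempty")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least three observations in total")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise adjusted per-test alpha: alpha / m."""
    if m < 1:
        raise ValueError("m must be at least 1")
    return alpha / m


@dataclass
class GroupTestResult:
    category: str
    group_means: dict[str, float]
    h_statistic: float
    p_value: float
    significant: bool


def compare_groups(group_texts: Mapping[str, Sequence[str]],
                   lexicon: CategoryLexicon,
                   alpha: float = 0.05,
                   categories: Iterable[str] | None = None) -> pd.DataFrame:
    """Normalized category occurrences by group + Kruskal-Wallis per category.

    Significance uses the Bonferroni-adjusted threshold alpha/m, with m the
    number of categories actually tested (logged).
    """
    if len(group_texts) < 2:
        raise ValueError("need at least two groups")
    cats = list(categories) if categories is not None else lexicon.categories
    m = len(cats)
    adjusted = bonferroni_threshold(alpha, m)
    logger.info("compare_groups: m=%d categories, adjusted alpha=%.6g", m, adjusted)

    per_group_props = {
        g: [category_proportions(t, lexicon) for t in texts]
        for g, texts in group_texts.items()
    }
    rows = []
    for cat in cats:
        samples = {g: [p[cat] for p in props] for g, props in per_group_props.items()}
        h, p = kruskal_wallis(list(samples.values()))
        rows.append(GroupTestResult(
            category=cat,
            group_means={g: float(np.mean(v)) for g, v in samples.items()},
            h_statistic=h, p_value=p, significant=p < adjusted))
    frame = pd.DataFrame([
        {"category": r.category, **{f"mean_{g}": v for g, v in r.group_means.items()},
         "H": r.h_statistic, "p": r.p_value, "significant": r.significant}
        for r in rows
    ])
    frame.attrs["m"] = m
    frame.attrs["adjusted_alpha"] = adjusted
    return frame
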