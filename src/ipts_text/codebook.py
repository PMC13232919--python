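"""Iterative codebook-based similarity labeling.

The central procedure: each psychological construct starts from a curated
set of seed phrases; candidate posts are labeled when their embedding is
close enough to a codebook phrase; RAKE pulls key phrases out of labeled
posts; vetted phrases join the codebook; repeat until no phrase is added.
Because phrases are only ever added and the labeling aggregator is a max
over phrases, the labeled set grows monotonically and a fixed point always
exists (the phrase universe extracted from a finite corpus is finite).

Vetting emulates the human-in-the-loop review that keeps theory-aligned
phrases and discards drift: automated policies based on embedding
similarity ship for unattended runs, and a callable hook supports real
interactive review.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import yaml

from ._text import STOPWORDS
from .embed import Embedder, HashedEmbedder, cosine_similarity

logger = logging.getLogger(__name__)

DEFAULT_SIMILARITY_THRESHOLD = 0.60
_WORD_RE = re.compile(r"[a-z0-9']+")


@dataclass(frozen=True)
class ScoredPhrase:
    phrase: str
    rake_score: float
    frequency: int


@dataclass
class Codebook:
    """Ordered, case-folded-unique phrase list for one construct."""

    dimension: str
    phrases: list[str] = field(default_factory=list)
    iteration_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        deduped: list[str] = []
        seen: set[str] = set()
        for p in self.phrases:
            key = p.casefold()
            if key not in seen:
                seen.add(key)
                deduped.append(p)
        self.phrases = deduped

    def __contains__(self, phrase: str) -> bool:
        return phrase.casefold() in {p.casefold() for p in self.phrases}

    def __len__(self) -> int:
        return len(self.phrases)

    def add(self, phrase: str) -> bool:
        if phrase in self:
            return False
        self.phrases.append(phrase)
        return True

    def copy(self) -> "Codebook":
        return Codebook(self.dimension, list(self.phrases), [dict(e) for e in self.iteration_log])


def load_seed_codebooks(path: str | Path | None = None) -> dict[str, Codebook]:
    """Load the shipped seed codebooks (or a user YAML of the same layout)."""
    if path is None:
        text = resources.files("ipts_text.data").joinpath("seed_codebook.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    return {dim: Codebook(dim, list(phrases)) for dim, phrases in raw.items()}


def save_codebooks(codebooks: Mapping[str, Codebook], path: str | Path) -> None:
    data = {dim: list(cb.phrases) for dim, cb in codebooks.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


# ---------------------------------------------------------------------------
# RAKE


def _candidate_runs(text: str, stopwords: frozenset[str] | set[str],
                    max_phrase_len: int) -> list[tuple[str, ...]]:
    """Maximal runs of non-stopword tokens, split at stopwords/punctuation."""
    runs: list[tuple[str, ...]] = []
    for fragment in re.split(r"[^\w'\s]+", text.lower()):
        run: list[str] = []
        for tok in _WORD_RE.findall(fragment):
            if tok in stopwords:
                if run:
                    runs.append(tuple(run[:max_phrase_len]))
                    run = []
            else:
                run.append(tok)
        if run:
            runs.append(tuple(run[:max_phrase_len]))
    return runs


def rake_extract(texts: Iterable[str],
                 stopwords: frozenset[str] | set[str] | None = None,
                 max_phrase_len: int = 4,
                 min_freq: int = 2) -> list[ScoredPhrase]:
    """Rapid automatic keyword extraction over a text collection.

    Word score = degree/frequency on the within-phrase co-occurrence graph
    (degree counts the full length of every phrase a word occurs in, self
    included); a phrase scores the sum of its member word scores. Phrases
    seen fewer than ``min_freq`` times are dropped; ties sort
    lexicographically after score.
    """
    if stopwords is None:
        stopwords = STOPWORDS
    if not stopwords:
        raise ValueError("RAKE requires a nonempty stopword list")

    freq: Counter[str] = Counter()
    degree: Counter[str] = Counter()
    phrase_count: Counter[tuple[str, ...]] = Counter()
    for text in texts:
        for run in _candidate_runs(text, stopwords, max_phrase_len):
            phrase_count[run] += 1
            for w in run:
                freq[w] += 1
                degree[w] += len(run)

    word_score = {w: degree[w] / freq[w] for w in freq}
    out = [
        ScoredPhrase(" ".join(run), sum(word_score[w] for w in run), count)
        for run, count in phrase_count.items()
        if count >= min_freq
    ]
    out.sort(key=lambda sp: (-sp.rake_score, sp.phrase))
    return out


# ---------------------------------------------------------------------------
# Similarity labeling


def _normalize_rows(mat: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return mat / norms


def similarity_to_codebook(post_vector: np.ndarray,
                           codebook_vectors: np.ndarray,
                           aggregator: str = "max") -> float:
    """Aggregated cosine similarity of one post against all codebook phrases."""
    codebook_vectors = np.atleast_2d(np.asarray(codebook_vectors, dtype=np.float64))
    if codebook_vectors.shape[0] == 0:
        raise ValueError("empty codebook")
    sims = [cosine_similarity(post_vector, row) for row in codebook_vectors]
    if aggregator == "max":
        return float(max(sims))
    if aggregator == "mean":
        return float(np.mean(sims))
    raise ValueError(f"unknown aggregator {aggregator!r}")


def _similarity_matrix(post_vecs: np.ndarray, phrase_vecs: np.ndarray) -> np.ndarray:
    return _normalize_rows(post_vecs) @ _normalize_rows(phrase_vecs).T


def label_by_similarity(candidates: Mapping[str, str],
                        codebook: Codebook,
                        embedder: Embedder | None = None,
                        threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
                        aggregator: str = "max",
                        ) -> tuple[set[str], dict[str, float]]:
    """Label candidate posts whose aggregated similarity strictly exceeds
    ``threshold`` ("exceeded" is read as a strict inequality); the score map
    for all candidates is retained for downstream risk-factor scoring."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if len(codebook) == 0:
        raise ValueError("empty codebook")
    if embedder is None:
        embedder = HashedEmbedder()
    ids = list(candidates)
    if not ids:
        return set(), {}
    post_vecs = embedder.embed_texts([candidates[i] for i in ids])
    phrase_vecs = embedder.embed_texts(codebook.phrases)
    sims = _similarity_matrix(post_vecs, phrase_vecs)
    agg = sims.max(axis=1) if aggregator == "max" else sims.mean(axis=1)
    scores = {pid: float(s) for pid, s in zip(ids, agg)}
    labeled = {pid for pid, s in scores.items() if s > threshold}
    return labeled, scores


# ---------------------------------------------------------------------------
# Vetting policies

VettingPolicy = Callable[[str, np.ndarray, np.ndarray], bool]

DEFAULT_BLOCKLIST: frozenset[str] = frozenset()


@dataclass
class CentroidVetting:
    """Accept a phrase iff its similarity to the codebook centroid exceeds
    ``threshold`` and it is not blocklisted.

    Suits dense semantic embedders where on-construct phrases cluster; under
    the sparse hashed reference embedder the centroid norm shrinks with
    codebook size, making :class:`NearestPhraseVetting` the better default.
    """

    threshold: float = 0.5
    blocklist: frozenset[str] = DEFAULT_BLOCKLIST

    def __call__(self, phrase: str, phrase_vec: np.ndarray,
                 codebook_vecs: np.ndarray) -> bool:
        if phrase.casefold() in self.blocklist:
            return False
        centroid = np.asarray(codebook_vecs).mean(axis=0)
        return cosine_similarity(phrase_vec, centroid) > self.threshold


@dataclass
class NearestPhraseVetting:
    """Accept a phrase iff its best similarity to any current codebook phrase
    exceeds ``threshold`` (same max aggregation as labeling itself)."""

    threshold: float = 0.5
    blocklist: frozenset[str] = DEFAULT_BLOCKLIST

    def __call__(self, phrase: str, phrase_vec: np.ndarray,
                 codebook_vecs: np.ndarray) -> bool:
        if phrase.casefold() in self.blocklist:
            return False
        return similarity_to_codebook(phrase_vec, codebook_vecs, "max") > self.threshold


def reject_all(phrase: str, phrase_vec: np.ndarray, codebook_vecs: np.ndarray) -> bool:
    """Vetting policy that accepts nothing (pure seed-codebook labeling)."""
    return False


# ---------------------------------------------------------------------------
# Fixed-point iteration


@dataclass
class ExpansionResult:
    codebook: Codebook
    labeled: set[str]
    scores: dict[str, float]
    iterations: int
    converged: bool


def iterate_to_fixed_point(candidates: Mapping[str, str],
                           seed_codebook: Codebook,
                           embedder: Embedder | None = None,
                           threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
                           vetting: VettingPolicy | None = None,
                           max_iterations: int = 10,
                           aggregator: str = "max",
                           rake_max_phrase_len: int = 4,
                           rake_min_freq: int = 2,
                           max_new_per_iteration: int = 200,
                           ) -> ExpansionResult:
    """Run label -> extract -> vet -> append until the codebook is constant.

    Newly extracted phrases are never added automatically: each passes the
    vetting policy (default: centroid similarity > 0.5). If the iteration
    budget runs out before a fixed point, ``converged`` is False — never a
    silent truncation.
    """
    if len(seed_codebook) == 0:
        raise ValueError("seed codebook must be nonempty")
    if embedder is None:
        embedder = HashedEmbedder()
    if vetting is None:
        vetting = CentroidVetting()

    codebook = seed_codebook.copy()
    labeled: set[str] = set()
    scores: dict[str, float] = {}
    converged = False
    iterations = 0

    for iteration in range(1, max_iterations + 1):
        iterations = iteration
        labeled, scores = label_by_similarity(
            candidates, codebook, embedder, threshold, aggregator)
        extracted = rake_extract(
            (candidates[pid] for pid in sorted(labeled)),
            max_phrase_len=rake_max_phrase_len, min_freq=rake_min_freq)

        codebook_vecs = embedder.embed_texts(codebook.phrases)
        added: list[str] = []
        rejected: list[str] = []
        for sp in extracted[: max_new_per_iteration * 5]:
            if len(added) >= max_new_per_iteration:
                break
            if sp.phrase in codebook:
                continue
            vec = embedder.embed(sp.phrase)
            if vetting(sp.phrase, vec, codebook_vecs):
                added.append(sp.phrase)
            else:
                rejected.append(sp.phrase)
        for phrase in added:
            codebook.add(phrase)
        codebook.iteration_log.append({
            "iteration": iteration,
            "n_labeled": len(labeled),
            "added": list(added),
            "rejected": list(rejected),
        })
        if not added:
            converged = True
            break

    if converged and codebook.iteration_log and codebook.iteration_log[-1]["added"] == []:
        # labels already reflect the final codebook (nothing was added)
        pass
    else:
        labeled, scores = label_by_similarity(
            candidates, codebook, embedder, threshold, aggregator)
    if not converged:
        logger.warning("codebook for %r did not reach a fixed point in %d iterations",
                       codebook.dimension, max_iterations)
    return ExpansionResult(codebook, labeled, scores, iterations, converged)
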