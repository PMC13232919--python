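"""Seeded topic modeling: clustering, c-TF-IDF keywords, MMR, coherence.

The stage mirrors the class-based-TF-IDF topic workflow common in social
media text analysis — embed documents, cluster, describe each cluster by
class-level term weights with frequent-word damping, diversify keywords by
maximal marginal relevance, sweep the topic count and keep the most
coherent solution, and park unassignable documents in an outlier topic
(id -1). The density-based clustering of the original toolchain is
replaced by seeded spherical k-means so the whole stage is deterministic
given a seed.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._text import STOPWORDS, word_tokens
from .embed import HashedEmbedder, cosine_similarity

logger = logging.getLogger(__name__)

NPMI_EPS = 1e-12


@dataclass
class TopicModelResult:
    k: int
    assignments: np.ndarray          # per-document topic id; -1 = outlier
    centroids: np.ndarray            # (k, dim), unit rows
    vocabulary: list[str]
    ctfidf_weights: np.ndarray       # (k, |vocab|)
    topic_keywords: list[list[str]]  # MMR-ranked per topic
    coherence: float
    coherence_per_topic: list[float]
    coherence_by_k: dict[int, float] = field(default_factory=dict)


def _normalize_rows(mat: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return mat / norms


def spherical_kmeans(vectors: np.ndarray, k: int, seed: int = 0,
                     n_init: int = 10, max_iter: int = 100,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """K-means on the unit sphere (cosine assignment, renormalised means).

    Seeded k-means++-style initialisation; the best of ``n_init`` runs by
    total cosine similarity wins. Deterministic given the seed.
    """
    X = _normalize_rows(np.asarray(vectors, dtype=np.float64))
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of documents ({n})")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_init):
        centroids = _init_plusplus(X, k, rng)
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            sims = X @ centroids.T
            new_labels = np.argmax(sims, axis=1)
            new_centroids = centroids.copy()
            for j in range(k):
                members = X[new_labels == j]
                if len(members) == 0:
                    # re-seed an empty cluster on the worst-fit document
                    worst = int(np.argmin(sims.max(axis=1)))
                    new_centroids[j] = X[worst]
                    continue
                mean = members.mean(axis=0)
                norm = np.linalg.norm(mean)
                new_centroids[j] = mean / norm if norm > 0 else centroids[j]
            moved = not np.array_equal(new_labels, labels)
            labels, centroids = new_labels, new_centroids
            if not moved:
                break
        score = float((X * centroids[labels]).sum())
        if best is None or score > best[0]:
            best = (score, labels, centroids)
    assert best is not None
    return best[1], best[2]


def _init_plusplus(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    dist = 1.0 - X @ centroids[0]
    for j in range(1, k):
        weights = np.clip(dist, 0.0, None)
        total = weights.sum()
        idx = int(rng.integers(n)) if total <= 0 else int(
            rng.choice(n, p=weights / total))
        centroids[j] = X[idx]
        dist = np.minimum(dist, 1.0 - X @ centroids[j])
    return centroids


def cluster_documents(vectors: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    labels, _ = spherical_kmeans(vectors, k, seed)
    return labels


def class_tfidf(assignments: Sequence[int], documents: Sequence[str],
                reduce_frequent: bool = True,
                stopwords: frozenset[str] | set[str] = STOPWORDS,
                ) -> tuple[list[str], np.ndarray]:
    """Class-level TF-IDF: each topic's concatenated documents form one
    pseudo-document.

    weight(w, c) = tf (square-root damped when ``reduce_frequent``) times
    log(1 + A / f_w), with A the mean token count per topic class and f_w
    the corpus frequency of w. Outlier documents (topic -1) are excluded.
    """
    assignments = np.asarray(assignments)
    topics = sorted({int(t) for t in assignments if t >= 0})
    tokens_per_doc = [
        [t for t in word_tokens(doc) if t not in stopwords] for doc in documents]
    corpus_freq: Counter[str] = Counter()
    class_counts: dict[int, Counter[str]] = {t: Counter() for t in topics}
    for topic, toks in zip(assignments, tokens_per_doc):
        if topic < 0:
            continue
        class_counts[int(topic)].update(toks)
        corpus_freq.update(toks)

    vocabulary = sorted(corpus_freq)
    if not vocabulary:
        raise ValueError("empty vocabulary after stopword filtering")
    col = {w: i for i, w in enumerate(vocabulary)}
    n_topics = len(topics)
    tf = np.zeros((n_topics, len(vocabulary)))
    for row, topic in enumerate(topics):
        counts = class_counts[topic]
        if not counts:
            warnings.warn(f"topic {topic} has no tokens; zero weight row", stacklevel=2)
            continue
        for w, c in counts.items():
            tf[row, col[w]] = c
    if reduce_frequent:
        tf = np.sqrt(tf)
    a_mean = np.mean([sum(class_counts[t].values()) for t in topics]) if topics else 0.0
    f_w = np.array([corpus_freq[w] for w in vocabulary], dtype=float)
    idf = np.log1p(a_mean / f_w)
    return vocabulary, tf * idf


def mmr_keywords(weights: np.ndarray, vocabulary: Sequence[str],
                 term_vectors: np.ndarray, top_n: int = 10,
                 diversity: float = 0.2) -> list[str]:
    """Greedy maximal-marginal-relevance keyword selection for one topic.

    Maximises (1 - diversity) * relevance - diversity * max similarity to
    already-selected terms; relevance is the c-TF-IDF weight. The first
    pick is the top-weight term; ties break lexicographically.
    """
    if not 0.0 <= diversity <= 1.0:
        raise ValueError("diversity must lie in [0, 1]")
    order = sorted(range(len(vocabulary)), key=lambda i: (-weights[i], vocabulary[i]))
    candidates = [i for i in order if weights[i] > 0]
    if not candidates:
        return []
    top_n = min(top_n, len(candidates))
    selected = [candidates.pop(0)]
    while len(selected) < top_n and candidates:
        best_idx, best_score = None, -np.inf
        for i in candidates:
            redundancy = max(cosine_similarity(term_vectors[i], term_vectors[j])
                             for j in selected)
            score = (1.0 - diversity) * weights[i] - diversity * redundancy
            if score > best_score or (score == best_score and best_idx is not None
                                      and vocabulary[i] < vocabulary[best_idx]):
                best_idx, best_score = i, score
        selected.append(best_idx)
        candidates.remove(best_idx)
    return [vocabulary[i] for i in selected]


def topic_coherence(topic_keywords: Sequence[Sequence[str]],
                    documents: Sequence[str], top_m: int = 10,
                    ) -> tuple[float, list[float]]:
    """Mean pairwise NPMI of each topic's top keywords, document windows.

    NPMI = ln(p(w1,w2) / (p(w1) p(w2))) / -ln p(w1,w2), with an epsilon
    guard so never-co-occurring pairs tend to -1. Keywords absent from
    every document are skipped (logged).
    """
    if top_m < 2:
        raise ValueError("top_m must be at least 2")
    doc_sets = [set(word_tokens(d)) for d in documents]
    n_docs = len(doc_sets)
    if n_docs == 0:
        raise ValueError("coherence needs at least one document")

    def doc_freq(word: str) -> int:
        return sum(1 for s in doc_sets if word in s)

    per_topic: list[float] = []
    for keywords in topic_keywords:
        kws = [w for w in keywords[:top_m]]
        present = [w for w in kws if doc_freq(w) > 0]
        skipped = set(kws) - set(present)
        if skipped:
            logger.info("coherence: keywords absent from all documents skipped: %s",
                        sorted(skipped))
        pairs = []
        for a in range(len(present)):
            for b in range(a + 1, len(present)):
                w1, w2 = present[a], present[b]
                p1 = doc_freq(w1) / n_docs
                p2 = doc_freq(w2) / n_docs
                p12 = sum(1 for s in doc_sets if w1 in s and w2 in s) / n_docs
                # limit conventions: never co-occurring pairs pin to -1,
                # perfectly coupled pairs (p12 = p1 = p2, incl. the 0/0
                # case at p12 = 1) pin to +1
                if p12 == 0.0:
                    pairs.append(-1.0)
                elif p12 == p1 == p2:
                    pairs.append(1.0)
                else:
                    p12 = max(p12, NPMI_EPS)
                    pairs.append(float(np.log(p12 / (p1 * p2)) / -np.log(p12)))
        per_topic.append(float(np.mean(pairs)) if pairs else 0.0)
    overall = float(np.mean(per_topic)) if per_topic else 0.0
    return overall, per_topic


def fit_topic_model(vectors: np.ndarray, documents: Sequence[str], k: int,
                    seed: int = 0, diversity: float = 0.2, top_n: int = 10,
                    coherence_top_m: int = 10,
                    embedder: HashedEmbedder | None = None) -> TopicModelResult:
    """Cluster + describe + score one value of k."""
    embedder = embedder or HashedEmbedder()
    labels, centroids = spherical_kmeans(vectors, k, seed)
    vocabulary, weights = class_tfidf(labels, documents)
    term_vectors = embedder.embed_texts(vocabulary)
    keywords = [mmr_keywords(weights[row], vocabulary, term_vectors, top_n, diversity)
                for row in range(weights.shape[0])]
    overall, per_topic = topic_coherence(keywords, documents, coherence_top_m)
    return TopicModelResult(
        k=k, assignments=labels, centroids=centroids, vocabulary=vocabulary,
        ctfidf_weights=weights, topic_keywords=keywords,
        coherence=overall, coherence_per_topic=per_topic)


def select_k(vectors: np.ndarray, documents: Sequence[str],
             k_range: Iterable[int] = range(5, 15), seed: int = 0,
             diversity: float = 0.2, top_n: int = 10,
             coherence_top_m: int = 10) -> TopicModelResult:
    """Sweep k, keep the argmax-coherence solution (ties -> smallest k)."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be nonempty")
    results: dict[int, TopicModelResult] = {}
    coherence_by_k: dict[int, float] = {}
    for k in ks:
        res = fit_topic_model(vectors, documents, k, seed, diversity, top_n,
                              coherence_top_m)
        results[k] = res
        coherence_by_k[k] = res.coherence
    best_k = max(ks, key=lambda k: (coherence_by_k[k], -k))
    best = results[best_k]
    best.coherence_by_k = coherence_by_k
    return best


def assign_outliers(vectors: np.ndarray, centroids: np.ndarray,
                    assignments: Sequence[int], min_similarity: float) -> np.ndarray:
    """Send documents whose best-centroid cosine falls below the floor to -1."""
    X = _normalize_rows(np.asarray(vectors, dtype=np.float64))
    out = np.asarray(assignments).copy()
    sims = X @ _normalize_rows(centroids).T
    best = sims.max(axis=1)
    out[best < min_similarity] = -1
    return out


def topic_ipts_prevalence(assignments: Mapping[str, int],
                          labels: pd.DataFrame) -> pd.DataFrame:
    """Share of each IPTS category's posts falling into each topic.

    Rows are label columns (dimensions, risk factors, lethal); columns are
    topic ids; entries are fractions of the category's posts. Rows sum to
    <= 1 over non-outlier topics (the outlier column absorbs the rest).
    """
    topics = sorted(set(assignments.values()))
    rows = {}
    for category in labels.columns:
        if labels[category].dtype != bool:
            continue
        members = [pid for pid in labels.index[labels[category]] if pid in assignments]
        if not members:
            warnings.warn(f"category {category!r} has no posts; zero row", stacklevel=2)
            rows[category] = {t: 0.0 for t in topics}
            continue
        counts = Counter(assignments[pid] for pid in members)
        rows[category] = {t: counts.get(t, 0) / len(members) for t in topics}
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
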