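"""Sparse additive contrast of a target corpus against a background.

A target corpus's word distribution is modeled as a log-linear deviation
from a background: p_w  ∝  exp(m_w + eta_w), with m the background
log-probabilities and eta a sparse deviation vector. Positive eta marks a
term as characteristic of the target group, negative of the background.
Sparsity comes from an L1 penalty sum_w |eta_w| / tau_w whose per-term
scales are self-tuned by alternating between the penalised fit and the
update tau_w = |eta_w| + eps, so that frequent and rare terms are balanced
without a hand-picked global regulariser. A fixed-lambda L1 fallback is
available, and with the penalty removed the fit reduces to the multinomial
maximum likelihood (a closed-form check used by the tests).

Optimisation is proximal gradient (ISTA) with backtracking line search on
the smooth negative log-likelihood; eta starts at 0, so the fit is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.feature_extraction.text import CountVectorizer

from ._text import STOPWORDS

BACKGROUND_SMOOTHING = 0.1
TAU_EPS = 1e-3


def build_ngram_counts(texts: Sequence[str], n_orders: tuple[int, int] = (1, 2),
                       stopwords: frozenset[str] | set[str] = STOPWORDS,
                       min_count: int = 1) -> tuple[list[str], np.ndarray]:
    """Unigram/bigram term counts with lowercasing and stop-word filtering.

    Stopwords are removed before n-gram formation (so "the pain ends"
    yields the bigram "pain ends"); terms with total count below
    ``min_count`` are dropped; the vocabulary is sorted deterministically.
    """
    if not texts:
        raise ValueError("texts must be nonempty")
    vectorizer = CountVectorizer(
        ngram_range=(min(n_orders), max(n_orders)),
        stop_words=list(stopwords), lowercase=True,
        token_pattern=r"[a-zA-Z0-9']+")
    try:
        matrix = vectorizer.fit_transform(texts)
    except ValueError as exc:
        raise ValueError("empty vocabulary after filtering") from exc
    vocab = vectorizer.get_feature_names_out()
    counts = np.asarray(matrix.sum(axis=0)).ravel().astype(float)
    keep = counts >= min_count
    if not keep.any():
        raise ValueError("empty vocabulary after min_count filtering")
    return [str(w) for w in vocab[keep]], counts[keep]


def align_vocabularies(vocab_a: Sequence[str], counts_a: np.ndarray,
                       vocab_b: Sequence[str], counts_b: np.ndarray,
                       ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Union-align two count vectors onto one shared sorted vocabulary."""
    shared = sorted(set(vocab_a) | set(vocab_b))
    idx = {w: i for i, w in enumerate(shared)}
    a = np.zeros(len(shared))
    b = np.zeros(len(shared))
    for w, c in zip(vocab_a, counts_a):
        a[idx[w]] = c
    for w, c in zip(vocab_b, counts_b):
        b[idx[w]] = c
    return shared, a, b


@dataclass
class SageModel:
    """Fitted contrast model."""

    vocabulary: list[str]
    m: np.ndarray        # background log-probabilities (exp(m) sums to 1)
    eta: np.ndarray      # sparse deviations
    tau: np.ndarray      # per-term penalty scales at convergence
    n_target: float
    converged: bool
    # one monotone non-increasing segment per proximal-gradient run (the
    # penalty weights change between outer rounds, so segments may jump)
    objective_path: list[list[float]] = field(default_factory=list)

    def target_distribution(self) -> np.ndarray:
        logp = self.m + self.eta
        return np.exp(logp - logsumexp(logp))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.vocabulary, "eta": self.eta,
                             "m": self.m}).sort_values("eta", ascending=False)


def _smooth_neg_loglik(eta: np.ndarray, m: np.ndarray, counts: np.ndarray,
                       n_target: float) -> tuple[float, np.ndarray]:
    z = m + eta
    lse = logsumexp(z)
    value = -(counts @ z - n_target * lse)
    grad = -counts + n_target * np.exp(z - lse)
    return float(value), grad


def _soft_threshold(x: np.ndarray, thresh: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thresh, 0.0)


def _ista(eta0: np.ndarray, m: np.ndarray, counts: np.ndarray, n_target: float,
          inv_tau: np.ndarray, max_iter: int, tol: float,
          objective_path: list[list[float]]) -> np.ndarray:
    """Proximal gradient with backtracking; monotone in the full objective."""
    eta = eta0.copy()
    f, grad = _smooth_neg_loglik(eta, m, counts, n_target)
    step = 1.0 / max(n_target, 1.0)
    segment = [f + float(inv_tau @ np.abs(eta))]
    objective_path.append(segment)
    for _ in range(max_iter):
        while True:
            candidate = _soft_threshold(eta - step * grad, step * inv_tau)
            delta = candidate - eta
            f_new, grad_new = _smooth_neg_loglik(candidate, m, counts, n_target)
            quad = f + float(grad @ delta) + float(delta @ delta) / (2.0 * step)
            if f_new <= quad + 1e-12:
                break
            step *= 0.5
            if step < 1e-16:
                candidate, f_new, grad_new, delta = eta, f, grad, np.zeros_like(eta)
                break
        segment.append(f_new + float(inv_tau @ np.abs(candidate)))
        if not np.isfinite(f_new):
            raise FloatingPointError("non-finite SAGE objective; check input counts")
        max_move = float(np.max(np.abs(delta))) if delta.size else 0.0
        eta, f, grad = candidate, f_new, grad_new
        if max_move < tol:
            break
        step *= 1.5  # gentle step recovery after successful moves
    return eta


def fit_sage(target_counts: np.ndarray, background_counts: np.ndarray,
             vocabulary: Sequence[str] | None = None,
             max_outer: int = 50, tol: float = 1e-4,
             adaptive: bool = True, lam: float | None = None,
             max_inner: int = 2000, inner_tol: float | None = None) -> SageModel:
    """Fit the sparse deviation vector eta.

    ``adaptive=True`` runs the self-tuned penalty (tau_w = |eta_w| + eps,
    alternated with penalised fits until max |delta eta| < tol);
    ``adaptive=False`` uses a fixed lambda (``lam``; 0 disables the penalty
    entirely, recovering the multinomial MLE on the shared vocabulary).
    """
    target = np.asarray(target_counts, dtype=float)
    background = np.asarray(background_counts, dtype=float)
    if target.shape != background.shape:
        raise ValueError("target and background counts must share one vocabulary")
    if vocabulary is None:
        vocabulary = [f"w{i}" for i in range(len(target))]
    if len(vocabulary) != len(target):
        raise ValueError("vocabulary length must match the count vectors")
    n_target = float(target.sum())
    if n_target <= 0:
        raise ValueError("target corpus has no tokens")

    smoothed = background + BACKGROUND_SMOOTHING
    m = np.log(smoothed / smoothed.sum())
    eta = np.zeros_like(m)
    objective_path: list[list[float]] = []
    inner_tol = inner_tol if inner_tol is not None else min(tol * 1e-2, 1e-6)

    converged = False
    if not adaptive:
        inv_tau = np.full_like(m, 0.0 if not lam else float(lam))
        eta = _ista(eta, m, target, n_target, inv_tau, max_inner, inner_tol,
                    objective_path)
        tau = np.full_like(m, np.inf) if not lam else np.full_like(m, 1.0 / float(lam))
        converged = True
    else:
        # Seed tau from the unpenalised deviations: starting from tau = eps
        # makes eta = 0 a degenerate fixed point of the reweighted scheme
        # (|grad| <= 1/eps holds for any realistic corpus). Terms whose
        # empirical deviation is sampling noise get tiny tau and are zeroed;
        # genuinely shifted terms keep room to move. The likelihood is
        # invariant to a constant shift of eta, so the MLE deviations are
        # median-centred before sizing the penalties.
        smoothed_target = target + BACKGROUND_SMOOTHING
        eta_mle = np.log(smoothed_target / smoothed_target.sum()) - m
        eta_mle = eta_mle - np.median(eta_mle)
        tau = np.abs(eta_mle) + TAU_EPS
        for _ in range(max_outer):
            inv_tau = 1.0 / tau
            new_eta = _ista(eta, m, target, n_target, inv_tau, max_inner,
                            inner_tol, objective_path)
            move = float(np.max(np.abs(new_eta - eta))) if eta.size else 0.0
            eta = new_eta
            tau = np.abs(eta) + TAU_EPS
            if move < tol:
                converged = True
                break

    return SageModel(list(vocabulary), m, eta, tau, n_target, converged,
                     objective_path)


def fit_sage_corpora(target_texts: Sequence[str], background_texts: Sequence[str],
                     min_count: int = 1, **kwargs) -> SageModel:
    """Convenience wrapper: texts in, fitted contrast model out.

    The background is the pooled contrast-group corpus (for the
    lethal-vs-nonlethal comparison, the responses to non-lethal posts).
    """
    tv, tc = build_ngram_counts(target_texts, min_count=min_count)
    bv, bc = build_ngram_counts(background_texts, min_count=min_count)
    vocab, target, background = align_vocabularies(tv, tc, bv, bc)
    return fit_sage(target, background, vocab, **kwargs)


def rank_discriminative(model: SageModel, top_k: int = 15,
                        ) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Top positive-eta and top negative-eta terms (|eta| > 0 only).

    Invariant to vocabulary permutation: ties in eta break on the term.
    """
    idx = range(len(model.vocabulary))
    pos_order = sorted(idx, key=lambda i: (-model.eta[i], model.vocabulary[i]))
    neg_order = sorted(idx, key=lambda i: (model.eta[i], model.vocabulary[i]))
    positive = [(model.vocabulary[i], float(model.eta[i]))
                for i in pos_order if model.eta[i] > 0][:top_k]
    negative = [(model.vocabulary[i], float(model.eta[i]))
                for i in neg_order if model.eta[i] < 0][:top_k]
    return positive, negative
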