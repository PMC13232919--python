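# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generators emulate,
and the known limits of what passing tests demonstrate.

## Labeling model

Posts are labeled with the four IPTS dimensions (loneliness, lack of
reciprocal love, self-hate, liability) and acquired capability through an
embedding-similarity codebook procedure:

- **Candidate selection.** A per-dimension binary classifier trained by
  distant supervision proposes candidates. The reference backend is
  L2-regularised logistic regression over hashed bag-of-words features
  (1,024 dimensions, `C = 10`), with class weights `w_c = n/(2 n_c)` and a
  stratified 55:45 train/test split. Posts with predicted probability
  strictly above 0.5 enter the candidate pool (the natural binary decision
  point; configurable). The recurrent reference architecture (64-dim
  embedding, 128-unit LSTM with dropout, global max pooling, 64-unit ReLU
  dense, sigmoid output, Adam, weighted cross-entropy) is declared as an
  optional adapter requiring a keras runtime.
- **Similarity labeling.** Candidates whose max cosine similarity to any
  codebook phrase strictly exceeds 0.60 are labeled. "Strictly" implements
  the exceeded-a-threshold reading; max (rather than mean) aggregation means
  one matching concept suffices, which is consistent with phrase-level
  seeds. Both aggregators are available.
- **Codebook expansion.** RAKE (max phrase length 4, minimum frequency 2,
  scikit-learn's English stopword list) extracts candidate phrases from
  labeled posts. Phrases are never added automatically: a vetting policy
  stands in for expert review. Two automated policies ship. CentroidVetting
  (similarity to the codebook centroid > 0.5) suits dense semantic
  embedders, where on-construct phrases cluster tightly. Under the sparse
  hashed reference embedder, near-orthogonal seed phrases make the centroid
  norm shrink like `1/sqrt(|codebook|)`, so a fixed centroid cut rejects
  everything once the codebook has more than a few phrases;
  NearestPhraseVetting (max similarity to any current phrase > 0.5) is the
  geometry-appropriate analogue and is what unattended pipeline runs use.
  Iteration stops when no phrase is added (guaranteed: the phrase universe
  of a finite corpus is finite; a 10-iteration budget is a safety valve that
  sets `converged=False` rather than truncating silently).
- **Composition.** TB score = mean(loneliness, lack-of-love scores); PB
  score = mean(self-hate, liability scores); AC score = capability score;
  each flagged at the same strict 0.60. Lethal = TB ∧ PB ∧ AC. Wilson score
  intervals back the distribution table; they reproduce published CI bounds
  to within one unit in the last printed decimal on spot checks and behave
  well near 0.

## Embedding backend

The reference embedder hashes lowercase alphanumeric tokens with 32-bit
FNV-1a, accumulates counts, and L2-normalises; empty text maps to the zero
vector, whose cosine to anything is defined as 0, so empty posts can never
cross a labeling threshold. The contract default is 256 dimensions; the
labeling pipeline configures 4,096 because its corpus vocabulary (a few
hundred to a few thousand types) would otherwise suffer hash collisions
that leak similarity across unrelated constructs (expected colliding pairs
scale as `|V|²/2d`). Transformer sentence encoders (the 384-dimensional
family typically used for this kind of semantic matching) plug in through
the same interface; an unavailable backend raises, never silently falls
back.

## Synthetic corpora

The generators define the study conditions the tests and acceptance run
exercise. `gen_ipts_posts` (defaults: 2,000 posts; single-dimension shares
0.06–0.08 per construct; risk-factor pair shares 0.05 each; lethal share
0.02; phrase injection rate 2; paraphrase share 0.3) builds positive posts
by injecting copies of one construct phrase per dimension — seed phrases
from the shipped codebooks, or near-paraphrases absent from the seeds —
among neutral background words, joined by punctuation so RAKE can recover
the phrases whole.

Generation is geometry-aware: the number of background tokens is budgeted
from the exact squared token counts so that every injected primary phrase's
cosine clears ~0.66 (slack over the 0.60 threshold for residual
collisions). For two-construct posts the budget escalates the copy count of
whichever phrase's admissible-norm cap binds. For three or more orthogonal
constructs no budget exists — the sum of squared cosines onto orthogonal
directions is at most 1 — so lethal-profile posts cannot clear the
threshold for all five constructs under any count-based embedder. They are
generated with prominent capability phrasing (method/attempt language is
what operationally distinguishes lethal disclosures), which keeps the
directly-scored construct recoverable while the paired constructs are not.
Consequences the tests make explicit: per-dimension F1 on the synthetic
study condition lands around 0.87–1.00 against a structural ceiling of
~0.92 for the paired dimensions, and the pipeline predicts no lethal posts
on synthetic corpora — lethal composition is validated on score tables and
ground-truth flags instead. A semantic (transformer) backend does not have
this orthogonality constraint; the limitation belongs to the offline
reference embedder, not to the procedure.

Paraphrase discovery requires a bridge: half of the single-construct posts
that use a paraphrase also restate the parent seed with its own budgeted
copy count, so the seed codebook labels them at iteration 1 and RAKE can
surface the paraphrase even when it shares no token with its parent.

`gen_themed_corpus` plants k disjoint theme vocabularies (20 words each)
plus rare "signature" tokens (compounds of two vocabulary words, 3–4 per
document, repeated 1–3 times) drawn from a 400-token pool. Merging themes
mixes never-co-occurring keywords (pairwise association pinned at −1);
over-splitting surfaces concentrated rare tokens into a sub-cluster's
c-TF-IDF top keywords, degrading coherence — together producing a genuine
coherence peak at the planted k, which the k-sweep recovers.

`gen_threads_with_responses` pairs each post with one community response
(informal narrative fragments, group-dependent category-word rates, planted
discriminative n-grams over-sampled ×10 in the lethal group) and one
templated response per AI setting (deterministic template choice by hash of
seed and post id; `{topic}` slots filled from the post). Planted bigram
components deliberately avoid stopwords, since stop-word filtering runs
before n-gram formation. The fixture reproduces the qualitative contrasts
the metric suite is designed to detect — templated pools are more verbose,
more formal, more semantically similar to the post and less diverse than
community pools — but not the published magnitudes, which depend on private
data and proprietary scorers.

What passing tests do *not* show: recovery rates on real crisis language
(synthetic positives are phrase-dominated by construction), robustness to
spelling variation or code-switching, or the behavior of the pipeline under
semantic embedders.

## Sparse lexical contrast (SAGE-style)

The target corpus distribution is modeled as `p_w ∝ exp(m_w + η_w)`, with
`m` the log of the additively smoothed (+0.1) background distribution. η
minimises the penalised multinomial negative log-likelihood
`−c·(m+η) + N·logsumexp(m+η) + Σ|η_w|/τ_w` by proximal gradient (ISTA) with
backtracking line search — monotone within each run — starting from η = 0.
The "self-tuned" penalty alternates fits with the update `τ_w = |η_w| + ε`
(ε = 1e−3) until `max|Δη| < 1e−4` (outer budget 50). τ is seeded from the
median-centred unpenalised deviations rather than from ε: with τ = ε the
subgradient condition `|∇| ≤ 1/ε` makes η = 0 a degenerate fixed point of
the reweighted scheme for any realistic corpus. A fixed-λ L1 fallback is
available; with the penalty off, the fit reaches the closed-form
multinomial MLE to ≤1e−6, which the tests verify. The exact penalty the
original formulation used is not printed anywhere authoritative; the
adaptive scheme here is this package's interpretation and is flagged as
such.

## Topic stage

Spherical k-means (seeded k-means++-style init, cosine assignment,
renormalised mean centroids, best of 10 restarts) replaces the
density-based clustering of the usual toolchain so the stage is
deterministic given a seed; documents below a cosine floor to their nearest
centroid move to outlier topic −1. Class-based TF-IDF uses
`sqrt(tf) · log(1 + A/f_w)` (A = mean tokens per class, f_w = corpus
frequency; the square root is the frequent-word damping). Keyword lists are
diversified by maximal marginal relevance at diversity 0.2 with c-TF-IDF
weight as relevance. Coherence is mean pairwise NPMI over the top 10
keywords with document-level windows; never-co-occurring pairs pin to −1
and perfectly coupled pairs to +1 (the continuity limits). k sweeps 5..14;
ties break to the smaller k.

## Statistics

Kruskal–Wallis is the tie-corrected rank H with a χ²(k−1) p-value
(scipy); the all-identical degenerate case maps to (H=0, p=1). Bonferroni
thresholds use the number of categories actually tested, logged per run.
Paired Cohen d divides the mean paired difference by the difference-score
standard deviation (ddof 1); zero-variance differences yield NaN with a
warning rather than a fabricated value. Kruskal–Wallis effect size is
`η² = (H − k + 1)/(n − k)`. The comparison table adjusts all its p-values
jointly by Benjamini–Hochberg.

## Metric interpretations

Repeatability is the type–token deficit `1 − distinct/total`; complexity is
the mean word length per sentence averaged over sentences. Both are
one-line definitions made precise here and are config-replaceable; the
published magnitudes for complexity are not reproducible from the plain
definition, so only ordering/direction properties are asserted. The CDI is
`(articles + prepositions) − (personal pronouns + impersonal pronouns +
auxiliary verbs + conjunctions + adverbs + negations)` on proportions ×100
with offset 0; scale and offset are configuration because the published
scaling is not printed, and assertions are sign/monotonicity only.
Formality and empathy are scorer contracts; the shipped scorers are
deterministic lexicon-ratio stand-ins suitable for ordering checks, not
calibrated instruments. The shipped `.dic` lexicon is a small synthetic
open fixture (function words plus a few affect categories); analyses are
lexicon-agnostic and accept any user-supplied `.dic`.

## Problem sizes

Defaults were chosen so the full suite and the acceptance script each run
in well under a minute of compute on one core: recovery experiments use
2,000 posts, the topic experiment 360 documents over a 5..14 sweep, the
SAGE fixtures 20-term vocabularies with 4,000–5,000 tokens, and the null
calibration 1,000 replicates of 3×20 samples. These sizes put Monte-Carlo
error well inside the asserted bands while keeping runs interactive.
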