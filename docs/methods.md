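# Methods

## Model and notation

Two views `X ∈ R^{n×p}` and `Y ∈ R^{n×q}` measure the same `n` samples.
Covariances are column-centered with denominator `n − 1` throughout (a
config-free, consistent convention; the ridge grid therefore lives on the
sample-covariance scale).  CCA solves

    C_xy (C_yy + λ_y I)⁻¹ C_yx w_x = ρ² (C_xx + λ_x I) w_x

and symmetrically for `w_y`; the reported canonical correlation is
`ρ = sqrt(eigenvalue)`, sorted non-increasing, clamped to [0, 1].  The ridge
terms model i.i.d. Gaussian feature noise in each view: under that noise
model the cross-covariance is unbiased while each auto-covariance is
inflated by the noise variance on its diagonal — which is exactly what the
ridge restores.

## Solver

Two branches:

* **Positive-definite branch** (any ridge > 0, or full-rank data).
  Cholesky factors of the regularized auto-covariances whiten the
  cross-covariance; an SVD of the whitened operator gives correlations
  (singular values) and weights (back-substituted singular vectors).  This
  is algebraically equivalent to the generalized eigenproblem and
  numerically stable.  Weights satisfy `w_xᵀ(C_xx + λ_x I) w_x = 1` per
  component.  A correlation exceeding 1 by more than 1e-10 raises an error
  here (it indicates inconsistent covariance input); smaller excursions are
  clamped silently.
* **Singular branch** (ridge = 0 with rank-deficient auto-covariance, i.e.
  `n < p + q + 1`).  The generalized eigenproblem is solved literally:
  SVD-based pseudo-inverses (relative cutoff 1e-10) stand in for the
  inverses, followed by a non-symmetric eigendecomposition whose leading
  real eigenvector parts are taken.  This branch intentionally reproduces
  how naive CCA implementations behave on such data: in-sample correlations
  saturate at 1, the eigenvalue cluster is degenerate, and the recovered
  embedding components are strongly mutually correlated — they carry the
  same overfitted information.  Exactly when the leading perturbed
  eigenvalues form a complex-conjugate pair, the two leading components
  become numerically identical (correlation 1); otherwise they are strongly
  but not perfectly correlated.  Because this branch is unreliable by
  construction, its correlations are clamped into [0, 1] without raising.
  The model flags itself `degenerate=True` so downstream code and plots can
  annotate the condition.

A deterministic sign convention (largest-magnitude entry of each `w_x`
column positive; `w_y` sign chosen so the paired in-sample correlation is
non-negative) makes results reproducible across platforms.

## Ridge selection

The grid is `v` evenly spaced values on `[θ₁, θ₂]`, traversed either as the
`v` coupled pairs `λ_x = λ_y` (default — this is the complexity regime in
which the supervised savings are quoted) or as all `v²` ordered pairs.
Criteria:

* `rcca-loo` — for each grid point, refit single-component CCA `n` times
  with one sample removed, score the removed sample on both views with the
  training centering, and return the Pearson correlation of the two
  held-out score vectors.  A zero-variance score vector yields 0 with a
  warning.
* `tt` — Welch t-score `|μ₁−μ₂| / sqrt(s₁²/n₁ + s₂²/n₂)` of the first
  canonical component of the scoring view (default `x`), with
  (n−1)-denominator class variances.  Both variances zero with distinct
  means returns +inf (a perfect-separation sentinel that wins any argmax).
* `wrst` — Mann–Whitney `U` from midranks, reported as
  `max(U, n₁n₂ − U)` so the score is class-symmetric; ceiling `n₁n₂` means
  perfect rank separation.
* `wlt` — Wilks lambda `SS_within / SS_total` of the component (population
  variance form, so Λ ∈ [0, 1]); minimized.

The selected pair is chosen once, from the first component's criterion, and
reused for all `d` metaspace components; no per-dimension adjustment is
attempted (none is well-defined).  Ties break toward the lexicographically
smallest `(λ_x, λ_y)`.  Each `solve` call increments a module-level counter,
so selection results report *measured* factorization counts — `v` for the
supervised criteria and `v·n` for `rcca-loo` in coupled mode — rather than
estimates.

## Metaspace and evaluation

The metaspace is the scoring view's projection onto the top components,
prefix-truncated at the first canonical correlation below `λ₀` (correlations
are sorted, so prefix truncation equals filtering) and capped at `d`.
Held-out samples are projected with the training centering vectors.

`loo_evaluate` runs the strict leave-one-out protocol: per fold, optional
Welch-t pruning of the x-view to at most `prune_k` features (two-sided
p < 0.05), ridge selection per scheme, model fit, metaspace construction and
classifier training all use only the `n−1` training samples.  Classifiers:
an internal 1-NN (Euclidean; exact distance ties go to the lowest training
index, making the protocol fully deterministic) and a 50-tree random forest
seeded per fold as `seed + fold_index`.  Accuracy is the unweighted fraction
of correct folds.  `sweep` evaluates every (scheme, classifier, d, pair)
cell and summarizes max and median accuracy per scheme × classifier; because
ridge selection is deterministic and independent of `d` and the classifier,
the sweep memoizes it per (pair, scheme, fold) — cell results are bit-equal
to standalone evaluations.  `paired_accuracy_ttest` is the two-sided paired
Student t-test on matched per-cell accuracies; identical vectors give
(t=0, p=1) and constant non-zero differences (zero variance, where t
diverges) return a signed infinite t with a p-value sentinel just above
zero, with a warning.

## Comparators

* **PCA** on the concatenated matrix `Z = [X Y]`, column-centered by
  default (a row-centering flag exists for the alternative convention of
  removing per-sample means, occasionally used for concatenated views).
  Eigenvalues are singular values squared over `n − 1`.
* **PLS2** regression of the y-view on the x-view.  Each component's weight
  vector is the dominant left singular vector of the deflated cross-product
  `EᵀF` — the exact fixed point of the classic NIPALS inner loop, computed
  directly because power iteration converges at rate `(s₂/s₁)²` and deep
  components of small-n folds routinely have near-tied singular values that
  stall it.  Both blocks are deflated with the predictor scores; held-out
  samples are projected through the standard rotation `W (PᵀW)⁻¹`.

## Synthetic data

`generate_two_view` draws `n_latent` shared standard-normal factors; the
first factor's mean is shifted `class_shift` standard deviations between the
two classes.  Each view observes `sqrt(c)·z_k` plus independent factor noise
with `c` calibrated so that, after the additive i.i.d. feature noise
(`noise_sd_x`, `noise_sd_y`), the *population* canonical correlation per
factor equals `latent_corr`; an unattainable request raises with the
attainable bound `1/sqrt((1+σ_x²)(1+σ_y²))`.  Factors map to features
through random orthonormal loading matrices.  Defaults are the study-like
conditions at the post-pruning scale: `n=19` split 10/9, `p=25`, `q=51`,
three factors, `latent_corr=0.9`, `class_shift=1.5`, noise sd 0.2.
`generate_study_like` emits the three full-size pairs (19×953 against
19×100, 19×51, 19×151) sharing one positive-valued expression view, so the
quantile/log2/standardize/prune chain is exercised end to end.

What the generator does *not* emulate — and hence what passing tests do not
show about real cohorts: heavy-tailed and batch-structured expression noise,
feature correlation beyond the shared factors, and crucially any
*outcome-irrelevant dominant covariation* between the views.  Because the
class shift inflates the shared variance of factor 1, the class-informative
factor is also the most correlated one, so the unsupervised stability
criterion recovers the same component the supervised criteria target and
the two selection families perform near-identically here (their medians
over repeated instances sit within one leave-one-out cell of each other).
In real multimodal data the dominant cross-view covariation is typically
unrelated to outcome — that is the regime in which supervised ridge
selection is expected to separate from unsupervised selection, and it is
outside what this generator can produce.  The supervised-vs-plain-CCA
advantage, by contrast, is large and robust here (plain CCA is degenerate
at these shapes).

## Problem sizes and numerical choices in the shipped tests

The test suite checks the solver against a whitened-SVD oracle on 100
well-conditioned instances (n=50, p=4, q=3, tolerance 1e-8), the three
separation criteria against direct-formula / exhaustive-rank /
sum-of-squares oracles on 1000 random small inputs, the leave-one-out
objective against a naive loop at n=12 (1e-12), factorization counts at the
study grid (v=200, n=19 → 200 vs 3800), degeneracy and rescue at n=19,
p=25, q=51, the scheme ordering over 50 study-like instances, and a full
3-pair × d=1..10 × 7-scheme × 2-classifier sweep on a v=20 grid.
`scripts/acceptance.py` recomputes the same families of quantities at
slightly reduced repetition counts (15 ordering instances; a 2-scheme,
1-NN sweep) so a full reproduction run stays near one minute.

## Known limitations

* Exactly two views and two classes; no kernelized or multi-block variants.
* The singular λ=0 branch is deliberately faithful to naive CCA behavior
  rather than maximally accurate; use any positive ridge for trustworthy
  components when `n < p + q + 1`.
* Wilks lambda selection requires a non-degenerate embedding (total
  variance > 0) and t-score selection needs ≥ 2 samples per class in every
  training fold.
* Random-forest accuracies are a single seeded run per fold; repeat with
  different seeds for stability estimates.
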