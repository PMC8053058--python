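# Methods

## The model

`geetgdr` selects features relevant to a longitudinal continuous outcome.
The data are a balanced panel: for each of n subjects a P-vector of
time-invariant baseline covariates x_i (e.g. lncRNA expression in lesional
skin) and a t-vector of outcomes Y_i = (Y_i1, …, Y_it) (e.g. PASI severity
scores at baseline and follow-up weeks).  The marginal model is linear with
identity link and a separate coefficient vector per time point,

    E[Y_ij | x_i] = x_i' β_j ,      β ∈ R^{t×P},

so β_jp measures how feature p relates to the outcome at time j, and the
per-time supports {p : β_jp ≠ 0} may differ across time — a feature can
matter early in treatment and not later.

Dependence within a subject is handled GEE-style through a working
covariance V = A^{1/2} R(α) A^{1/2}, where A = diag(σ²_1, …, σ²_t) holds
per-time marginal variances and R(α) is one of four working correlation
structures: independent (identity), exchangeable (constant off-diagonal α),
AR1 (α^|j−l|), or unstructured (a free symmetric unit-diagonal matrix).
The objective is the quasilikelihood quadratic form

    QL(β) = n^{-1} Σ_i (Y_i − μ_i(β))' V^{-1} (Y_i − μ_i(β)).

## The optimizer: threshold gradient descent

QL is minimized by thresholded gradient descent from β = 0 (the null
model).  At iteration k the negative gradient g_jp = n^{-1} Σ_i X_ip
[V^{-1}(Y_i − μ_i)]_j is computed, and only entries whose magnitude is at
least a fraction τ of the row-wise maximum (the maximum over features,
separately for each time point) are updated:

    β_jp ← β_jp + Δv · g_jp · 1{ |g_jp| ≥ τ · max_l |g_jl| } .

No penalty term appears; sparsity comes from the thresholding, and the
iteration count K is the regularization parameter.  Small K gives a sparse,
heavily shrunken model; large K approaches the per-time least-squares fit.
K (and optionally τ) is tuned by subject-level k-fold cross-validation on
held-out mean squared error.  Nuisance parameters (σ², α) are re-estimated
from the current residuals by the residual-based moment method inside the
loop (every iteration by default; `nuisance_refresh` trades accuracy for
speed).  With a single time point and the independence structure the
procedure reduces exactly to conventional cross-sectional TGDR, which the
package also exposes directly (`tgdr_fit`).

A univariate GEE screen is provided as the standard comparator: for each
feature separately, an intercept-plus-slope marginal model (slope shared
across time points) is fitted by iterated generalized least squares with
moment nuisance re-estimation, and the slope is tested with a robust
sandwich (bread = model-based information, meat = empirical score outer
products) Wald statistic against the normal reference; features with
p < 0.05 are selected, with no multiple-testing correction.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| Δv (`delta_v`) | 0.01 | gradient step increment; must stay below the quadratic stability bound ≈ 1/(λ_max(V^{-1})·λ_max(n^{-1}X'X)) or the path diverges (detected and raised) |
| τ (`tau`) | 1.0 | threshold fraction in [0, 1]; 1 updates only the per-row argmax (sparsest), 0 is plain gradient descent; CV grid {0, 0.5, 1} available |
| K | CV-chosen | iteration count; default CV grid {10, 20, 50, 100, 200, 500, 1000} |
| structure | unstructured | working correlation; unstructured is the most agnostic choice for short, unevenly spaced panels |
| `nuisance_refresh` | 1 | iterations between moment re-estimations of (σ², α) |
| folds | 5 | CV folds; folds split subjects, never subject-time observations, and standardization is re-learned inside each training fold to avoid leakage |

Covariates are standardized to mean 0, sample SD 1 (denominator n−1) and
outcomes are mean-centered per time point before fitting: the threshold
compares gradient magnitudes across features, which is only meaningful on a
common scale, and per-time centering stands in for unpenalized time-specific
intercepts.  The factor 2 from differentiating the squared error is dropped
throughout (absorbed by Δv).

## Numerical choices

- **Gradient weight.**  The implemented weight is V^{-1} =
  A^{-1/2} R^{-1} A^{-1/2}, the exact (half, negated) derivative of QL with
  the nuisance held fixed — verified against central finite differences to
  <1e-5 relative error.  An asymmetric variant A^{1/2} R^{-1} A^{-1/2}
  (`literal_eq5=True`) is available; the two coincide up to a positive
  per-row rescaling whenever variances are equal across time points, and
  they produce identical selections because thresholding is row-wise and
  scale-invariant.
- **Independence structure.**  Under working independence the residuals
  enter unweighted (V = I).  This makes the t = 1 path coincide bitwise with
  conventional TGDR and makes the GLS limit the per-time ordinary
  least-squares solution; weighting by estimated per-time variances under
  independence would only rescale rows of the gradient without changing any
  selection.
- **Moment estimates.**  σ̂²_j = n^{-1} Σ_i e_ij² (time-specific, matching
  A's definition), Pearson residuals r_ij = e_ij/σ̂_j, exchangeable
  α̂ = mean of r_ij r_il over subjects and pairs j<l, AR1 α̂ = mean over
  adjacent pairs, unstructured R̂ = n^{-1} r'r with unit diagonal restored.
  Denominators use n with no degrees-of-freedom correction (no parametric
  df exists when P ≫ n).  Estimates are clipped to keep R positive definite:
  exchangeable to [−1/(t−1)+10⁻³, 0.99], AR1 and unstructured off-diagonals
  to [−0.99, 0.99].
- **Inversion safeguard.**  R is inverted after flooring its smallest
  eigenvalue at 10⁻⁶ (ridge added if needed); unstructured moment estimates
  at n near t are routinely near-singular.
- **Ties.**  At τ = 1 every component tied at the row maximum updates (the
  threshold uses ≥).  "Selected" means exactly nonzero after K updates; no
  magnitude floor is applied.
- **Initialization.**  R starts at the identity and σ² at the marginal
  outcome variances, since β = 0 residuals only carry the raw outcome
  correlation after the first re-estimation.
- **Degenerate inputs.**  Missing values, duplicate or mismatched subject
  IDs, zero-variance covariates, non-finite paths, t = 1 with a
  non-independent structure, and zero residual variance all raise
  informative errors rather than proceeding.

## The synthetic test bed

All tests and the acceptance script run on synthetic panels shaped like the
motivating application (default n = 30 subjects, t = 4 time points
[baseline, weeks 1, 2, 4], P = 662 features, 10 signal features): covariates
i.i.d. standard normal (optionally equicorrelated through a shared factor),
errors multivariate normal with covariance diag(σ)·R(α)·diag(σ), and a
sparse time-varying truth.  By default each signal feature is active on a
random contiguous window of time points with coefficient 1.0 (a marker
relevant during a phase of the response); `time_pattern` switches to
constant-across-time or single-time-point activity.  Effect size 1.0 on
standardized covariates with σ = 1 is detectable at n ≈ 100.  The generator
does not attempt realistic expression marginals (heavy tails, probe
effects) or the bounded scale of clinical severity scores, so passing tests
demonstrate algorithmic correctness and behavior under the stated Gaussian
panel model, not performance on real microarray data.

Heavier experiments use a recovery preset of n = 100, t = 4, P = 200 with
5 signal features — large enough for the signal to be reliably detectable,
small enough that cross-validated fits over the full K grid run in seconds.

## Design choices where the design was open

- The nuisance-refresh schedule is per-iteration (the re-estimation step
  sits inside the loop); `nuisance_refresh` exposes coarser schedules.
- CV picks the grid point with minimal mean held-out MSE, ties broken
  toward smaller K then smaller τ; the whole-data fit reported alongside is
  computed at that chosen point.
- The screening model shares one slope across time points and omits a time
  covariate (outcomes are per-time centered in the main fitter; in the
  screen the intercept absorbs the common level).  The normal, not t,
  reference is used for the Wald test.
- Pearson residuals use time-specific variances rather than a pooled one.

## Known limitations

- **Overselection at the CV optimum.**  Like other stagewise/boosting-type
  paths tuned for prediction, the iteration count that minimizes held-out
  MSE lies well past the point where the signal enters the model: with
  Δv = 0.01 the signal coefficients need several hundred iterations to
  converge, and in every iteration each time-point row updates its largest
  gradient entry, so rows whose signal is exhausted admit one small noise
  coefficient every few iterations.  The CV-chosen union therefore has high
  sensitivity but also a high false-discovery proportion (dozens of
  near-zero noise coefficients).  Interpreting coefficient magnitudes, or
  truncating the path earlier than the MSE optimum, mitigates this; the
  package reports full coefficient tables so users can do either.
- **Nuisance feedback under strong signal.**  Re-estimating α from the
  residuals of a heavily regularized (near-null) fit attributes unexplained
  signal to within-subject correlation.  For non-independent structures
  R^{-1} then over-amplifies within-subject contrast directions, the
  thresholded updates preferentially fit those amplified directions, and
  the re-estimated α can drift upward toward its clip over long paths.  In
  consequence the independence structure can out-predict the correctly
  specified one on strong-signal panels, and selections under different
  structures agree less than the robustness of converged GEE estimators
  would suggest.  The effect disappears as the fit approaches convergence
  or when the signal is weak relative to the noise; it is intrinsic to
  coupling in-loop moment re-estimation with slow thresholded descent.
- Only balanced complete panels, time-invariant covariates, identity link
  and continuous outcomes are supported; missing panels are an error, never
  imputed.
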