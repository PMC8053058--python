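# geetgdr

Feature selection for **longitudinal continuous outcomes** by threshold
gradient descent regularization (TGDR) on a generalized estimating equation
(GEE) quasilikelihood.

The package is aimed at biostatisticians analyzing short repeated-measures
studies with high-dimensional baseline covariates — the motivating shape is
a treatment-response study where ~30 patients have hundreds of baseline
expression values (e.g. lncRNAs) and a clinical severity score measured at
baseline and a few follow-up weeks.  The goal is a sparse set of features
whose baseline values explain the outcome trajectory, allowing the selected
set to differ by time point.

## Model and algorithm

For subject i with time-invariant covariates x_i ∈ R^P and outcomes
Y_i ∈ R^t, the marginal model is E[Y_ij | x_i] = x_i'β_j with a separate
coefficient vector per time point.  Within-subject dependence enters
through a working covariance V = A^{1/2} R(α) A^{1/2} (per-time variances A,
working correlation R: independent, exchangeable, AR1 or unstructured),
and the objective is the quasilikelihood quadratic form

    QL(β) = n⁻¹ Σᵢ (Yᵢ − μᵢ(β))' V⁻¹ (Yᵢ − μᵢ(β)).

Starting from β = 0, each of K iterations computes the negative gradient
g_jp = n⁻¹ Σᵢ X_ip [V⁻¹(Yᵢ − μᵢ)]_j, keeps only entries with
|g_jp| ≥ τ·max_l |g_jl| (the maximum taken within each time point), and
updates β_jp ← β_jp + Δv·g_jp.  Sparsity comes from the thresholding; K is
the regularization parameter, tuned by subject-level cross-validation on
held-out MSE.  Nuisance parameters (σ², α) are re-estimated from residuals
by the moment method inside the loop.  With t = 1 and working independence
the procedure is exactly conventional TGDR.  A univariate GEE screen
(robust sandwich Wald test per feature, p < 0.05) is included as the
standard comparator.  See `docs/methods.md` for assumptions, defaults and
known limitations.

## Worked example

Simulate an application-shaped panel (30 subjects, 4 time points, 40
features of which 4 carry signal), fit under the unstructured working
correlation, cross-validate K, and screen:

```sh
geetgdr simulate --n 30 --t 4 --p 40 --support 4 \
    --structure exchangeable --alpha-true 0.5 --seed 3 --out-prefix demo
# wrote n=30, t=4, P=40 dataset with 4 signal feature(s) to demo.*

geetgdr fit demo.covariates.tsv demo.outcomes.tsv \
    --structure unstructured -K 150 --out-prefix fitted
# whole-data MSE: 1.3737
# selected union (11): F0002, F0003, F0004, F0007, F0010, F0019, F0026, ...

geetgdr cv demo.covariates.tsv demo.outcomes.tsv \
    --structure exchangeable --k-grid 10,50,100 --folds 5 --seed 1 --out cv.tsv
# best K=100, tau=1.0: mean CV MSE 1.7029 (SD 0.4369), whole-data MSE 1.4676

geetgdr screen demo.covariates.tsv demo.outcomes.tsv --structure unstructured
# selected 8 of 40 features at p < 0.05
```

The fit reports the training-set MSE (1.37, against an average outcome
variance of about 2.0 here) and the union of features selected at any time point; the
truth file `demo.truth.tsv` lists which of them are real.  The CV table
gives the mean and SD of held-out MSE per grid point, mirroring how such
results are usually tabulated, and the chosen K.  The same operations are
available as library functions (`geetgdr.fit`, `geetgdr.cross_validate`,
`geetgdr.screen`, `geetgdr.generate`).

Input files are delimited tables with a header and a shared subject-ID
column: one subjects × features covariate table and one subjects ×
time-points outcome table (complete balanced panels only).

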