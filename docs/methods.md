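# Methods

## Factor coding and experimental plans

Factors are coded as (natural − centre)/half-range, so the low/centre/high
study levels map to −1/0/+1. The gradient study uses centres (37.5 % v/v,
80 % v/v, 17.5 min) and half-ranges (2.5, 5, 2.5); all model coefficients
are reported on this coded scale, which makes their magnitudes directly
comparable across factors.

The Box–Behnken plan places the 12 edge runs — all (±1, ±1) combinations
over each factor pair with the third factor at 0 — plus `n_center`
replicated centre runs (4 by default, giving 16 runs). Run order is emitted
canonically and carries no meaning: fitting is order-invariant, and the
physical study was executed in randomised order.

The 12-run Plackett–Burman plan is built from the classical cyclic
generating row (+ + − + + + − − − + −) plus the all-minus row. Columns are
lettered A…L (skipping I); in the 7-real + 4-dummy layout, B, E, G and J are
dummies. Any published PB12 plan is equivalent up to row/column permutation
and sign switches, so equivalence with an external table is checked by
column signature (six +1 and six −1 per column, pairwise orthogonality),
never by row order.

## Response-surface fitting and diagnostics

Each retention response (t_e_imp_x, t_b_imp_III, t_imp_V, and the span
t_range = t_imp_V − t_imp_I) is fitted with the full 10-term quadratic
model; the mean USP peak width ⟨W_USP⟩ uses a main-effects-only model.
Model choice is per-response configuration, and no stepwise pruning is
applied: non-significant terms stay in the model, matching how the study
results are tabulated. Estimation is ordinary least squares (statsmodels
under the hood); a rank check names the first unsupported term when the
design cannot estimate a requested model. On the 16-run plan every
main-effect column is orthogonal to all other model columns, so each fitted
main effect also equals the simple contrast Σxᵢy/8 — the test suite asserts
this identity.

Diagnostics:

* R² = 1 − SSres/SStot, adjusted R² with the usual (n−1)/(n−p) correction.
* PRESS via the leverage identity Σ(eᵢ/(1−hᵢᵢ))²; predicted R² =
  1 − PRESS/SStot. The identity is verified against an explicit
  leave-one-out refit in the tests.
* Lack of fit partitions SSres into pure error — from runs with *identical
  coded rows* (the four centre replicates; exact match on coded levels, not
  natural units) — and lack-of-fit, reported as an F test. Designs without
  replicates report no lack-of-fit statistic rather than zero.
* Coefficient significance is the two-sided t test with the residual
  degrees of freedom; flags use strict p < α.

Comparisons with the published coefficient table use an absolute tolerance
of 0.005 on coefficients and 0.0005 on R² values, because the study
responses are printed rounded to 2–3 decimals. One known artifact: the
published R² for ⟨W_USP⟩ (0.9838) was evidently computed from unrounded
data — the printed width column carries two decimals, which collapses the
centre-replicate spread and makes the linear fit on printed data nearly
exact (R² ≈ 0.99996). The width R² family is therefore not a reproduction
target; the width *coefficients* do reproduce within tolerance.

## Design-space probability mapping

The design space is defined on a natural-unit grid, inclusive arithmetic
sequences per factor (21 × 21 × 11 = 4851 points for the study ranges).
Levels are generated by integer index (min + k·step) to avoid floating
accumulation, and (max − min)/step must be integral to 1e−9.

Coefficient uncertainty is propagated by Monte Carlo. Per iteration, each
coefficient of each model is drawn independently and uniformly on
[b̂ − SE, b̂ + SE] — a uniform error of *half-width* one standard error,
centred on the estimate. This is the most literal reading of adding "a
uniform error distribution equal to the calculated standard error" to each
coefficient; an alternative reading (total width = SE) is exposed as the
`uniform_fullwidth_se` mode. Only coefficient uncertainty is propagated;
replicate noise is not added to predictions. π at a grid point is the
fraction of iterations in which **all** criteria hold jointly.

The separation factor S is always computed indirectly, as
predict(t_b_imp_III) − predict(t_e_imp_x) from the two separately fitted
retention models; it is never fitted to per-run S values.

One coefficient draw per iteration is shared across all grid points. The
marginal π at each point is unchanged by this sharing (each point still
sees n independent draws), the cost drops by the grid size, and a 2-D slice
computed with the same seed reproduces the corresponding plane of the 3-D
map exactly, because draws depend only on (seed, iteration count,
perturbation mode) and a canonical response ordering. The default seed,
20230914, is recorded in all outputs; identical seeds give bit-identical
maps.

The extracted design space is the mask π ≥ π_min (default 0.80), with
member count and bounding box reported. The 2-D slice supports off-grid
fixed values (the working point's gradient duration, 16.25 min, is not a
level of the 0.5-min discretisation) as long as they stay inside the
experimental range.

At the selected working point the predicted separation margin is thin
(S ≈ 0.022 min) relative to the propagated coefficient error, so the
point's π under the default error model sits only slightly above 0.8
(≈ 0.82 at the default seed and 5000 iterations). The package treats the
working point's design-space membership as a reported quantity, not an
assertion.

## Robustness screening

Effects are mean-at-high minus mean-at-low contrasts, identical to twice
the coded OLS slope of the saturated main-effects model (asserted in
tests). The effect standard error per response is the root-mean-square of
the four dummy-column effects; t tests use df = 4 (one per dummy), two-
sided, α = 0.05 with strict inequality. Dummies exist precisely to estimate
error in a saturated design, which makes this the natural test; Lenth's
pseudo-standard-error (df = 11/3) is available as `method="lenth"` for
studies without dummy columns. If the dummy spread is zero at floating
precision, the standard error is reported as 0 with a warning and any
nonzero effect is flagged.

A known tension on the bundled screening data: the dummy-variance t test at
α = 0.05 flags gradient duration and column temperature on the API peak
area (p ≈ 0.034/0.035) in addition to gradient duration on the impurity-V
peak area (p ≈ 0.036), while the flow-rate effect on the impurity-II peak
area reaches only p ≈ 0.115. The magnitude ordering is inherent to the
printed peak areas — the API gradient-duration |t| (3.15) exceeds the
impurity-V |t| (3.10) under any uniform rule — so a screening report from
this package lists all three flagged pairs. The `summary()` output maps
column letters to factor names so the report reads in method terms.

## Synthetic generators

`simulate_bbd_study` draws responses as exact polynomials in the coded
factors (ground truth defaults to the published coefficient set) plus
homoscedastic Gaussian noise. Default noise SDs are calibrated per response
to the centre-replicate spread of the real study: 0.066, 0.056, 0.035 and
0.026 min for t_e_imp_x, t_b_imp_III, t_imp_V and t_range. The printed
width replicates round to identical values, so the width noise default
(0.003 min) is set at the scale of the printed resolution instead.

`simulate_pb_study` draws peak areas as baseline + (effect/2)·coded level +
Gaussian noise. Baselines match the magnitudes of the real screening study;
noise SDs are back-calculated from its dummy-effect spread
(σ = RMS dummy effect × √3). The default planted pattern mirrors the
screening conclusion — flow rate acting on the impurity-II area and
gradient duration on the impurity-V area — with magnitude 5 × the response
noise SD, which puts the expected |t| near 5√3 ≈ 8.7 and makes recovery
nearly certain while inactive factors false-flag at the nominal α.

What the generators do **not** emulate: mechanistic retention models, peak
shape, drift or run-order effects, heteroscedastic or correlated noise.
Passing recovery tests therefore demonstrates correctness of the
statistical pipeline under its own assumptions, not instrument realism.

Parameter-recovery checks standardise estimation error two ways. Against
the *true* sampling standard error (noise SD known to the generator,
SE² = σ²·diag((XᵀX)⁻¹)), errors are standard normal and the ±3 SE band
covers ≈ 99.7 % of draws. Against the *estimated* SE, the standardised
error follows a t distribution with 6 residual df and ±3 SE covers only
≈ 97.6 % — the suite tests both behaviours at their own expected rates.

## Numerical choices and problem sizes

* Strict inequalities throughout for significance (p < α) and as printed
  for the CMA bounds (<, <, ≥, ≤).
* Monte Carlo iterations are processed in chunks of 1000 to bound memory;
  chunking does not affect the draws, which are generated once per map.
* Stochastic tests use fixed seeds and sizes chosen for stable unit-test
  runtimes: 60–200 replicates for recovery rates, 2000 iterations for
  seed-agreement bounds on a 5 × 5 × 3 subgrid, with the full
  4851 × 5000 map exercised once in the end-to-end suite (a few seconds,
  vectorised).
* Leverages ≥ 1 − 1e−12 make PRESS infinite (the deletion residual is
  undefined); predicted R² is NaN when SStot is zero.

## Known limitations

* LOD/LOQ by signal-to-noise needs raw chromatogram traces and is out of
  scope; published validation values ship as reference metadata only.
* Only the two design shapes used by the workflow (3-factor Box–Behnken,
  PB12) are provided; no general design catalogue.
* No analytic predictive distributions or Bayesian posterior simulation —
  design-space probabilities are purely Monte Carlo.
* The probability model ignores replicate noise in future measurements;
  π quantifies model-coefficient uncertainty only.
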