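# Methods

## The problem and the model

Prognostic gene-expression signatures for early-stage lung adenocarcinoma
(and bulk transcriptomics generally) are hard to transfer across measurement
platforms: absolute expression values from different microarrays and RNA-seq
live on incomparable scales. `pairsig` implements a signature family that
sidesteps normalization entirely by using only *within-sample relative
expression ordering* (REO). For an ordered gene pair (g1, g2) and a sample
with expression x, the pair score is

    s(g1, g2) = 0  if x[g1] > x[g2]
    s(g1, g2) = 1  otherwise  (ties score 1)

Because s depends only on the ordering of two genes inside one sample, it is
invariant under any strictly increasing transform applied to that sample's
values — which is precisely the class of distortions that monotone platform
effects induce. This invariance is the load-bearing property of the whole
method and is enforced by tests end to end (identical selected pairs,
weights, cutoff and scores with and without per-cohort distortions).

A signature is a Cox linear predictor over pair indicators,
`index = Σ_k w_k s_k`, with a risk cutoff θ; samples with index > θ are
called high risk (scores exactly at the cutoff are low risk). The shipped
published model has 10 pairs over 15 unique genes and θ = 1.35. The clinical
composite adds coded tumor stage (I=1, II=2) and age in years:
`composite = w_index·index + w_stage·stage + w_age·age`; the published
composite is `0.6657·index + 0.4445·stage + 0.0199·age` with cutoff 1.31.

## Training pipeline

`train_signature` runs, on harmonized cohorts (gene intersection, identical
order):

1. enumerate all G(G−1)/2 unordered pairs of the shared genes;
2. score the 0/1 pair matrix on the merged samples;
3. constancy filter: drop any pair whose score vector is constant within
   *any* single cohort (strict reading; `mode="pooled"` relaxes this to the
   pooled sample set). The strict rule is what protects against a platform
   that pins one gene above another across an entire dataset;
4. per-pair two-group log-rank screen, keep p < 0.05 (unadjusted, mirroring
   the source procedure; a Benjamini–Hochberg mode exists but is off by
   default);
5. LASSO-penalized Cox over the screened pairs, 10-fold cross-validation,
   penalty chosen by the 1-SE rule (`lambda_rule="min"` falls back to the CV
   minimum);
6. unpenalized Cox refit on the selected pairs — the refit coefficients are
   the signature weights (`refit=False` keeps the penalized ones instead;
   whether a published signature of this kind reports penalized or refit
   coefficients is generally not decidable from a paper's text, so both are
   provided);
7. risk cutoff: Youden's J maximized on a time-dependent ROC of the training
   scores at a reference horizon (default 1825 days = 5 years, the
   conventional clinical horizon; the source procedure names no horizon).

Every default actually used (span, horizon, penalty rule, seeds, counts at
each pipeline stage) is recorded in the trained model's metadata.

**Screening leakage.** The log-rank screen is computed on the same samples
that the CV folds later resample, exactly as in the original procedure.
Consequently the screen's selection bias leaks into the CV criterion: on
pure-noise data the screened pipeline occasionally carries a few
spuriously-screened pairs through to the 1-SE selection. The 1-SE rule
itself, exercised on unscreened noise features, selects a median of zero
coefficients. This is a property of the published procedure being mirrored,
not a defect of the implementation; users wanting unbiased selection should
screen inside each fold (out of scope here).

## Survival estimators

All estimators are implemented from first principles in `pairsig.survival`
(established survival packages appear in the test suite only, as independent
oracles).

* **Kaplan–Meier** — product-limit estimator; censoring handled by risk-set
  decrement.
* **Log-rank** — two-group statistic from hypergeometric moments at each
  distinct event time, χ² reference with 1 df; `logrank_screen` evaluates
  thousands of binary markers simultaneously with suffix-sum vectorization.
* **Cox PH** — Newton–Raphson on the partial likelihood with Breslow ties
  (Efron available). Convergence uses the squared Newton decrement
  `U'I⁻¹U < 1e-10·(1+|pll|)`: unlike a raw gradient-norm threshold it is
  invariant to covariate units, so fits with age-in-years covariates stop at
  the same relative accuracy as fits with 0/1 indicators. Step-halving
  guards the likelihood ascent; ‖β‖∞ > 15 aborts with a monotone-likelihood
  (perfect separation) error instead of returning astronomical hazard
  ratios. Wald SEs come from the observed information; the Breslow baseline
  cumulative hazard is attached.
* **LASSO-Cox** — objective `−(1/n)·pll + λ‖β‖₁`. Proximal Newton with the
  exact Breslow Hessian; the inner subproblem is cyclic soft-threshold
  coordinate descent in Gram form (a coordinate update is O(p), not O(n)),
  restricted to sequential-strong-rule candidates with full KKT verification
  afterwards, so screening never changes the solution. The λ grid is
  log-spaced over [λ_max·ratio, λ_max] (50 points, ratio 0.05), warm-started
  downwards. Coordinate-descent stops at max coefficient change < 1e-7.
  Cross-validation uses the Verweij–van Houwelingen partial-likelihood
  deviance `−2·[pll_all(β_k) − pll_train(β_k)]` per left-out fold,
  normalized per event with event-count weights across folds (the
  unnormalized fold deviances carry large fold-specific offsets that would
  inflate the SE and push the 1-SE rule to λ_max). Covariates are *not*
  standardized by default — 0/1 pair indicators keep their per-flip
  interpretation — with a `standardize` flag.
* **Time-dependent ROC** — cumulative-case / dynamic-control definition at a
  horizon, estimated with the nearest-neighbor bivariate survival smoother:
  the conditional survival S(t|X=x_i) is a weighted Kaplan–Meier over
  samples whose marker percentile is within `span` of sample i (default
  span 0.25·n^(−0.20), the conventional choice). Candidate thresholds are
  midpoints between adjacent distinct marker values; small non-monotonic
  wiggles of the raw estimator are removed by isotonic clipping; AUC by
  trapezoid with (0,0) and (1,1) endpoints. The cutoff rule is Youden's J
  with ties broken toward the smaller threshold.
* **Concordance** — Harrell's C over censoring-admissible ordered pairs
  (earlier event vs later time, or event vs same-time censored); tied
  markers count one half. Two correlated C statistics on the same samples
  are compared with a leave-one-out jackknife of the paired difference
  (per-sample pair contributions are removed in O(1) from precomputed row
  sums, so the jackknife is O(n²) overall) and a two-sided normal p-value.
  The jackknife variance is validated against a 1000-replicate bootstrap
  (within 20%) and its type-I error against 500 null simulations.
* **RMST** — area under the KM step function on [0, τ], exact for the step
  function. The model-based RMS curve for a scalar index x integrates
  `S₀(t)^{exp(βx)}` with the Breslow baseline; a model-based curve (rather
  than kernel-smoothed empirical values) was the design choice where the
  construction was open. Grid points outside the observed index range
  trigger an extrapolation warning.

## Synthetic cohorts

`simulate_cohorts` emulates the study setting — about a dozen microarray
cohorts on different platforms merged without normalization — with known
ground truth:

* latent log-normal expression field with gene-specific location and scale,
  shared across cohorts;
* five default true pairs with generating log-hazard ratios
  (1.0, −1.0, 0.9, −0.9, 0.8); the two genes of a true pair share a
  per-sample latent factor (co-expression) and a mean offset calibrated so
  the indicator's minority frequency lands in a 25–45% band — independent
  genes would make many indicators near-constant and the features
  degenerate;
* age ~ N(65, 9) years truncated to [35, 90]; stage II prevalence 0.30; sex
  balanced with no effect on hazard;
* Weibull proportional-hazards survival by inverse-transform sampling
  (shape 1.2, scale 8500 days) with linear predictor
  `Σβ_j z_j + 0.03·(age−65) + 0.7·(stage−1)` — per-year age hazard ratio
  ≈1.03 and stage-II hazard ratio ≈2, the magnitudes typical of early-stage
  lung adenocarcinoma cohorts; uniform right censoring on (0, 5500) days.
  The scale/censoring pair was calibrated once so that the defaults yield
  ≈37% observed events and a median follow-up near 4.6 years, matching the
  targeted clinical setting;
* per-cohort strictly increasing platform transforms (affine, power,
  logistic, monotone piecewise-linear spline) applied to all of a cohort's
  values after the indicators are fixed — the transforms change every
  absolute value but no within-sample ordering. `apply_distortions=False`
  regenerates the identical latent data undistorted;
* `tie_fraction` snaps that fraction of values to integers to exercise the
  tie-scores-one convention (default 0: continuous values).

What the generator does *not* emulate: probe-level artifacts, missing
values, batch effects that are not monotone within a cohort,
non-proportional hazards, correlated censoring, or dependence between the
signature genes and the clinical covariates. Passing tests therefore
demonstrate correctness of the machinery and recoverability under a
well-specified PH world, not clinical performance on real cohorts.

## Experiment sizes used by the test suite

Chosen as the package's own desk-scale study conditions: signal recovery
uses 50 seeded runs at n = 800 (4 cohorts × 200) with the five default
pairs and no clinical hazard (the pairs-only hazard keeps the refit Cox
correctly specified, so coefficient recovery is not confounded with
omitted-covariate attenuation); coefficient recovery averages 20 runs at
n = 1500; the clinical-composite comparison runs 50 seeds of 6 cohorts ×
350, training on four cohorts (n = 1400) and comparing C-indices on the two
held-out, differently-distorted cohorts (n = 700).

## Known limitations

* Breslow (not exact) handling of tied event times; Efron is available for
  the unpenalized fit only.
* The nearest-neighbor ROC estimator is O(n²) in memory and time; fine to a
  few thousand samples, not for biobank scale.
* The jackknife C-comparison assumes asymptotic normality of the paired
  difference; very small cohorts or near-degenerate censoring patterns will
  make the p-value unreliable.
* `rms_curve` extrapolates the baseline beyond the observed index range only
  with a warning; extrapolated values inherit no statistical guarantee.
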