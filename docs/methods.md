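# Methods

This note documents the statistical model behind `owlitr`, the estimation
choices that were genuinely open, the synthetic-data conditions the test
suite runs under, and known limitations.

## Estimand and estimator

The target is the optimal individualized treatment rule
`d*(z) = argmin_d E[Y | treated per d]` over linear rules
`d(z) = 1{b₀ + bᵀz ≥ 0}` on six standardized baseline factors, with 1 =
telehealth and 0 = in-person and lower outcome = better. In a randomized
trial the value of a rule is identified by inverse-probability weighting on
the subjects whose assigned arm coincides with the rule's recommendation.

Outcome Weighted Learning converts value optimization into weighted
classification. Because the outcome is a 0–80 symptom scale with lower
scores better, the reward transform is `B = 80 − Y`, anchored at the
instrument's printed maximum, so every weight is nonnegative and "larger is
better". OWL is *not* invariant to this choice: adding a constant to `B`
changes the finite-sample rule (only the Fisher-consistent limit is
unaffected). Residualized/augmented variants that remove the nuisance mean
are deliberately out of scope; the consequences are visible in the
simulation results below and in the sample sizes needed for recovery.

Per-subject weights are `w = B·r/π`:

- `r` — inverse probability that the 6-month outcome was observed, from a
  main-effects logistic (IRLS via statsmodels GLM; design = intercept + six
  standardized factors + arm). Probabilities are floored at 0.05 (logged
  positivity safeguard) and `r = 0` for missing outcomes, which removes
  those subjects from every weighted sum. Weights are unstabilized; the
  Hájek normalization downstream absorbs the marginal-rate numerator a
  stabilized version would add. Perfect separation falls back to a
  ridge-regularized logistic fit with a warning.
- `π` — empirical frequency of the arm actually received (not the nominal
  ½), configurable.

### Convex solver

The penalized weighted hinge loss with unpenalized intercept is exactly a
weighted soft-margin linear SVM after the reparameterization
`C = 1/(2λn)`; the fit is delegated to libsvm (scikit-learn `SVC`, linear
kernel), which handles per-sample weights and leaves the intercept
unpenalized. Two numerical facts shaped the implementation:

1. The objective is invariant to jointly scaling `(w, λ)` by a positive
   constant. Weights are therefore normalized to unit mean before solving,
   and the tuning grid is read on that scale-free axis — otherwise the
   meaningful λ range would drift with the outcome scale (raw OWL weights
   average ~80–150 here).
2. libsvm's internal KKT stopping test often fails to trigger with
   fractional per-sample weights even when the iterate has converged (we
   observed relative duality gaps ~1e-7 at status "not converged").
   `fit_owl` therefore caps iterations and certifies the solution itself
   with an explicitly computed primal–dual gap; the certificate includes an
   intercept correction for the slight dual-feasibility violation at early
   stopping and must be below 1e-4 (relative). It is a guard against
   gross non-convergence; actual solution accuracy, verified against
   independent optimizers, is far better.

Two independent reference optimizers are shipped for verification only:
a Polyak dynamic-target subgradient method, and a smoothed-hinge
continuation (softplus temperature 1e-1 → 1e-8, L-BFGS at each stage; the
smoothing bias in the objective is O(t)). `reference_minimize` returns the
best of the two (plus a warm-started variant) and agrees with the SVM fit
to ~1e-6 relative on random small instances; a pure subgradient method
alone plateaus around 5e-4 on ill-conditioned small-λ instances, which is
why the continuation route exists.

Degenerate inputs are handled explicitly: all-zero weights return the zero
rule (all-telehealth by the tie convention, with a warning); weight
confined to one arm returns that fixed arm, the objective's minimizer among
intercept-only rules. Tie at decision score exactly 0 assigns telehealth,
matching the indicator convention `score ≥ 0`.

### Penalty selection

Leave-one-out (jackknife) cross-validation over a 13-point grid
`2⁻⁸ … 2⁴` (log-spaced; spans near-unregularized fits through collapse to
a single fixed arm). Each candidate is scored by the Hájek IPW value of the
left-out assignments on the symptom scale; the minimizing λ wins and ties
break toward the larger penalty. For large n a `max_folds` option
subsamples the folds without replacement — a purely computational
concession used at n ≥ 1000 in the test suite (50–150 folds); the default
is the full jackknife.

### Value estimation and inference

The value estimator is the Hájek (normalized) IPW form; it is invariant to
outcome location shifts, reduces exactly to an arm's sample mean for a
fixed-arm rule on complete data, and is affine-equivariant. The
Horvitz–Thompson (unnormalized) form was rejected for its scale
sensitivity.

Inference uses a nonparametric bootstrap (default B = 1000) stratified by
arm, conditioning on the realized randomization ratio. Within each
replicate the observation model, weights, and the statistic are recomputed;
the decision rule is held fixed. Re-running jackknife-tuned OWL inside
every replicate would multiply cost by ~10⁴ and the reported intervals are
standard errors *for the value parameters of a given rule*, so rule
uncertainty is deliberately not propagated — out-of-sample validation is
the appropriate tool for that and is out of scope. Intervals are Wald:
estimate ± 1.96·SE, symmetric by construction. Replicates on which the
statistic fails (e.g., no matched subject) are dropped and logged; more
than 10% failures aborts.

An important related caveat: the in-sample value of a *data-driven* rule is
optimistically biased (the rule is selected on the same data it is scored
on). The test suite measured this directly — refitting the rule on each
null-scenario replicate gives contrasts of −0.7 to −1.2 points rather than
0 — so null-behavior checks hold the rule fixed across fresh replicates,
where the contrasts are provably mean-zero.

## Synthetic trial generator

The generator emulates a two-arm psychotherapy-delivery trial in women
veterans with PTSD:

| component | default | basis |
|---|---|---|
| n | 122 | study size |
| randomization | Bernoulli(½) per subject | 1:1 allocation |
| age | N(42.80, 11.61²) clipped to [18, 90] | reported marginal |
| White | Bern(0.279) | reported marginal |
| disability | Bern(0.639) | reported marginal |
| rural | Bern(0.344) | reported marginal |
| low income | Bern(0.492) | share of income brackets < USD 35k |
| baseline PCL-5 | N(52.74, 12.81²) clipped to [0, 80] | reported marginal |
| outcome noise SD | 22.0 | calibrated by MC so the marginal 6-month SD ≈ 21.8 |
| observation model | logit p = 0.85 − 1.5·z_age − 0.9·z_pcl + 0.2·A | ~35% missing, MAR |

Covariates are generated independently (only marginals are reported for the
real study; a correlation hook would be a config extension). Clipping, not
rejection, enforces the age bounds so the configured mean survives (the
induced shift is ~0.06 years).

Outcomes follow `Y = μ₀(z) + A·τ(z) + ε`, clipped to [0, 80], with both
surfaces linear in the *population*-standardized covariates (binary columns
scaled by √(p(1−p))). Linear surfaces make the true optimal rule linear —
the estimator's own hypothesis class — so regret recovery is a fair test.
The default interaction `τ(z) = 2 + 5·z_age + 3·white_z − 3·low_income_z +
1·z_pcl` makes telehealth slightly worse on average (+2 points) but
markedly better for younger, non-White, low-income subjects
(heterogeneity SD ≈ 6.6 points), qualitatively mirroring the
access-to-care story the prescriptive factors encode.

The default MAR strength (complete-case bias ≈ −2.9 points against a
sampling SD of ≈ 0.9 at n = 1000) was set so that "IPW beats the
complete-case mean in ≥ 90% of replicates" is a property of the estimator,
not a coin flip: under weaker MAR the two estimators differ by less than
sampling noise and the comparison is uninformative.

Ground truth: policy values include outcome noise and the 0–80 clipping
(they are the exact estimand of the generated data), computed by Monte
Carlo with common random numbers across rules; regret uses the noise-free,
unclipped surfaces, where per-draw gaps are nonnegative by pointwise
optimality of the true rule. In a single-covariate scenario
(`τ = c·z_age`) the anti-optimal rule's regret has the closed form
`c·√(2/π)`, used as an analytic oracle.

### Named test scenarios

- **strong interaction** — τ slopes (8, 5, 0, 0, −5, 2), noise SD 10,
  control surface centered at 40 (clipping never binds), complete
  outcomes. At n = 2000 the learned rule's regret is well under 1 symptom
  point. Under the default 21.8-point outcome SD vanilla OWL needs far
  larger samples: with `B = 80 − Y` the signal (±10–20 points of τ) rides
  on a ~47-point positive offset plus 22 points of noise, and measured
  regret at n = 2000 stays near 4 points — a documented consequence of the
  unresidualized reward transform, not an implementation artifact.
- **uniformly better arm** — τ ≡ ±8, noise SD 12, complete outcomes; the
  jackknife must select a collapsing penalty and assign ≥95% of subjects
  to the better arm at n = 1000.
- **null** — τ ≡ 0: every rule has the same true value; fixed-rule
  contrasts are mean-zero across replicates.
- **single covariate** — age-only effect with age centered 6 SD from its
  bounds, for the closed-form regret check.

## Problem sizes used by the test suite

Solver cross-checks: 50 random instances (n ≤ 30) plus 20 margin-separable
instances (n = 12). Estimator unbiasedness: 1000 replicates at n = 200.
IPW win rate: 500 replicates at n = 1000. Regret recovery: one n = 2000
fit (50-fold subsampled jackknife) against a 100,000-draw oracle.
Bootstrap coverage: 200 replicates at n = 300 with B = 200 per replicate
(B = 1000 for the single-dataset determinism check). These sizes keep the
full suite under ~10 minutes on one core while leaving Monte-Carlo
tolerances (3 SE) meaningfully tight.

## Preprocessing contracts

Race collapses to a White indicator (Black and all other races → 0);
annual household income collapses to a low-income indicator at the
< USD 35,000 threshold (the five brackets below it); labels are
whitespace/dash-normalized and anything unrecognized raises with the
offending value. Covariate missingness (a few percent in practice) is
imputed deterministically — mode for binaries (ties → 1), mean for
continuous — with counts logged; multiple imputation would be immaterial
at that rate and would break exact reproducibility of the rule.
All six factors, binaries included, are standardized to mean 0, SD 1
(n − 1 denominator); the training means/SDs are embedded in the serialized
rule so a saved rule is self-contained for scoring new individuals.
Whether published coefficients of such rules are meant to be applied to
raw or training-standardized values is genuinely ambiguous in the field's
reporting convention; this package always standardizes with the stored
parameters (`assign_raw`) and records them alongside the coefficients.
Intention-to-treat: every randomized row is retained; completion status is
ignored; missing outcomes are masked, never dropped.

## Known limitations

- Vanilla OWL's reward-shift sensitivity (above): sample-size requirements
  grow quickly with outcome noise; no residualization or doubly robust
  augmentation.
- The bootstrap does not propagate rule-selection uncertainty (rule held
  fixed), and in-sample values of data-driven rules retain selection
  optimism.
- Linear kernel only; two arms only; no correlated-covariate generator
  default; no survey weights or item-level instrument scoring.
- The observation model is main-effects logistic; under model
  misspecification the IPW correction is only approximate (no doubly
  robust backup).
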