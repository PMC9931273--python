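# Methods

This note documents the statistical machinery in `svscore`, the choices
made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Model and loss

All scores are built on binary-outcome logistic regression. The
"optimal" model is the unpenalized maximum-likelihood fit on the
dummy-encoded candidate design (each categorical variable with L
declared levels contributes L−1 indicators against its first level).
Model loss is the **per-observation mean** negative log-likelihood in
nats, so the nearly-optimal band is sample-size free; predicted
probabilities are clipped away from {0,1} by machine epsilon before
taking logs. Fitting is deterministic Newton iteration (statsmodels);
a fit is rejected when the design is rank-deficient, when the
post-convergence mean-gradient norm exceeds 1e−4, or when coefficients
diverge (separation), naming the offending columns.

## The nearly-optimal (Rashomon) ensemble

A coefficient vector θ (intercept included) is nearly optimal when
`L(θ) ≤ (1+ε)·L(β̂)` with ε = 0.05 by default. Candidates are drawn from
`N(β̂, u·Σ̂)`, Σ̂ the inverse observed information, and rejection-sampled
against the band; exact ties with the optimum are kept, so accepted
loss ratios lie in [1, 1+ε]. The isotropic multiplier `u` is the single
exploration knob: it preserves the MLE correlation structure while
widening the proposal. `tune_scale` picks the smallest `u` (geometric
grid from 0.25 upward) whose 50-draw pilot occupies all five quintiles
of the band; when no `u` manages that — typical when the band is much
wider than the sampling distribution can reach, as in small cohorts
with many parameters — the best-covering `u` is used and a warning
raised. Defaults: M = 350 models, max 2000·M draws. Diagnostics record
draws attempted, acceptance rate and band-decile occupancy. No claim is
made that the sample covers the full Rashomon set uniformly; it is an
empirical exploration of the band around the MLE.

## SAGE importance per model

A variable's reliance for a model f is its Shapley value in the game
`v(S) = L_∅ − L_S`, where `L_S` is the mean loss of f's predictions
with the variables outside S marginalized: the prediction for a case is
`mean_b f(x_S, b_{S^c})` over a fixed background sample (the empirical
marginal / interventional convention). All indicator columns of a
categorical variable move as one player, so importance is per clinical
variable. The background sample (default 512 rows) is drawn once from
the training split — the models' reference distribution — and shared by
every ensemble member, so the M games are identical and poolable.

Estimation is permutation sampling: each of `n_permutations` (default
256) Monte-Carlo iterations draws one random player permutation and a
minibatch (default 32) of evaluation cases, cycled through the
evaluation sample in reshuffled epochs so all cases are covered
equally; walking the permutation, a variable's increment is the loss
drop when it becomes known. The value is the mean iteration increment
and its standard error the iteration SD over √T, which reflects both
permutation and evaluation-case noise. Convergence is budget-based
(fixed T, SE reported) rather than adaptive, for reproducibility. A
variable with an exactly-zero coefficient block produces bit-identical
predictions, hence an exactly zero value and SE — the null-player axiom
holds exactly. Per-iteration increments telescope, so values sum to
`L_∅ − L_full` up to case-coverage error (checked to 3 combined SEs).

An exact oracle (`exact_shapley`, full 2^d enumeration, refused above
d = 10) validates the estimator on small problems. Per-model seeds
derive from the SAGE seed and a hash of the model's own coefficient
vector, so results are independent of ensemble order and identical
members give identical rows.

Evaluation uses the leading `eval_rows` of the validation split
(default 3500, capped at the split size), mirroring the first-cases
convention rather than a random subsample.

**Collinearity.** Generalized VIFs come from the determinant-ratio
formulation on the centred dummy design; the comparable score
`(GVIF^(1/(2·df)))²` reduces to the classical VIF at df = 1. Variables
scoring above 2 take the absolute SAGE value as their reliance, since
collinearity can push a genuinely used variable's raw value negative.

## Pooling, prediction intervals, ranking

Per variable, the M (value, σ) pairs are pooled by non-iterative
DerSimonian–Laird: τ̂² = max(0, (Q − (M−1))/c), inverse-variance weights
1/(σ² + τ̂²), and the 95% prediction interval
`mean ± t_{0.975, M−2}·√(τ̂² + SE_mean²)` (Higgins-style; at M = 350 the
t-quantile is effectively normal). A variable observed at exactly zero
with zero SE in every model yields the degenerate PI {0}. Variables are
**significant** iff the PI lower bound is strictly positive; when all σ
are zero but values differ, τ̂² falls back to the sample variance.

Within each model, variable j beats k when
`(mr_j − mr_k)/√(σ_j² + σ_k²) > z_{0.975}` (two-sided α = 0.05, the
package's reading of "significantly larger"; σ_j = σ_k = 0 pairs fall
back to strict value comparison, and no multiplicity correction is
applied across the d(d−1)/2 pairs). Win counts are competition-ranked
(ties share the smallest available integer), ranks are averaged across
models, and the final ordering is ascending average rank with ties
broken by higher pooled mean, then name. Filtering happens **after**
ranking; a sensitivity mode can rank all variables unfiltered.

## Scorecard construction

Continuous variables are binned at the training 5/20/80/95th
percentiles by default (five bins; 1-D k-means with centre-midpoint
cuts is the alternative), intervals closed below and open above.
Duplicate cuts collapse; categories empty in training merge into their
lower neighbour with a warning. A logistic model refit on the binned
design gives per-category coefficients; within each variable the
minimum is subtracted (guaranteeing a 0-point row), one global factor
scales the summed per-variable maxima to the cap (default 100, kept
configurable), and rounding drift on the maxima is repaired by largest
remainder so the maximum attainable total is exactly the cap. The
parsimony curve adds ranked variables one at a time and suggests the
smallest size after which the next validation-AUC increment falls below
1%; the full curve is retained for manual override, and cut-offs can be
fine-tuned (re-binned, refit, re-scaled) without changing the cap.

## Evaluation

AUC is the Mann–Whitney rank statistic (ties half-counted), identical
to trapezoidal integration of the empirical ROC. Confidence intervals
are percentile bootstrap over case resamples (default 1000; one-class
resamples redrawn up to 10 times). The operating threshold is the ROC
point nearest the (0,1) corner, ties resolving to the lower threshold,
with `score ≥ threshold` predicting positive; reported F1 uses the
outcome-positive class as the positive class.

## Synthetic cohorts and what the tests show

Real development cohorts for clinical scores are rarely shareable, so
validation runs on generated cohorts: continuous vitals/labs (normal,
log-normal), utilisation counts (Poisson), binary comorbidities,
ordered categories (multinomial), one additively constructed collinear
pair (child = ρ·z_parent + √(1−ρ²)·noise, targeting VIF = 1/(1−ρ²)),
and a Bernoulli outcome under a logistic model with effects planted on
the standardized scale. The default intercept −1.62 targets a ~16.5%
base rate, a realistic event rate for 30-day readmission/death; signal
effects span |β| ∈ [0.3, 1.0]. Ground truth (coefficients, signal/noise
labels, distribution parameters) is recorded with every cohort.

The acceptance-scale runs use n = 5000 cohorts, M = 100 models,
evaluation on the full 500-row validation split, 128 background rows
and 400 permutations — sizes chosen so each stage's Monte-Carlo error
is small against the effects being detected while the whole suite runs
on a laptop. Two honest caveats at this scale:

- the 5% loss band around an n = 3500-row fit is wide in coefficient
  space, so nearly-optimal models genuinely disagree about weak
  predictors; a |β| = 0.3 signal sits near the edge of significance and
  its PI verdict can flip with the realized validation split;
- the |SAGE| rule makes a collinear *proxy* of a true signal (the
  planted ρ = 0.8 child) register positive reliance — expected
  behaviour of the absolute-value convention, not a defect, but a
  reminder that it measures usefulness-to-the-model, not causal effect.

Synthetic cohorts reproduce the structural variety of EHR extracts,
not any real cohort's joint distribution; passing tests demonstrate
correctness and recovery behaviour of the machinery, not clinical
performance.

## Known limitations

Binary outcomes only (no survival extension); no regularized fits; no
DeLong analytic CI or calibration metrics; no per-pair multiplicity
correction in the ranking; missing values are imputed only for
continuous variables (training-split median, even counts averaging the
middle pair) — missing categorical values are an error by design.
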