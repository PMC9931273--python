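# svscore

Sparse, integer-point clinical risk scores built with a **Shapley
variable importance cloud** over nearly-optimal logistic models.

## The problem

Clinical risk scores (think LACE-style scorecards for 30-day
readmission or death) are logistic regressions whose coefficients have
been binned, scaled and rounded into integer points a clinician can sum
at the bedside. The hard part is choosing *which* of the dozens of
candidate EHR variables deserve points. Rankings from a single machine
learning model (e.g. a random forest) routinely disagree with the
score-generating logistic model itself, burying variables that matter
and promoting ones that do not.

`svscore` ranks variables by studying a whole *cloud* of well-performing
logistic models instead of one:

1. **Nearly-optimal model sampling.** Fit the maximum-likelihood
   logistic model on all candidates, then rejection-sample `M`
   coefficient vectors from a multivariate normal centred at the MLE
   (covariance `u·Σ̂`), keeping θ only when its training loss satisfies
   `L(θ) ≤ (1+ε)·L(β̂)` with ε = 5% — an empirical Rashomon set.
2. **Per-model importance.** For each model, every variable's reliance
   is its SAGE value: the Shapley value `φ_j` of the cooperative game
   `v(S) = L_∅ − L_S`, where `L_S` is the mean logistic loss with the
   variables outside `S` marginalized over a background sample.
   Collinear variables (generalized VIF comparable score
   `(GVIF^(1/2df))² > 2`) use `|φ_j|`. Estimation is by permutation
   sampling with a Monte-Carlo standard error `σ_j`; an exact `2^d`
   enumeration oracle backs the estimator for small `d`.
3. **Pooling and significance.** The `M` per-variable `(φ, σ)` pairs
   are pooled by DerSimonian–Laird random-effects meta-analysis; the
   95% prediction interval `mean ± t₀.₉₇₅,M₋₂·√(τ̂² + SE²)` brackets the
   importance a *new* nearly-optimal model would assign. Variables
   whose interval touches zero are filtered out.
4. **Ensemble ranking and scorecard.** Within each model, variables are
   competition-ranked by the number of pairwise wins
   (`(φ_j−φ_k)/√(σ_j²+σ_k²) > z₀.₉₇₅`); average ranks across models give
   the ensemble ranking. Continuous variables are binned at training
   quantiles, a logistic model is refit on the bins, and coefficients
   are shifted (per-variable minimum → 0 points), globally scaled and
   rounded so the maximum attainable total is exactly 100. A parsimony
   curve (validation AUC vs. number of variables) picks the sparsest
   adequate score.

## Worked example

`examples/03_build_scorecard.py` builds a score on a synthetic
5000-encounter EHR-like cohort with five planted signal variables:

```
parsimony curve (validation AUC as variables enter):
  1. +ed_visits      AUC=0.685
  2. +sodium         AUC=0.738
  3. +renal_disease  AUC=0.760
  4. +triage         AUC=0.774 <- suggested size
  5. +resp_rate      AUC=0.781

scoring table (max attainable total = 100):
| Variable | Interval | Points |
| --- | --- | --- |
| ed_visits | <2 | 0 |
|  | [2, 3) | 19 |
|  | >=3 | 35 |
| sodium | <131.482 | 37 |
|  | [131.482, 134.738) | 27 |
...
test AUC 0.788 (95% CI 0.753-0.817)
optimal threshold >= 35: sens 0.76, spec 0.69, accuracy 0.71
```

Reading it: adding a fifth variable would improve validation AUC by
less than the 1% threshold, so the suggested score keeps four. A
patient with 2 prior ED visits, sodium 133, renal disease and triage P2
scores 19+27+17+3 = 66; scores at or above the printed threshold
(chosen as the ROC point nearest the (0,1) corner) predict the outcome.
The other examples cover cohort generation, the importance cloud with
its bar/violin plots, patient scoring, and the one-call pipeline with a
random-forest comparison arm.

A thin CLI wraps the same library:

```bash
svscore synth --n 5000 --seed 7 --out cohort.csv --truth truth.json
svscore run --config run.yaml --cohort cohort.csv --schema schema.yaml
svscore score --table out/scoring_table.csv --patients patients.csv
```

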