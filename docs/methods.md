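# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `circastress`.

## Study design being modelled

A prospective cohort of hospital workers completes a baseline battery
(PSS-4 perceived stress 0–16; CD-RISC-2 resilience; 2-item emotional
support, 2–10; 2-item quality of life; Life-Orientation-Test optimism),
weekly PSS-4/QoL surveys, daily exposure surveys (care type, symptoms,
mobility), and wears a smartwatch that records ultrashort SDNN (ms) a few
times per day at arbitrary clock times. A daily community COVID-19 case
series provides an environmental stressor covariate.

## Period alignment

Weekly surveys arrive irregularly (5–10-day gaps, skipped weeks). Each
survey anchors an inclusive window: the day after the previous survey when
the gap is < 7 days, otherwise the 6 days up to and including the survey
date. Consequences, verified by property tests: windows never exceed 7
inclusive days, never overlap within a participant, and days falling in
no window (gaps > 7 days) are excluded from every summary rather than
imputed. The first period of a participant has no predecessor; we anchor
it at max(survey date − 6 days, enrollment date). This is a convention —
the windowing rule itself is silent about the first survey — and it
mirrors the ≥ 7-day branch. Daily summaries are arithmetic means over
*observed* days only; a period without daily responses yields missing
values, never zeros. Post-diagnosis flags compare the period's survey date
with the diagnosis date: within (d, d+14] for the 2-week flag, (d, d+28]
for the 4-week flag, and any later period for the cumulative flag; the
4-week flag deliberately subsumes the 2-week flag so model stages can
choose which to enter.

## Occupation classification

Care types `covid_facing` and `noncovid_facing` make a day clinical;
working without patient contact, remote work, and non-working days are
nonclinical. One clinical day makes a period clinical; one clinical period
makes a participant clinical (trainee if resident/fellow, otherwise
nontrainee); everyone else is staff. A period with no daily responses is
nonclinical, because the rule counts *reported* clinical days. A resident
or fellow who never reports patient care is staff: the staff definition is
applied literally rather than by enrollment role.

## Longitudinal stress model

For subject i at period t:

    y_it = x_it' β + b_i (+ s_i · c_it) + e_it
    b_i ~ N(0, τ²),  s_i ~ N(0, ω²),  Corr(e_it, e_is) = φ^{|t−s|}

with the continuous AR(1) distance taken over the **period index**, not
calendar days, and residual variance σ². Estimation is REML: β and σ² are
profiled out, and the variance ratios (τ²/σ², ω²/σ²) and φ are optimised
on log and logistic scales by L-BFGS-B from three starting points
(objective tolerance ~1e-12). Per-subject covariance blocks that share an
identical (ordering, random-effect design) pattern are factorised once,
which makes balanced simulated designs nearly free; with no residual
correlation the within-subject solve uses the Woodbury identity with a
q×q capacitance matrix, so fits on tens of thousands of sparse HRV rows
cost O(subjects · p²) per objective evaluation. The test-suite proves the
profiled objective equals a brute-force dense multivariate-normal
restricted likelihood to 1e-8 at arbitrary parameter points, and that the
degenerate case (no random effects, φ = 0) reproduces OLS exactly.

Random-effect covariance is diagonal (independent intercept and slope).
An intercept–slope correlation could matter in principle; it is omitted
because the slope enters only through its variance test and none of the
reported quantities depend on the correlation.

Inference conventions:

* **Marginal ("Type-III") tests** are Wald chi-squares on each term's
  coefficient block. The univariate screen fits one candidate at a time
  with a random intercept and CAR(1) errors and selects P < .10.
  Continuous covariates are standardized by default (effects are per
  covariate SD); a flag disables this.
* **Random-slope LRT**: the multivariate model is fitted with and without
  an independent per-subject slope on the standardized mean case count
  (identical fixed effects, both REML, so the restricted likelihoods are
  comparable); the reference distribution is the 50:50 mixture of a point
  mass at zero and χ²₁ because the null pins a variance at the boundary.
  Plain χ²₁ is available (`boundary=False`) and is conservative.
* **Marginal means and contrasts** are counterfactual averages: the model
  frame is copied, the focal column is pinned, the design matrix rebuilt,
  and its rows averaged. Continuous covariates therefore sit at their
  observed values and factors keep their observed weights (the
  "proportional" reference grid). Wald z statistics throughout; no
  multiple-testing correction anywhere, since all p-values are reported
  nominally.
* **Stratified effects** use one focal column per tertial
  (focal × indicator) instead of a literal interaction term, so a tertial
  in which the focal exposure never varies is dropped with a warning
  instead of aliasing the design.
* **Tertials** cut at the 1/3 and 2/3 sample quantiles with lower
  interpolation; ties go to the lower tertial, which keeps the labels
  exhaustive and deterministic on integer-scored instruments. All-identical
  scores raise an error.
* **Missing covariates**: listwise deletion per model, with dropped-row
  counts logged.

Approximate standard errors for the covariance parameters (φ, log variance
ratios) come from the central-difference Hessian of the profiled REML
objective; the residual-variance uncertainty uses the large-sample
log-scale SE √(2/n_subjects). These are profile approximations, adequate
for the 3-SE recovery checks they serve; they are not used for any
reported p-value.

## Mixed-effect cosinor model

SDNN at clock time t (hours since local midnight, single configured time
zone) follows Y(t) = M + A·cos(2πt/24 + φ) + e(t) with fixed τ = 24 h.
The standard linearisation x = cos(2πt/24), z = sin(2πt/24) gives
Y = M + βx + γz with β = A·cos φ, γ = −A·sin φ; group tertials enter as
main effects and group×(x, z) interactions, adjustment covariates as main
effects, and the subject as a random intercept (REML, same engine as
above). Group parameters come from counterfactual rows: M_g pins
(x, z) = (0, 0), and β_g, γ_g are the derivative rows for x and z; the
inverse relationship A = √(β²+γ²), φ = atan2(−γ, β) is applied with φ
wrapped into (−2π, 0] (so −φ·24/2π is the clock time of the daily peak).
A flat rhythm (β = γ = 0) yields amplitude 0 with the acrophase explicitly
flagged undefined. Delta-method SEs are attached per group; the bootstrap
below is the primary inference.

**Bootstrap group comparison.** Per iteration: draw independent unit-mean
exponential weights per *subject* (Bayesian bootstrap; subject-level
weighting preserves within-subject correlation), refit by weighted least
squares with the variance components frozen at their full-data REML
estimates, rebuild each group's (M, A, φ), and record all pairwise
differences, wrapping acrophase differences into (−π, π]. The two-sided
p-value is 2·min(frac ≤ 0, frac ≥ 0) with the (r+1)/(n_boot+1)
continuity correction. Freezing the variance components makes each
iteration a closed-form GLS solve from precomputed per-subject
cross-products, so the default 1000 iterations run in milliseconds;
resampling subjects with replacement is available as an alternative mode
(`mode="resample"`). Iterations whose weighted normal equations are
singular are redrawn and counted; more than 5% failures is a hard error.
Calibration is verified empirically in the test-suite: under identical
groups the rejection rate at α = .05 stays within [0.02, 0.09] for MESOR,
amplitude, and acrophase, and a halved amplitude at 60 subjects/group is
detected with power ≥ 0.8.

Subjects with fewer than `min_obs` recordings (default 10) are excluded
before fitting; the threshold is configurable and the exclusion warned.

A note on the linearisation: the published description of this model
family prints both regressors as sines, which is rank-deficient; the
cosine/sine pair used here is the standard cosinor linearisation and is
what the inverse relationship assumes.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume, with
defaults fixed at the study conditions:

| knob | default | basis |
|---|---|---|
| n_subjects | 361 | published cohort size |
| study_days | 60 | mean follow-up |
| weekly gap | 5–10 days | stated survey cadence |
| baseline traits | age 36.8 (10.1); BMI 25.7 (5.8); 69.3% female; PSS-4 5.3 (3.1); CD-RISC-2 5.7 (1.4); optimism 19.1 (4.2); emotional support 6.8 (1.5); QoL 7.8 (1.5) | published baseline table |
| stress effects (per trait SD) | case count +0.8, emotional support −0.6, resilience −0.5, QoL −0.5, intercept 5.3 | published effect directions/magnitudes |
| stress AR(1) φ | 0.6 | plausible weekly autocorrelation |
| stress subject SD / residual SD | 1.5 / 2.0 score units | splits the PSS-4 SD between stable and occasion variance |
| HRV cosinor | M = 40 ms; tertial amplitudes (12, 10, 6) ms; acrophases (−2.0, −2.0, −2.6) rad | flatter, later rhythm in the high tertial |
| HRV subject SD / noise SD | 8 / 10 ms | sparse ultrashort recordings are noisy |
| HRV sampling | Poisson(4)/day, uniform clock times | free choice; density unreported in this design |
| daily response rate | 0.7 | realistic app adherence |
| case curve | log-normal-shaped single wave, peak 6000/day on day 20 | one epidemic wave |

Weekly PSS-4 is generated continuously (fixed effects on z-scored
baseline traits + subject intercept + AR(1) residual over the survey
sequence, with the period-mean case count built by the same windowing rule
the analysis uses) and then rounded and clamped to 0–16, keeping the
Gaussian model approximately valid while emitting legal scores. SDNN is
generated directly from the cosinor (no beat-to-beat simulation) and
floored at 0. All randomness flows from one master seed through named
`SeedSequence` substreams, so each table regenerates independently and
identical configurations are byte-identical.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: smartwatch duty cycles and wear-time gaps
(timestamps are uniform within day), measurement-error structure of
ultrashort SDNN, missingness that is informative about stress, multi-wave
epidemics, enrollment attrition, and any nonlinearity between traits and
stress. Recovery results demonstrate correctness of the estimators under
the assumed model, not robustness to these violations.

## Problem sizes used by the test-suite

Calibration tests use 200 replicates throughout: CI coverage at 300
subjects × 8 periods; screen calibration at 200 subjects × 6 periods;
bootstrap type-I at 2 × 30 subjects × 30 days with 200 iterations per
replicate, and power at 2 × 60 subjects × 30 days. The cosinor recovery
instance is 150 subjects × 60 days × ~4 recordings/day. These sizes keep
the full suite to a few minutes on one CPU while leaving the Monte-Carlo
bands (e.g. ±4 percentage points on a 10% rate) comfortably wider than
the binomial noise.

## Known limitations

* CAR(1) distance is the period index; analyses that want calendar-day
  decay would need a different ordering column (supported via `time=`,
  but the default pipeline uses the index).
* The LRT mixture reference is exact only for a single variance component
  tested at the boundary.
* Wald inference everywhere; no Satterthwaite/Kenward-Roger small-sample
  degree-of-freedom corrections. At the cohort sizes targeted (hundreds of
  subjects) the normal approximation is adequate, as the coverage tests
  confirm.
* The bootstrap freezes variance components; uncertainty in τ² and σ² is
  not propagated into the replicate spread (the calibration tests bound
  the practical consequence).
* Acrophase comparisons assume both groups have a genuinely nonzero
  amplitude; near-flat rhythms make phase differences unstable.
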