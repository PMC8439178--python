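# circastress

Longitudinal stress mixed models and circadian heart-rate-variability (HRV)
analysis for digital-phenotyping cohorts of health-care workers.

Studies that pair weekly psychometric surveys (Perceived Stress Scale-4,
quality of life) with daily exposure reports and sparse smartwatch SDNN
recordings face three recurring problems: weekly surveys arrive at irregular
5–10-day intervals and must be aligned with daily data and community case
counts; within-subject stress scores are serially correlated; and SDNN
arrives as a handful of ultrashort recordings at arbitrary clock times per
day, so its 24-hour rhythm must be estimated from sparse, nonuniform,
repeated measures. `circastress` implements the full analysis stack for
this design, driven by a synthetic-cohort generator so every stage is
testable without access to participant data.

## What it computes

**Survey periods.** Each weekly survey anchors a *period*: if it falls
fewer than 7 days after the previous survey, the window starts the day
after that survey; otherwise it starts 6 days before the current one.
Daily metrics and the community case curve are summarised as per-period
means, and post-diagnosis windows (2-week / 4-week / any) are flagged.

**Occupation classes.** Days with patient-area exposure are clinical; a
period with ≥ 1 clinical day is clinical; a participant with ≥ 1 clinical
period is a clinical trainee (resident/fellow) or clinical nontrainee, and
otherwise staff.

**Longitudinal stress model.** A Gaussian linear mixed model for PSS-4
over periods, estimated by REML with a subject random intercept and a
continuous first-order autoregressive residual correlation over the period
index, Φ_jk = φ^{|t_j − t_k|}. Candidate covariates pass a marginal
(Type-III Wald) screen at P < .10; the multivariate model adds a
per-subject random slope on the community case burden, tested by a
boundary-corrected likelihood-ratio test; focal effects (e.g. the 4-week
post-diagnosis window) are reported within tertials of a baseline trait.

**Mixed-effect cosinor.** SDNN at clock time t follows
Y(t) = M + A·cos(2πt/24 + φ) + e(t), linearised through
x = cos(2πt/24), z = sin(2πt/24) into a mixed model with subject random
intercepts and group×(x, z) interactions; per-group MESOR M, amplitude
A = √(β²+γ²), and acrophase φ = atan2(−γ, β) are recovered by the inverse
relationship. Group differences in (M, A, φ) are tested by a subject-level
Bayesian bootstrap: each iteration reweights subjects with unit-mean
exponential weights, refits by weighted least squares with variance
components frozen at the full-data REML values, and records the pairwise
parameter differences.

## Worked example

```python
from circastress import SimulationConfig, run_pipeline

config = SimulationConfig(n_subjects=60, study_days=40, seed=3)
results = run_pipeline(config, out_dir="run", n_boot=200)

mv = results["stress"]["multivariate"]
print(round(mv["car1_phi"], 2), round(mv["coefficients"]["mean_case_count"], 2))
for level, p in results["cosinor"]["group_params"].items():
    print(level, round(p["amplitude"], 1), round(p["acrophase"], 2))
```

prints (seed 3):

```
0.5 1.01
medium 9.9 -2.04
high 6.1 -2.67
low 11.8 -1.99
```

The fitted CAR(1) correlation between adjacent periods is 0.50, and one
standard deviation of community case burden raises concurrent PSS-4 by
about one point. The per-tertial circadian amplitudes (ms) and acrophases
(radians; −2.0 rad peaks near 07:40) recover the generating rhythm: the
high-emotional-support tertial shows a flatter daily SDNN swing (6.1 ms
vs 11.8 ms) peaking later in the morning.

The same stages are available from a shell:

```sh
circastress simulate --seed 3 --out-dir tables/
circastress run --seed 3 --out-dir run/
circastress compare-groups --hrv tables/hrv.csv --baseline tables/baseline.csv \
    --group emotional_support --n-boot 1000 --seed 3 --out comparisons.json
```

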