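# oxbalance

Construction of the **oxidative balance score** (OBS) — a 22-component
composite of dietary and lifestyle antioxidant/pro-oxidant exposures — and
its full downstream inference pipeline for colorectal-cancer (CRC)
epidemiology: nested Cox proportional-hazards models by subsite and
subgroup, quartile trend tests, leave-one-out and diet/lifestyle sub-score
sensitivity analyses, logistic biomarker associations, and counterfactual
mediation analysis through serum albumin, uric acid and neutrophil count.

The package is aimed at epidemiologists and biostatisticians who want a
tested, configuration-driven implementation of this analysis that can be
exercised end-to-end on **synthetic cohorts with known ground truth** —
individual-level biobank data cannot be redistributed, so every estimator
here is validated against a simulator that encodes the causal structure the
analysis assumes.

## The score and the models

Each component contributes 0/1/2 points (total 0–44; higher = more
antioxidant exposure).  Tertile components are cut at sex-stratified 1/3
and 2/3 sample quantiles — antioxidants score 0/1/2 upward, pro-oxidants
2/1/0 — while smoking, alcohol and meat follow the abstention rule:
non-consumers score 2 and consumers split at the consumer median (1 below,
0 above).  The scored total enters Cox models of the hazard of CRC

    h(t | x) = h0(t) · exp(β·OBS + γ'z),

with three nested adjustment sets (Model 1: age, ethnicity, education,
deprivation; Model 2: + energy intake; Model 3: + CRP, NSAIDs), either per
OBS unit or by quartile against Q1, with the Wald p of the quartile index
as P-for-trend.  Mediation uses the potential-outcomes decomposition of a
one-unit OBS contrast into indirect (through a biomarker) and direct
effects on the risk-difference scale, with quasi-Bayesian intervals.
See `docs/methods.md` for the full specification.

## Worked example

```python
import oxbalance as ox
from oxbalance.simulate import SimulationConfig, generate_cohort

cfg = SimulationConfig(n_participants=20_000, seed=42)   # true HR 0.974/unit
sim = generate_cohort(cfg)                               # cohort + ground truth
scored = ox.categorize_quartiles(ox.score_cohort(sim.cohort))

res = ox.fit_cox(scored, ox.ModelSpec(model_id=3))[0]
print(
    f"Model 3 continuous: HR {res.hr:.3f} (95% CI {res.ci_low:.3f}-"
    f"{res.ci_high:.3f}), p={res.p:.4f}, events={res.n_events}"
)
med = ox.estimate_mediation(scored, "uric_acid", n_sims=500, seed=7)
print("\n".join(med.summary_lines()))
```

prints (exactly, under these seeds):

```
Model 3 continuous: HR 0.977 (95% CI 0.950-1.005), p=0.1051, events=348
mediator: uric_acid (n=17219, 500 draws)
  path a (OBS -> mediator):      -1.557
  path b (mediator -> outcome):  +0.002269
  IE = -6.415e-05 [-1.078e-04, -2.373e-05] *
  DE = -4.608e-04 [-9.863e-04, +7.096e-05]
  total = -5.249e-04
  proportion mediated = 12.22%
```

The fitted HR of 0.977/unit sits on the configured truth of 0.974 (348
events give a CI of about ±0.03).  The mediation summary reads: one OBS
unit lowers uric acid by 1.56 µmol/L (path a); each µmol/L of uric acid
raises the log-odds of CRC by 0.0023 (path b); the resulting indirect
effect is −6.4 × 10⁻⁵ on the risk scale (starred: its interval excludes 0),
about 12% of the total per-unit effect in this replicate.

The same pipeline runs from the shell:

```bash
oxbalance all --n 20000 --seed 42 --outdir run/
```

writing the scored cohort, exclusion log, baseline table, Cox /
complication / biomarker / sub-score / leave-one-out tables, mediation
summaries, and a manifest with the seed and configuration hash.

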