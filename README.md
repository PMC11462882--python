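# rmstprofile

Risk-adjusted comparisons of **process-quality indicators** of health care
across entities — patient residential regions, hospitals, or providers —
using the **restricted mean survival time (RMST)** and its complement, the
cause-decomposed **restricted mean time lost (RMTL)**.

The motivating application is medication persistence assessed from claims
data: patients discharged after an acute myocardial infarction should stay
on high-intensity statins, and the quality question is *how much of the
first 12 months each region's patients spend in compliance*. Binary
indicators (compliant at 12 months: yes/no) miss partial compliance;
event rates assume a constant hazard. The restricted mean does neither.

## The estimands

Let `Y` be the time from index discharge to first non-adherence (therapy
cessation), subject to competing events `j = 2` (death, recurrent
infarction) and right censoring, with all-cause survival `S(t) = P(Y > t)`
and cause-specific cumulative incidences `F_j(t) = P(Y ≤ t, D = j)`. For a
restriction time `τ` (12 months):

```
RMST(τ)  = E[Y ∧ τ] = ∫₀^τ S(t) dt          expected time in compliance
RMTL_j(τ) = ∫₀^τ F_j(t) dt                   expected time lost to cause j
RMST + Σ_j RMTL_j = τ                        (exact decomposition)
```

`S` and `F_j` are estimated by the Kaplan–Meier and Aalen–Johansen
estimators and integrated exactly. Per-patient **jackknife
pseudo-observations** `θ̂ᵢ = n·θ̂ − (n−1)·θ̂^(−i)` turn the incompletely
observed restricted means into regression-ready responses. Entity
comparisons are **standardized** for case mix by three estimators:

* **IPTW** — Hájek-weighted entity means with weights `1/ê_z(X)`, where
  `ê_z(X)` are multinomial propensity scores from a ridge-penalized
  logistic model (penalty by 10-fold cross-validated deviance);
* **outcome regression** — linear pseudo-value models with entity
  intercepts, averaged over the cohort counterfactually assigned to each
  entity (g-computation);
* **doubly robust (AIPW)** — their combination, consistent if either
  model is correct.

Uncertainty comes from a patient-level **bias-corrected bootstrap**
(default 250 resamples) with **Bonferroni**-adjusted simultaneous
intervals across entities.

## Episodes from claims

Four CSV tables (patients, prescription fills, hospital stays, terminal
events; schemas in `rmstprofile/io.py`) are converted to per-patient
episodes by a supply-pooling sweep: dispensed packages are converted to
days supplied, a running stock covers each outpatient day, inpatient days
neither consume stock nor allow cessation (plus a 2-day post-discharge
tolerance), and cessation is declared when no refill restores coverage
within a 30-day grace window after supply exhaustion.

## Worked example

```python
from rmstprofile import (SimConfig, generate_population, build_cohort_episodes,
                         EpisodeParams, restricted_means)
from rmstprofile.comparators import rmst_fraction

cfg = SimConfig(n_patients=20_000, n_entities=4, seed=1,
                entity_effect_vector=(0.0, 0.3, -0.3, 0.6))
bundle = generate_population(cfg)                 # synthetic claims tables
episodes = build_cohort_episodes(bundle, EpisodeParams())
nat = restricted_means(episodes, 365)
print({k: round(v * 12 / 365, 2) for k, v in nat.items()})
print(round(rmst_fraction(nat["rmst"], 365), 1), "% of the year in compliance")
```

prints

```
{'rmst': 4.25, 'rmtl_noncompliance': 6.42, 'rmtl_competing': 1.33}
35.4 % of the year in compliance
```

i.e. in this synthetic cohort patients keep continuous statin coverage for
4.25 of 12 months on average; 6.42 months are lost to non-adherence and
1.33 to death or reinfarction — the three numbers summing to 12 exactly.
The full pipeline (pseudo-values, propensity fitting, standardized
estimates, bootstrap intervals, report CSVs) runs from the command line:

```bash
rmstprofile simulate tables/ --n-patients 5000 --n-entities 6 --seed 7
rmstprofile run out/ --input-dir tables/ --seed 7 --bootstrap-reps 250
```

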