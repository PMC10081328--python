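# radonshift

Tools for quantifying how shifts in human time-activity patterns change
annual radiation dose from residential radon gas, and for evaluating
microinfluencer-based public-health outreach.

Radon (²²²Rn) is a radioactive indoor-air carcinogen; the lung dose a
person absorbs depends jointly on the radon concentration of their home
and on how many hours per year they spend in it. When a large behavioural
disruption — such as the shift to working from home after March 2020 —
moves time into the primary residence, radon dose rises even though no
building changed. `radonshift` is aimed at environmental-epidemiology and
health-physics analysts who have (or want to simulate) seasonal time-use
diaries, long-term household radon measurements, and outreach-campaign
telemetry.

## What it computes

**Annual occupancy.** Seasonal diaries record hours/day in five
environments (primary residence, other residence, non-residential
building, vehicle, outside), split workday vs off-day, plus workdays per
week per season. Annual hours per environment follow the closed form

    T[e] = Σ_s [ W_s · h_workday_s[e] + (days_s − W_s) · h_offday_s[e] ],
    W_s = workdays_per_week_s · days_s / 7

over a 365-day year (winter 90, spring 92, summer 92, fall 91 days;
8760 h total). Participants without diaries are imputed from the mean
occupancy of their employment-status stratum.

**Dosimetry.** The ICRP conversion

    D [mSv/y] = κ · C [Bq/m³] · T_home [h/y],   κ = 6.7×10⁻⁶ mSv per Bq·h/m³

gives annual alpha-particle lung dose; pre/post dose deltas are
classified into decrease / minimal / typical (0.2–2 mSv/y) / large
(> 2 mSv/y) exposure-change groups, and the linear excess-relative-risk
line (16% lifetime lung-cancer risk per 100 Bq/m³) is provided.

**Statistics.** Stratified summaries (arithmetic and geometric means,
GSD) with two-sided Mann–Whitney U tests for pairwise contrasts and
one-way ANOVA with Bonferroni–Holm-corrected pairwise post-hocs for
multi-level demographics.

**Influencer networks.** Pairwise shared-follower counts and
row-normalised percentages, and the interaction index

    II_i = 1 + (Σ_{j≠i} |F_i ∩ F_j|) / |F_i|,

whose cohort mean estimates message exposures per subscriber per post
(1 ⇔ no sharing). Campaign uplift is the percent change in daily-mean
website impressions / kit orders between a case period and each control
period.

**Synthetic cohorts.** A seeded generator produces demographically
structured households, lognormal within-stratum radon (geometric mean
105.3 Bq/m³ by default), paired pre/post diaries whose population mean
at-home fraction moves from 66.4% to 77.0% of the year (concentrated in
younger, working, urban/suburban strata and newer homes — which couples
the shift to radon), exact-overlap follower networks, and Poisson
intervention time series.

## Worked example

```python
import numpy as np
from radonshift import (CohortConfig, annual_dose, annual_hours, dose_table,
                        generate_cohort, generate_diaries, generate_radon)

print(round(annual_dose(100.0, 6018.0), 2))   # 4.03 mSv/y at the time-use baseline

cfg = CohortConfig(seed=1)                    # n = 4009 households
cohort = generate_cohort(cfg)
occ = annual_hours(generate_diaries(cohort, cfg))
doses = dose_table(generate_radon(cohort, cfg), occ)
post = occ.query("period == 'post'")["pct_primary_residence"]
print(round(post.mean(), 1))                                       # 76.9
print(round(float(np.exp(np.mean(np.log(doses["C_bqm3"])))), 1))   # 104.9
print(doses["change_group"].value_counts(normalize=True).round(3).to_dict())
# {'minimal': 0.452, 'typical_increase': 0.379, 'large_increase': 0.168, 'decrease': 0.001}
```

The first number is the annual dose for a home at 100 Bq/m³ occupied
6018 h/y (~4 mSv/y). The cohort lines show the generator recovering its
calibration: mean post-pandemic at-home time near 77% of the year and a
radon geometric mean near 105.3 Bq/m³ (both within sampling error at
n = 4009), with
most people in the 0.2–2 mSv/y "typical increase" band.

The `radonshift` CLI exposes the same pipeline (`simulate`, `occupancy`,
`dose`, `stats`, `network`, `uplift`, `run-all`) from YAML configs; see
`radonshift run-all --help`.

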