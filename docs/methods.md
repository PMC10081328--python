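# Methods

## Occupancy model

A diary describes a person-period as 8 day templates (4 seasons × workday
/ off-day), each a 5-vector of hours summing to 24, plus workdays per
week per season. Annual hours per environment use the closed form with
fractional workdays `W_s = wpw_s · days_s / 7` applied as a real number —
no rounding — so the aggregation is exactly linear in the templates and
conserves 8760 h by construction. The independent check enumerates the
365 calendar days, assigning `⌊W_s⌋` whole workdays per season plus one
fractional day that linearly interpolates the workday and off-day
templates; with that convention the enumeration and the closed form agree
to numerical precision, which the tests assert on 1000 random diaries.

Season lengths are fixed at 90/92/92/91 days (Dec–Feb, Mar–May, Jun–Aug,
Sep–Nov); leap years are ignored since the whole analysis is normalised
to 8760 h/y. Holidays are simply non-workdays, so "off-day" covers
weekends and holidays alike. Full- or part-time education counts as
employment.

Diary validation rescales any day whose hours sum within ±1 h of 24
(default tolerance) proportionally to exactly 24, and rejects days
outside the tolerance rather than silently repairing them.

Participants without diaries receive the arithmetic-mean annual hours of
their employment-status stratum (per period, per environment),
renormalised to 8760 h and flagged as imputed. Employment status is the
imputation key because it is the dominant determinant of the workday /
off-day split.

Two summary statistics of the pre→post shift are reported separately and
never reconciled: the mean of per-person hour deltas, and the difference
of aggregate period percentages. They answer different questions (typical
individual change vs population redistribution of time) and need not
agree numerically.

## Dosimetry

Dose is `κ·C·T_home` with κ = 6.7×10⁻⁶ mSv per Bq·h/m³, configurable so
newer dose coefficients can be substituted. Only primary-residence time
carries dose: the household measurement applies to that building, and
assigning it to "other residence" time would be unfounded. No
equilibrium-factor or progeny modelling beyond the single coefficient,
and no age-specific coefficients.

Exposure-change groups use explicit boundary conventions (the bands are
conventionally quoted only approximately): decrease `Δ ≤ −0.2`, minimal
`−0.2 < Δ < 0.2`, typical `0.2 ≤ Δ ≤ 2`, large `Δ > 2` mSv/y; both edges
are configurable and the partition is exhaustive by construction.

Because dose is a product of positives, geometric means factorise:
`GM(D) = κ·GM(C)·GM(T)`. A consequence worth flagging: the *geometric*
mean dose ratio post/pre equals the time ratio alone (radon cancels), so
any excess of the relative dose increase over the relative time increase
is an *arithmetic*-mean phenomenon driven by cov(C, ΔT) > 0. The pipeline
reports both and labels them.

## Statistics

Pairwise contrasts are two-sided Mann–Whitney U tests: exact null
distribution when both groups have ≤ 8 observations and the pooled sample
is tie-free, otherwise the normal approximation with tie correction.
Multi-level demographics use a one-way ANOVA omnibus at α = 0.05
followed, when significant, by all pairwise Mann–Whitney comparisons with
Bonferroni–Holm adjustment. ANOVA on skewed dose data is retained
deliberately to mirror the analysis scheme this package operationalises;
a Kruskal–Wallis omnibus is available (`omnibus="kruskal"`) but off by
default. Zero-variance degenerate inputs are reported as "no difference"
(p = 1) rather than NaN. Geometric means reject non-positive input;
handling detection limits is the caller's data-cleaning problem.

## Synthetic cohort generator

The generator encodes the study conditions; its defaults are not tuning
knobs. Calibrated-to-printed-values: n = 4009 households; geometric mean
age 53.9 y (lognormal, σ_log = 0.30, clipped to 18–100); mean occupants
2.34 (1 + Poisson); employment mix ≈ 59/35/3/2% work-education / retired
/ unemployed / leave via an age-logistic; gender 48/40/12/0.1%; community
25/59/16% urban/suburban/rural-isolated; construction years 1900–2020
with newer homes given to younger respondents; construction-era radon
multipliers 0.80/0.90/1.10/1.38 (new-to-oldest ratio ≈ 1.72, matching the
~72% excess of new builds); at-home fraction means 0.664 (pre) and 0.770
(post).

Stated assumptions where no value is printed: radon GSD 2.8 (indoor-radon
dispersion is typically GSD 2–3; 2.8 makes the > 2 mSv/y tail of the
change distribution non-empty, as observed), rural multiplier 1.3,
individual at-home noise sd 0.06 (pre level) and 0.08 (shift), sector/job
/income categoricals with plausible fixed weights. All are exposed in
`CohortConfig`.

Radon is lognormal within strata: log-concentration is the configured
log-GM plus a mean-centred stratum offset (era × community multipliers)
plus `ln(GSD)·z`. Centring anchors the realised overall geometric mean at
the configured value while preserving multiplier ratios between strata;
GSD = 1 collapses each stratum to its median exactly.

The pre→post at-home shift is carried entirely by working respondents,
with weight `1 + g·youngness + 0.3·urban/suburban + 0.4·newness`
(g = `shift_age_gradient`), scaled so the population mean shift equals
the configured 10.6 percentage points. The newness term makes the shift
positively correlated with household radon through the shared
construction-era stratum — no explicit copula — reproducing the
dose-increase-exceeds-time-increase phenomenon as an emergent property.
Non-working respondents get identical pre and post diaries: the decrease
and minimal-change tails among them arise in reality from behaviour the
generator does not model (e.g. returning to frontline work), a known
limitation; the modelled decrease tail comes from workers with negative
idiosyncratic shifts.

Seasonal diary templates are deterministic given the annual at-home
fraction: workday/season deviations are centred under the day-count
weights so each person's annual at-home hours equal their target fraction
× 8760 exactly, and deviations are damped near 0 or 24 h/day to keep all
entries feasible. Consequently the generator reproduces its configured
population means up to sampling noise only, which is what the 3-SE
calibration tests exercise.

Follower networks are constructed, not sampled: each requested pairwise
overlap becomes a dedicated block of follower identifiers assigned to
exactly that pair (blocks pairwise disjoint), remaining identifiers are
unique, and all identifiers pass through a seeded permutation for
opacity. Realised sizes and intersections therefore equal the request
exactly, making network tests deterministic. A follower shared by m > 2
influencers would contribute m − 1 to each of their indices; the
generator's pairwise blocks never create such followers, but the
interaction-index implementation handles them correctly (verified by the
per-follower exposure-count oracle).

Intervention counts are Poisson around period-specific daily means
(baseline × per-period multiplier); only period means are specified, so
Poisson is the minimal noise model.

## What passing tests do and do not show

The generator reproduces the marginals and correlations stated above,
not the real cohort's joint demographic distribution, reporting biases,
or seasonal survey-recall error. Calibration-recovery tests therefore
validate the pipeline's arithmetic and the generator's self-consistency;
they do not re-estimate any population quantity. Statistics computed at
study scale in the tests use n = 4009 and ~150-day campaign periods —
the study's own sizes — so no scaling-down caveats apply.

## Numerical choices

All randomness flows from one root seed through named substreams
(cohort 0, radon 1, diaries 2, response-withholding 99), so each
generator is reproducible in isolation. Conservation checks use an
absolute tolerance of 1e-6 h after float aggregation; oracle-equivalence
checks use 1e-9 relative. Mann–Whitney p-values are capped at 1 after
continuity correction. CSV output keeps full float precision for
lossless round-trips.
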