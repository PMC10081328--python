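"""Shared fixtures: hand-built diaries, random diaries, and a study-scale cohort."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from radonshift.seasons import DAY_TYPES, ENVIRONMENTS, SEASON_DAYS, SEASONS


def diary_rows(person_id, period, hours_by_row, wpw_by_season):
    """Long-format diary rows from {(season, day_type): 5-vector} and {season: wpw}."""
    rows = []
    for season in SEASONS:
        for day_type in DAY_TYPES:
            h = hours_by_row[(season, day_type)]
            row = {
                "person_id": person_id,
                "period": period,
                "season": season,
                "day_type": day_type,
                "workdays_per_week": wpw_by_season[season],
            }
            row.update({f"h_{e}": float(v) for e, v in zip(ENVIRONMENTS, h)})
            rows.append(row)
    return rows


def uniform_diary(person_id="p1", period="pre", home_frac=0.687, wpw=4.5):
    """Diary with the same day everywhere: home_frac at home, rest split evenly."""
    home = 24.0 * home_frac
    rest = (24.0 - home) / 4.0
    vec = (home, rest, rest, rest, rest)
    hours = {(s, d): vec for s in SEASONS for d in DAY_TYPES}
    return pd.DataFrame(diary_rows(person_id, period, hours, {s: wpw for s in SEASONS}))


def random_diaries(n_people, rng, period="pre"):
    """n valid random diaries: Dirichlet days, uniform workdays per week."""
    rows = []
    for i in range(n_people):
        wpw = {s: float(rng.uniform(0, 7)) for s in SEASONS}
        hours = {
            (s, d): 24.0 * rng.dirichlet(np.ones(5)) for s in SEASONS for d in DAY_TYPES
        }
        rows.extend(diary_rows(f"r{i:04d}", period, hours, wpw))
    return pd.DataFrame(rows)


def enumeration_annual_hours(diary, person_id, period):
    """365-day enumeration oracle for one person-period.

    Builds the year day by day: within each season, the whole workdays
    come first, then one fractional day interpolating workday/off-day
    hours, then off-days.  Independent of the closed-form aggregation.
    """
    sub = diary[(diary["person_id"] == person_id) & (diary["period"] == period)]
    total = np.zeros(len(ENVIRONMENTS))
    for season in SEASONS:
        days = SEASON_DAYS[season]
        srows = sub[sub["season"] == season]
        hw = srows.loc[srows["day_type"] == "workday", [f"h_{e}" for e in ENVIRONMENTS]].to_numpy()[0]
        ho = srows.loc[srows["day_type"] == "offday", [f"h_{e}" for e in ENVIRONMENTS]].to_numpy()[0]
        w = float(srows["workdays_per_week"].iloc[0]) * days / 7.0
        nw = int(np.floor(w))
        frac = w - nw
        day_rows = [hw] * nw
        if nw < days:
            day_rows.append(frac * hw + (1.0 - frac) * ho)
            day_rows.extend([ho] * (days - nw - 1))
        total += np.vstack(day_rows).sum(axis=0)
    return total


@pytest.fixture(scope="session")
def study_bundle():
    """Default-calibration synthetic study (n=4009), generated once."""
    from radonshift import CohortConfig, generate_cohort, generate_diaries, generate_radon
    from radonshift.activity import annual_hours, validate_diaries

    config = CohortConfig(seed=20230407)
    cohort = generate_cohort(config)
    radon = generate_radon(cohort, config)
    diaries = validate_diaries(generate_diaries(cohort, config))
    occupancy = annual_hours(diaries)
    return {
        "config": config,
        "cohort": cohort,
        "radon": radon,
        "diaries": diaries,
        "occupancy": occupancy,
    }
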