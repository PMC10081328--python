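"""Convert seasonal activity diaries into annual environment occupancy.

A diary records, for one person and one period (pre- or post-pandemic
onset), the hours per day spent in each of five environments, separately
for workdays and off-days (weekends plus holidays), in each of the four
seasons, together with the number of workdays per week in that season.

The annual hours in environment ``e`` are the closed form

    T[e] = sum_s [ W_s * h_workday_s[e] + (days_s - W_s) * h_offday_s[e] ]

with ``W_s = workdays_per_week_s * days_s / 7`` applied as a real number
(no rounding).  Because every diary day sums to 24 h, the annual totals
conserve 8760 h by construction.

Diaries are held in a long-format :class:`pandas.DataFrame` with one row
per (person, period, season, day type); see :data:`DIARY_COLUMNS`.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DiaryValidationError
from .seasons import (
    DAY_TYPES,
    DEFAULT_CALENDAR,
    ENVIRONMENTS,
    HOURS_PER_DAY,
    HOURS_PER_YEAR,
    PERIODS,
    SEASONS,
    SeasonCalendar,
)

HOUR_COLUMNS = [f"h_{e}" for e in ENVIRONMENTS]
T_COLUMNS = [f"T_{e}" for e in ENVIRONMENTS]
PCT_COLUMNS = [f"pct_{e}" for e in ENVIRONMENTS]

#: Schema of the long-format diary table.
DIARY_COLUMNS = ["person_id", "period", "season", "day_type", "workdays_per_week"] + HOUR_COLUMNS

#: Schema of the annual occupancy table.
OCCUPANCY_COLUMNS = ["person_id", "period"] + T_COLUMNS + PCT_COLUMNS + ["T_home", "imputed"]

_KEY = ["person_id", "period"]


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DiaryValidationError(f"{what} table is missing columns {missing}")


def validate_diaries(diaries: pd.DataFrame, tolerance: float = 1.0) -> pd.DataFrame:
    """Validate and normalise a diary table.

    Each (person, period, season, day-type) hours vector must be
    non-negative and sum to within ``tolerance`` hours of 24; vectors
    inside the tolerance are proportionally rescaled to sum to exactly
    24, vectors outside it are rejected.  Workdays per week must lie in
    [0, 7] and agree between the workday and off-day rows of the same
    (person, period, season).

    Returns a normalised copy; raises :class:`DiaryValidationError`
    identifying the offending rows otherwise.
    """
    _require_columns(diaries, DIARY_COLUMNS, "diary")
    d = diaries.copy()

    bad_cat = d.loc[~d["season"].isin(SEASONS) | ~d["day_type"].isin(DAY_TYPES) | ~d["period"].isin(PERIODS)]
    if len(bad_cat):
        raise DiaryValidationError(
            f"unknown season/day_type/period labels in rows {bad_cat.index[:5].tolist()}"
        )

    hours = d[HOUR_COLUMNS].to_numpy(dtype=float)
    if np.any(hours < 0) or not np.all(np.isfinite(hours)):
        bad = d.index[np.any((hours < 0) | ~np.isfinite(hours), axis=1)]
        raise DiaryValidationError(f"negative or non-finite hours in rows {bad[:5].tolist()}")

    wpw = d["workdays_per_week"].to_numpy(dtype=float)
    if np.any((wpw < 0) | (wpw > 7) | ~np.isfinite(wpw)):
        bad = d.index[(wpw < 0) | (wpw > 7) | ~np.isfinite(wpw)]
        raise DiaryValidationError(f"workdays_per_week outside [0, 7] in rows {bad[:5].tolist()}")

    sums = hours.sum(axis=1)
    off = np.abs(sums - HOURS_PER_DAY) > tolerance
    if np.any(off):
        rows = d.loc[off, ["person_id", "period", "season", "day_type"]].head(5)
        detail = "; ".join(
            f"person={r.person_id} period={r.period} season={r.season} day_type={r.day_type}"
            for r in rows.itertuples()
        )
        raise DiaryValidationError(
            f"daily hours sum outside 24±{tolerance} h for {int(off.sum())} row(s): {detail}"
        )
    d[HOUR_COLUMNS] = hours * (HOURS_PER_DAY / sums)[:, None]

    spread = d.groupby(_KEY + ["season"])["workdays_per_week"].nunique()
    if (spread > 1).any():
        bad = spread.index[spread > 1][:5].tolist()
        raise DiaryValidationError(f"workdays_per_week differs between day types for {bad}")

    counts = d.groupby(_KEY).size()
    if (counts != len(SEASONS) * len(DAY_TYPES)).any():
        bad = counts.index[counts != 8][:5].tolist()
        raise DiaryValidationError(f"expected 8 season×day-type rows per person-period, bad keys: {bad}")
    return d


def annual_hours(diaries: pd.DataFrame, calendar: SeasonCalendar = DEFAULT_CALENDAR) -> pd.DataFrame:
    """Aggregate validated diaries into annual occupancy per person-period.

    Returns a table with hours per year ``T_<env>``, percent of year
    ``pct_<env>``, the ``T_home`` alias for primary-residence hours, and
    an ``imputed`` flag (False here; see :func:`impute_occupancy`).
    """
    _require_columns(diaries, DIARY_COLUMNS, "diary")
    d = diaries.copy()
    days = d["season"].map(calendar.days).to_numpy(dtype=float)
    workdays_in_season = d["workdays_per_week"].to_numpy(dtype=float) * days / 7.0
    weight = np.where(d["day_type"] == "workday", workdays_in_season, days - workdays_in_season)
    for e in ENVIRONMENTS:
        d[f"T_{e}"] = d[f"h_{e}"].to_numpy(dtype=float) * weight
    occ = d.groupby(_KEY, as_index=False, sort=True)[T_COLUMNS].sum()
    for e in ENVIRONMENTS:
        occ[f"pct_{e}"] = 100.0 * occ[f"T_{e}"] / HOURS_PER_YEAR
    occ["T_home"] = occ["T_primary_residence"]
    occ["imputed"] = False
    return occ[OCCUPANCY_COLUMNS]


def occupancy_delta(occupancy: pd.DataFrame) -> pd.DataFrame:
    """Per-person post-minus-pre change, in hours/year and percentage points.

    Every person must appear in both periods; returns one row per person
    with ``delta_T_<env>`` and ``delta_pct_<env>`` columns plus the
    ``delta_T_home`` alias.
    """
    _require_columns(occupancy, ["person_id", "period"] + T_COLUMNS, "occupancy")
    pre = occupancy[occupancy["period"] == "pre"].set_index("person_id")
    post = occupancy[occupancy["period"] == "post"].set_index("person_id")
    if set(pre.index) != set(post.index):
        odd = sorted(set(pre.index) ^ set(post.index))[:5]
        raise DiaryValidationError(f"persons present in only one period: {odd}")
    post = post.reindex(pre.index)
    out = pd.DataFrame({"person_id": pre.index})
    for e in ENVIRONMENTS:
        dT = (post[f"T_{e}"] - pre[f"T_{e}"]).to_numpy()
        out[f"delta_T_{e}"] = dT
        out[f"delta_pct_{e}"] = 100.0 * dT / HOURS_PER_YEAR
    out["delta_T_home"] = out["delta_T_primary_residence"]
    out["delta_pct_home"] = out["delta_pct_primary_residence"]
    return out


def impute_occupancy(cohort: pd.DataFrame, occupancy: pd.DataFrame) -> pd.DataFrame:
    """Extend occupancy to cohort members without diaries.

    Each person lacking a computed occupancy for a period receives the
    arithmetic mean annual hours of their employment-status stratum
    (computed from non-imputed donors in that period), renormalised so
    the environments sum to exactly 8760 h, and is flagged ``imputed``.
    A stratum with no donors is an error.
    """
    _require_columns(cohort, ["person_id", "employment_status"], "cohort")
    donors = occupancy[~occupancy["imputed"]]
    status = cohort.set_index("person_id")["employment_status"]
    unknown = set(donors["person_id"]) - set(status.index)
    if unknown:
        raise ConfigurationError(f"occupancy rows for persons not in cohort: {sorted(unknown)[:5]}")

    pieces = [occupancy]
    for period in PERIODS:
        have = set(donors.loc[donors["period"] == period, "person_id"])
        need = status.index[~status.index.isin(have)]
        if len(need) == 0:
            continue
        dp = donors[donors["period"] == period].copy()
        dp["employment_status"] = dp["person_id"].map(status)
        means = dp.groupby("employment_status")[T_COLUMNS].mean()
        missing_strata = sorted(set(status.loc[need]) - set(means.index))
        if missing_strata:
            raise ConfigurationError(
                f"no diary donors for employment status strata {missing_strata} in period '{period}'"
            )
        filled = means.loc[status.loc[need]].to_numpy()
        filled *= HOURS_PER_YEAR / filled.sum(axis=1, keepdims=True)
        block = pd.DataFrame(filled, columns=T_COLUMNS)
        block.insert(0, "person_id", np.asarray(need))
        block.insert(1, "period", period)
        for e in ENVIRONMENTS:
            block[f"pct_{e}"] = 100.0 * block[f"T_{e}"] / HOURS_PER_YEAR
        block["T_home"] = block["T_primary_residence"]
        block["imputed"] = True
        pieces.append(block[OCCUPANCY_COLUMNS])
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["period", "person_id"], ignore_index=True)
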