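"""Radon lung dosimetry: concentration × occupancy → annual dose.

The ICRP conversion gives the annual alpha-particle lung dose from
residential radon as

    D [mSv/y] = kappa * C [Bq/m^3] * T_home [h/y],

with kappa = 6.7e-6 mSv per Bq·h/m^3.  Only time in the primary
residence carries dose; the household radon measurement applies to that
residence alone.  The linear no-threshold excess-relative-risk line for
lung cancer is 16% per 100 Bq/m^3 of long-term exposure.

Pre/post dose deltas are classified into four exposure-change groups
with configurable boundaries (defaults ±0.2 and 2 mSv/y):

    decrease          delta <= -0.2
    minimal           -0.2 < delta < 0.2
    typical_increase  0.2 <= delta <= 2
    large_increase    delta > 2
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: ICRP dose conversion coefficient, mSv per Bq·h/m^3.
ICRP_DOSE_COEFFICIENT: float = 6.7e-6

#: Excess relative lifetime lung-cancer risk, percent per 100 Bq/m^3.
ERR_PERCENT_PER_100_BQM3: float = 16.0

CHANGE_GROUPS = ("decrease", "minimal", "typical_increase", "large_increase")

DOSE_COLUMNS = [
    "person_id",
    "C_bqm3",
    "T_home_pre",
    "T_home_post",
    "D_pre_msv_y",
    "D_post_msv_y",
    "delta_msv_y",
    "change_group",
]


@dataclass(frozen=True)
class ChangeThresholds:
    """Band edges (mSv/y) for the exposure-change classification."""

    minimal: float = 0.2
    large: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.minimal < self.large:
            raise ConfigurationError(
                f"change thresholds must satisfy 0 < minimal < large, got {self.minimal}, {self.large}"
            )


DEFAULT_THRESHOLDS = ChangeThresholds()


def annual_dose(concentration, time_at_home, coefficient: float = ICRP_DOSE_COEFFICIENT):
    """Annual lung dose in mSv/y; accepts scalars or arrays."""
    c = np.asarray(concentration, dtype=float)
    t = np.asarray(time_at_home, dtype=float)
    if coefficient <= 0:
        raise ConfigurationError(f"dose coefficient must be positive, got {coefficient}")
    if np.any(c < 0) or np.any(t < 0):
        raise ValueError("concentration and time at home must be non-negative")
    out = coefficient * c * t
    return float(out) if out.ndim == 0 else out


def dose_delta(dose_pre, dose_post):
    """Post-minus-pre dose change, sign preserved."""
    out = np.asarray(dose_post, dtype=float) - np.asarray(dose_pre, dtype=float)
    return float(out) if out.ndim == 0 else out


def classify_change(delta, thresholds: ChangeThresholds = DEFAULT_THRESHOLDS):
    """Map dose deltas (mSv/y) onto the four exposure-change groups."""
    d = np.asarray(delta, dtype=float)
    out = np.empty(d.shape, dtype=object)
    out[d <= -thresholds.minimal] = "decrease"
    out[(d > -thresholds.minimal) & (d < thresholds.minimal)] = "minimal"
    out[(d >= thresholds.minimal) & (d <= thresholds.large)] = "typical_increase"
    out[d > thresholds.large] = "large_increase"
    if d.ndim == 0:
        return str(out[()])
    return out


def excess_relative_risk(concentration):
    """Linear excess relative lifetime lung-cancer risk, in percent."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = ERR_PERCENT_PER_100_BQM3 * c / 100.0
    return float(out) if out.ndim == 0 else out


def dose_table(
    radon: pd.DataFrame,
    occupancy: pd.DataFrame,
    coefficient: float = ICRP_DOSE_COEFFICIENT,
    thresholds: ChangeThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Join household radon to pre/post occupancy and build dose records.

    ``radon`` needs columns person_id and radon_bqm3; ``occupancy`` is
    the output of :func:`radonshift.activity.annual_hours` (optionally
    after imputation) with both periods for every person in ``radon``.
    """
    for col in ("person_id", "radon_bqm3"):
        if col not in radon.columns:
            raise ConfigurationError(f"radon table is missing column '{col}'")
    if np.any(radon["radon_bqm3"].to_numpy(dtype=float) <= 0):
        raise ValueError("radon concentrations must be strictly positive")
    wide = occupancy.pivot(index="person_id", columns="period", values="T_home")
    missing = [p for p in ("pre", "post") if p not in wide.columns]
    if missing:
        raise ConfigurationError(f"occupancy table lacks period(s) {missing}")
    merged = radon.set_index("person_id").join(wide, how="inner")
    lost = len(radon) - len(merged)
    if lost:
        raise ConfigurationError(f"{lost} household(s) have radon but no occupancy in both periods")
    out = pd.DataFrame(
        {
            "person_id": merged.index,
            "C_bqm3": merged["radon_bqm3"].to_numpy(dtype=float),
            "T_home_pre": merged["pre"].to_numpy(dtype=float),
            "T_home_post": merged["post"].to_numpy(dtype=float),
        }
    )
    out["D_pre_msv_y"] = annual_dose(out["C_bqm3"], out["T_home_pre"], coefficient)
    out["D_post_msv_y"] = annual_dose(out["C_bqm3"], out["T_home_post"], coefficient)
    out["delta_msv_y"] = dose_delta(out["D_pre_msv_y"], out["D_post_msv_y"])
    out["change_group"] = classify_change(out["delta_msv_y"].to_numpy(), thresholds)
    return out[DOSE_COLUMNS]


def change_group_distribution(doses: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of the four exposure-change groups."""
    counts = doses["change_group"].value_counts()
    rows = []
    for g in CHANGE_GROUPS:
        n = int(counts.get(g, 0))
        rows.append({"change_group": g, "n": n, "percent": 100.0 * n / len(doses)})
    return pd.DataFrame(rows)
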