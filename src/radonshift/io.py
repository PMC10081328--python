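"""CSV schemas and round-trip readers/writers.

All tables are UTF-8 CSV with a header row.  Readers validate the
documented column set and numeric types and report offending line
numbers (header = line 1), so locale quirks such as comma decimals
surface as clear schema errors instead of silent NaNs.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import DIARY_COLUMNS, HOUR_COLUMNS, OCCUPANCY_COLUMNS
from .dosimetry import DOSE_COLUMNS
from .errors import SchemaError
from .network import SERIES_COLUMNS
from .synthetic import COHORT_COLUMNS

FOLLOWER_COLUMNS = ["influencer_id", "follower_id"]
RADON_COLUMNS = ["person_id", "radon_bqm3"]

_NUMERIC = {
    "diaries": ["workdays_per_week"] + HOUR_COLUMNS,
    "cohort": ["age", "occupants", "construction_year"],
    "radon": ["radon_bqm3"],
    "occupancy": [c for c in OCCUPANCY_COLUMNS if c.startswith(("T_", "pct_"))],
    "dose": [c for c in DOSE_COLUMNS if c not in ("person_id", "change_group")],
    "series": ["count"],
    "followers": [],
}

_SCHEMAS = {
    "diaries": DIARY_COLUMNS,
    "cohort": COHORT_COLUMNS,
    "radon": RADON_COLUMNS,
    "occupancy": OCCUPANCY_COLUMNS,
    "dose": DOSE_COLUMNS,
    "series": SERIES_COLUMNS,
    "followers": FOLLOWER_COLUMNS,
}


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a CSV at full float precision (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate one of the documented table schemas."""
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema '{schema}'; known: {sorted(_SCHEMAS)}")
    path = Path(path)
    try:
        with warnings.catch_warnings():
            # Ragged rows (e.g. unquoted comma decimals) must fail loudly,
            # not silently shift or drop fields.
            warnings.simplefilter("error", pd.errors.ParserWarning)
            df = pd.read_csv(path, encoding="utf-8", index_col=False)
    except FileNotFoundError:
        raise SchemaError(f"input file not found: {path}") from None
    except (pd.errors.ParserError, pd.errors.ParserWarning) as exc:
        raise SchemaError(
            f"{path}: malformed CSV ({exc}); note comma decimal separators are not accepted"
        ) from None
    expected = _SCHEMAS[schema]
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{path}: {schema} table columns mismatch; missing={missing}, unexpected={extra}"
        )
    for col in _NUMERIC[schema]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]
            raise SchemaError(
                f"{path}: non-numeric value(s) in column '{col}' at line(s) {lines} "
                "(comma decimal separators are not accepted; use '.')"
            )
        if coerced.isna().any():
            lines = [int(i) + 2 for i in df.index[coerced.isna()][:5]]
            raise SchemaError(f"{path}: missing value(s) in column '{col}' at line(s) {lines}")
        df[col] = coerced
    return df[expected]
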