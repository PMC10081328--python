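"""Season calendar and environment vocabulary.

The analysis resolves time use by four meteorological seasons and by
workday versus off-day (weekends and holidays).  A non-leap year is
assumed throughout: 365 days, 8760 hours.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigurationError

#: The five diary environments, in canonical column order.
ENVIRONMENTS: tuple[str, ...] = (
    "primary_residence",
    "other_residence",
    "non_residential_building",
    "vehicle",
    "outside",
)

SEASONS: tuple[str, ...] = ("winter", "spring", "summer", "fall")
DAY_TYPES: tuple[str, ...] = ("workday", "offday")
PERIODS: tuple[str, ...] = ("pre", "post")

#: Days per season: winter = Dec+Jan+Feb, spring = Mar+Apr+May,
#: summer = Jun+Jul+Aug, fall = Sep+Oct+Nov (non-leap year).
SEASON_DAYS: Mapping[str, int] = {"winter": 90, "spring": 92, "summer": 92, "fall": 91}

HOURS_PER_DAY: float = 24.0
DAYS_PER_YEAR: int = 365
HOURS_PER_YEAR: float = 8760.0


@dataclass(frozen=True)
class SeasonCalendar:
    """Mapping season → day count, constrained to a 365-day year."""

    days: Mapping[str, int] = field(default_factory=lambda: dict(SEASON_DAYS))

    def __post_init__(self) -> None:
        if set(self.days) != set(SEASONS):
            raise ConfigurationError(
                f"calendar must define exactly the seasons {SEASONS}, got {tuple(self.days)}"
            )
        total = sum(self.days.values())
        if total != DAYS_PER_YEAR:
            raise ConfigurationError(f"season days must sum to {DAYS_PER_YEAR}, got {total}")

    @property
    def hours_per_year(self) -> float:
        return HOURS_PER_YEAR


DEFAULT_CALENDAR = SeasonCalendar()
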