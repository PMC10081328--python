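"""Shared-follower analysis for microinfluencer cohorts.

For influencers with follower sets F_1..F_n the shared-count matrix is
S[i][j] = |F_i ∩ F_j| and the percent matrix P[i][j] = 100·S[i][j]/|F_i|
(row-normalised, hence generally asymmetric).  The interaction index of
influencer i,

    II_i = 1 + (sum_{j != i} S[i][j]) / |F_i|,

is the mean, over i's followers, of the number of cohort influencers
each follows — the self-term contributes the 1, so fully disjoint
follower sets give exactly 1.  A follower subscribing to m cohort
influencers contributes m−1 shared pairs to each of their m indices.
Averaged over the cohort this estimates the number of message exposures
per subscriber generated by one post per influencer; multiplied by the
mean number of posts it gives expected exposures over a campaign.

Intervention uplift compares daily-mean activity in a case period
against each control period: 100·(mean_case − mean_control)/mean_control.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Default influencer labels, as commonly anonymised with Greek letters.
GREEK_LABELS = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta", "iota", "kappa")

SERIES_COLUMNS = ["date", "metric", "count", "period_label"]


@dataclass(frozen=True)
class FollowerNetwork:
    """Influencer → follower-identifier sets."""

    followers: dict[str, frozenset]

    def __post_init__(self) -> None:
        if not self.followers:
            raise ConfigurationError("follower network has no influencers")
        empty = [k for k, v in self.followers.items() if len(v) == 0]
        if empty:
            raise ConfigurationError(f"influencer(s) with empty follower set: {empty}")

    @property
    def labels(self) -> list[str]:
        return list(self.followers)

    @classmethod
    def from_sets(cls, followers: dict) -> "FollowerNetwork":
        return cls({str(k): frozenset(v) for k, v in followers.items()})

    @classmethod
    def from_edges(cls, edges: pd.DataFrame) -> "FollowerNetwork":
        """Build from a two-column (influencer_id, follower_id) table."""
        for col in ("influencer_id", "follower_id"):
            if col not in edges.columns:
                raise ConfigurationError(f"follower edge list is missing column '{col}'")
        grouped = edges.groupby("influencer_id")["follower_id"].agg(frozenset)
        return cls({str(k): v for k, v in grouped.items()})

    def to_edges(self) -> pd.DataFrame:
        rows = [(label, f) for label, fs in self.followers.items() for f in sorted(fs)]
        return pd.DataFrame(rows, columns=["influencer_id", "follower_id"])

    def sizes(self) -> pd.Series:
        return pd.Series({k: len(v) for k, v in self.followers.items()}, name="followers")

    def shared_matrix(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(counts, percent) matrices; diagonals hold |F_i| and 100%."""
        labels = self.labels
        n = len(labels)
        counts = np.zeros((n, n), dtype=int)
        for i, li in enumerate(labels):
            counts[i, i] = len(self.followers[li])
            for j in range(i + 1, n):
                shared = len(self.followers[li] & self.followers[labels[j]])
                counts[i, j] = counts[j, i] = shared
        sizes = counts.diagonal().astype(float)
        percent = 100.0 * counts / sizes[:, None]
        return (
            pd.DataFrame(counts, index=labels, columns=labels),
            pd.DataFrame(percent, index=labels, columns=labels),
        )

    def interaction_index(self, influencer: str) -> float:
        """II_i = 1 + cross-shared followers over own follower count."""
        if influencer not in self.followers:
            raise ConfigurationError(f"unknown influencer '{influencer}'; have {self.labels}")
        own = self.followers[influencer]
        shared = sum(len(own & other) for k, other in self.followers.items() if k != influencer)
        return 1.0 + shared / len(own)

    def interaction_indices(self) -> pd.Series:
        return pd.Series(
            {k: self.interaction_index(k) for k in self.labels}, name="interaction_index"
        )

    def overall_interaction_index(self) -> float:
        """Arithmetic mean of the per-influencer interaction indices."""
        return float(self.interaction_indices().mean())

    def edge_list(self) -> pd.DataFrame:
        """Undirected shared-count edges (i < j), for chord/network plots."""
        counts, _ = self.shared_matrix()
        labels = self.labels
        rows = [
            {"source": labels[i], "target": labels[j], "shared_count": int(counts.iloc[i, j])}
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "shared_count"])


def expected_interactions(overall_index: float, mean_posts: float) -> float:
    """Expected message encounters per subscriber, to one decimal."""
    if overall_index <= 0 or mean_posts <= 0:
        raise ValueError("overall index and mean posts must be positive")
    return round(overall_index * mean_posts, 1)


def uplift(series: pd.DataFrame, case_label: str = "case") -> pd.DataFrame:
    """Percent change of case-period daily means versus each control.

    ``series`` is the long intervention table (date, metric, count,
    period_label).  Returns one row per (metric, control period) with
    the case and control daily means and the percent uplift.
    """
    missing = [c for c in SERIES_COLUMNS if c not in series.columns]
    if missing:
        raise ConfigurationError(f"intervention series is missing columns {missing}")
    labels = series["period_label"].unique().tolist()
    if case_label not in labels:
        raise ConfigurationError(f"no '{case_label}' period in series; have {labels}")
    controls = [l for l in labels if l != case_label]
    if not controls:
        raise ConfigurationError("series has no control period")
    means = series.groupby(["metric", "period_label"])["count"].mean()
    rows = []
    for metric in sorted(series["metric"].unique()):
        case_mean = means[(metric, case_label)]
        for control in controls:
            control_mean = means.get((metric, control), np.nan)
            if not np.isfinite(control_mean):
                continue
            if control_mean == 0:
                raise ValueError(f"control period '{control}' has zero mean for metric '{metric}'")
            rows.append(
                {
                    "metric": metric,
                    "control_period": control,
                    "case_mean_per_day": float(case_mean),
                    "control_mean_per_day": float(control_mean),
                    "uplift_percent": 100.0 * (case_mean - control_mean) / control_mean,
                }
            )
    return pd.DataFrame(rows)
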