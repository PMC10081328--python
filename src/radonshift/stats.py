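"""Stratified summaries and the study's significance-testing scheme.

Exposure variables (radon, dose) are summarised by geometric means —
the natural location statistic for lognormal data — alongside
arithmetic means.  Two-group comparisons use the two-sided Mann–Whitney
U test; three or more groups use a one-way ANOVA omnibus followed, when
significant, by all pairwise Mann–Whitney comparisons with
Bonferroni–Holm step-down adjustment.  A Kruskal–Wallis omnibus is
available as an option for heavily skewed data but is off by default.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError

__all__ = [
    "TestResult",
    "geometric_mean",
    "geometric_sd",
    "geometric_se_factor",
    "compare_groups",
    "compare_many",
    "holm_adjust",
    "significance_stars",
    "stratify",
]


@dataclass
class TestResult:
    """One hypothesis test: raw and (optionally) Holm-adjusted p-value."""

    label: str
    method: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted if self.p_adjusted is not None else self.p_value)


def _positive(values, what: str) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError(f"{what}: empty input")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError(f"{what} requires strictly positive finite values")
    return x


def geometric_mean(values) -> float:
    """exp(mean(log x)) for strictly positive values."""
    return float(np.exp(np.mean(np.log(_positive(values, "geometric mean")))))


def geometric_sd(values) -> float:
    """Multiplicative dispersion exp(sd(log x)); 1 for a constant sample."""
    x = _positive(values, "geometric SD")
    if x.size == 1:
        return 1.0
    return float(np.exp(np.std(np.log(x), ddof=1)))


def geometric_se_factor(values) -> float:
    """exp(SE of mean log): GM * factor**±k brackets a k-SE interval."""
    x = _positive(values, "geometric SE")
    return float(np.exp(np.std(np.log(x), ddof=1) / np.sqrt(x.size)))


def significance_stars(p: float) -> str:
    """Star convention: * ** *** **** at 0.05 / 0.01 / 0.001 / 0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return "ns"


def compare_groups(a, b, label: str = "a vs b") -> TestResult:
    """Two-sided Mann–Whitney U test between two samples.

    Uses the exact null distribution when both samples have at most 8
    observations and the pooled sample is tie-free, and the normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("Mann–Whitney requires non-empty groups")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # Zero-variance degenerate case: no evidence of a difference.
        return TestResult(label, "mann_whitney", float(a.size * b.size / 2.0), 1.0)
    exact = max(a.size, b.size) <= 8 and np.unique(pooled).size == pooled.size
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact" if exact else "asymptotic")
    return TestResult(label, "mann_whitney", float(res.statistic), float(min(res.pvalue, 1.0)))


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni–Holm step-down adjusted p-values (original order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def compare_many(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    omnibus: str = "anova",
) -> tuple[TestResult, list[TestResult]]:
    """Omnibus test across >= 3 groups, with Holm-adjusted post-hoc pairs.

    Returns (omnibus result, post-hoc results); the post-hoc list is
    empty when the omnibus p-value is not below ``alpha``.  Post-hoc
    pairwise comparisons are Mann–Whitney tests.
    """
    if len(groups) < 3:
        raise ValueError("compare_many needs >= 3 groups; use compare_groups for two")
    if omnibus not in ("anova", "kruskal"):
        raise ConfigurationError(f"unknown omnibus '{omnibus}'; use 'anova' or 'kruskal'")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group '{k}' is empty")
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        name = "one_way_anova" if omnibus == "anova" else "kruskal_wallis"
        return TestResult("omnibus", name, 0.0, 1.0), []
    if omnibus == "anova":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = sps.f_oneway(*arrays.values())
        omni = TestResult("omnibus", "one_way_anova", float(stat), float(p))
    else:
        stat, p = sps.kruskal(*arrays.values())
        omni = TestResult("omnibus", "kruskal_wallis", float(stat), float(p))
    if not np.isfinite(omni.p_value):
        omni = TestResult("omnibus", omni.method, 0.0, 1.0)
    posthoc: list[TestResult] = []
    if omni.p_value < alpha:
        labels = list(arrays)
        for i, gi in enumerate(labels):
            for gj in labels[i + 1:]:
                posthoc.append(compare_groups(arrays[gi], arrays[gj], label=f"{gi} vs {gj}"))
        adjusted = holm_adjust([t.p_value for t in posthoc])
        for t, padj in zip(posthoc, adjusted):
            t.p_adjusted = float(padj)
            t.method = "mann_whitney+holm"
    return omni, posthoc


def summarize(values, label: str) -> dict:
    """n, arithmetic mean, and (for all-positive data) GM and GSD."""
    x = np.asarray(values, dtype=float)
    row = {"stratum": label, "n": int(x.size), "mean": float(np.mean(x))}
    if np.all(x > 0):
        row["geometric_mean"] = geometric_mean(x)
        row["geometric_sd"] = geometric_sd(x)
    else:
        row["geometric_mean"] = np.nan
        row["geometric_sd"] = np.nan
    return row


def stratify(
    table: pd.DataFrame,
    by: str,
    value: str,
    alpha: float = 0.05,
    omnibus: str = "anova",
) -> tuple[pd.DataFrame, list[TestResult]]:
    """Per-stratum summaries of ``value`` plus the appropriate test.

    Two strata → Mann–Whitney; three or more → omnibus ANOVA with
    Holm-corrected pairwise post-hocs; a single stratum yields summaries
    only, with a warning.
    """
    for col in (by, value):
        if col not in table.columns:
            raise ConfigurationError(
                f"column '{col}' not in table; available: {sorted(table.columns)}"
            )
    sub = table[[by, value]].dropna()
    levels = sorted(sub[by].unique(), key=str)
    if len(levels) < 1:
        raise ValueError(f"no non-missing data for stratifier '{by}'")
    groups = {str(lv): sub.loc[sub[by] == lv, value].to_numpy(dtype=float) for lv in levels}
    summary = pd.DataFrame([summarize(v, k) for k, v in groups.items()])
    summary.insert(0, "variable", value)
    summary.insert(1, "stratifier", by)
    if len(groups) == 1:
        warnings.warn(f"stratifier '{by}' has a single level; no test performed", stacklevel=2)
        return summary, []
    if len(groups) == 2:
        (la, va), (lb, vb) = groups.items()
        return summary, [compare_groups(va, vb, label=f"{la} vs {lb}")]
    omni, posthoc = compare_many(groups, alpha=alpha, omnibus=omnibus)
    return summary, [omni, *posthoc]


def tests_to_frame(tests: list[TestResult]) -> pd.DataFrame:
    """Flatten test results for CSV export."""
    return pd.DataFrame(
        [
            {
                "comparison": t.label,
                "method": t.method,
                "statistic": t.statistic,
                "p_value": t.p_value,
                "p_adjusted": t.p_adjusted if t.p_adjusted is not None else np.nan,
                "significance": t.stars,
            }
            for t in tests
        ],
        columns=["comparison", "method", "statistic", "p_value", "p_adjusted", "significance"],
    )
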