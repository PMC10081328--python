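"""End-to-end pipeline: synthesis or real inputs → report bundle.

A :class:`PipelineConfig` (usually loaded from YAML) names either input
CSV paths or a synthesis block, plus the dose coefficient, change-group
thresholds, significance level and root seed.  :func:`run_pipeline`
executes every stage — diary validation, annual occupancy, employment-
status imputation, dosimetry, exposure-change classification,
stratified statistics, follower-network indices and intervention
uplift — and writes the result tables plus a machine-readable run log
(seed, input hashes, package versions) to the output directory.
"""
from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import annual_hours, impute_occupancy, occupancy_delta, validate_diaries
from .dosimetry import (
    ChangeThresholds,
    ICRP_DOSE_COEFFICIENT,
    change_group_distribution,
    dose_table,
)
from .errors import ConfigurationError
from .io import write_table
from .network import FollowerNetwork, expected_interactions, uplift
from .stats import stratify, tests_to_frame
from .synthetic import (
    CohortConfig,
    Period,
    generate_cohort,
    generate_diaries,
    generate_follower_network,
    generate_intervention_series,
    generate_radon,
)

#: Demographic variables analysed by default in the stratified stage.
DEFAULT_STRATIFIERS = ("gender", "community", "employment_status", "income_bracket")

_TABLES = ("cohort", "diaries", "radon", "followers", "series")


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration.

    Exactly one of ``inputs[table]`` / synthesis must provide each
    table; supplying both is a configuration error.
    """

    outdir: Path
    seed: int = 0
    kappa: float = ICRP_DOSE_COEFFICIENT
    thresholds: ChangeThresholds = field(default_factory=ChangeThresholds)
    alpha: float = 0.05
    diary_tolerance: float = 1.0
    diary_response_rate: float = 1.0
    stratifiers: tuple[str, ...] = DEFAULT_STRATIFIERS
    mean_posts: float = 3.2
    inputs: dict[str, Path] = field(default_factory=dict)
    cohort_config: CohortConfig | None = None
    network_spec: dict[str, Any] | None = None
    intervention_spec: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.diary_response_rate <= 1:
            raise ConfigurationError(
                f"diary_response_rate must be in (0, 1], got {self.diary_response_rate}"
            )
        synth = {
            "cohort": self.cohort_config,
            "diaries": self.cohort_config,
            "radon": self.cohort_config,
            "followers": self.network_spec,
            "series": self.intervention_spec,
        }
        for table in _TABLES:
            if table in self.inputs and synth[table] is not None:
                raise ConfigurationError(
                    f"table '{table}' is given both as an input path and via synthesis"
                )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw: Mapping[str, Any] = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        synthesis = raw.get("synthesis", {}) or {}
        cohort_cfg = None
        if "cohort" in synthesis:
            kw = dict(synthesis["cohort"] or {})
            kw.setdefault("seed", raw.get("seed", 0))
            cohort_cfg = CohortConfig(**kw)
        thresholds = ChangeThresholds(**(raw.get("change_thresholds") or {}))
        kwargs: dict[str, Any] = dict(
            outdir=Path(raw.get("outdir", "radonshift_out")),
            seed=int(raw.get("seed", 0)),
            kappa=float(raw.get("kappa", ICRP_DOSE_COEFFICIENT)),
            thresholds=thresholds,
            alpha=float(raw.get("alpha", 0.05)),
            diary_tolerance=float(raw.get("diary_tolerance", 1.0)),
            diary_response_rate=float(raw.get("diary_response_rate", 1.0)),
            stratifiers=tuple(raw.get("stratifiers", DEFAULT_STRATIFIERS)),
            mean_posts=float(raw.get("mean_posts", 3.2)),
            inputs={k: Path(v) for k, v in (raw.get("inputs") or {}).items()},
            cohort_config=cohort_cfg,
            network_spec=synthesis.get("network"),
            intervention_spec=synthesis.get("intervention"),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_or_synthesize(config: PipelineConfig):
    from .io import read_table

    tables: dict[str, pd.DataFrame | None] = {t: None for t in _TABLES}
    for table, path in config.inputs.items():
        if table not in _TABLES:
            raise ConfigurationError(f"unknown input table '{table}'; known: {_TABLES}")
        tables[table] = read_table(path, table)

    if config.cohort_config is not None:
        cc = config.cohort_config
        tables["cohort"] = generate_cohort(cc)
        tables["radon"] = generate_radon(tables["cohort"], cc)
        diaries = generate_diaries(tables["cohort"], cc)
        if config.diary_response_rate < 1.0:
            rng = np.random.default_rng(np.random.SeedSequence((config.seed, 99)))
            persons = tables["cohort"]["person_id"].to_numpy()
            keep = persons[rng.random(len(persons)) < config.diary_response_rate]
            diaries = diaries[diaries["person_id"].isin(keep)].reset_index(drop=True)
        tables["diaries"] = diaries

    if config.network_spec is not None:
        spec = config.network_spec
        net = generate_follower_network(
            n_influencers=int(spec["n_influencers"]),
            sizes=spec["sizes"],
            overlap_fractions=spec["overlap_fractions"],
            seed=int(spec.get("seed", config.seed)),
            labels=spec.get("labels"),
        )
        tables["followers"] = net.to_edges()

    if config.intervention_spec is not None:
        spec = config.intervention_spec
        periods = [Period(**p) for p in spec["periods"]]
        tables["series"] = generate_intervention_series(
            daily_baseline=spec["daily_baseline"],
            uplift=spec.get("uplift", {}),
            periods=periods,
            seed=int(spec.get("seed", config.seed)),
        )
    return tables


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every configured stage and write the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = _load_or_synthesize(config)
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        written[name] = write_table(df, outdir / f"{name}.csv")

    for t in _TABLES:
        if tables[t] is not None:
            emit(t, tables[t])

    summary: dict[str, Any] = {}
    if tables["diaries"] is not None:
        diaries = validate_diaries(tables["diaries"], tolerance=config.diary_tolerance)
        occupancy = annual_hours(diaries)
        if tables["cohort"] is not None:
            occupancy = impute_occupancy(tables["cohort"], occupancy)
        emit("occupancy", occupancy)
        delta = occupancy_delta(occupancy)
        emit("occupancy_delta", delta)
        for period in ("pre", "post"):
            summary[f"mean_pct_home_{period}"] = float(
                occupancy.loc[occupancy["period"] == period, "pct_primary_residence"].mean()
            )
        summary["mean_delta_hours_home"] = float(delta["delta_T_home"].mean())
        summary["delta_pct_home_aggregate"] = (
            summary["mean_pct_home_post"] - summary["mean_pct_home_pre"]
        )

        if tables["radon"] is not None:
            doses = dose_table(
                tables["radon"], occupancy, coefficient=config.kappa, thresholds=config.thresholds
            )
            emit("dose", doses)
            emit("change_groups", change_group_distribution(doses))
            gm_pre = float(np.exp(np.mean(np.log(doses["D_pre_msv_y"]))))
            gm_post = float(np.exp(np.mean(np.log(doses["D_post_msv_y"]))))
            summary["dose_gm_pre_msv_y"] = gm_pre
            summary["dose_gm_post_msv_y"] = gm_post
            summary["dose_mean_delta_msv_y"] = float(doses["delta_msv_y"].mean())
            summary["dose_relative_increase_arithmetic_pct"] = float(
                100.0
                * (doses["D_post_msv_y"].mean() - doses["D_pre_msv_y"].mean())
                / doses["D_pre_msv_y"].mean()
            )
            summary["dose_relative_increase_geometric_pct"] = 100.0 * (gm_post / gm_pre - 1.0)

            if tables["cohort"] is not None:
                merged = doses.merge(
                    tables["cohort"], left_on="person_id", right_on="person_id", how="left"
                )
                summaries, tests = [], []
                for var in config.stratifiers:
                    s, t = stratify(merged, var, "delta_msv_y", alpha=config.alpha)
                    summaries.append(s)
                    tf = tests_to_frame(t)
                    tf.insert(0, "stratifier", var)
                    tests.append(tf)
                emit("stratified_summaries", pd.concat(summaries, ignore_index=True))
                emit("stratified_tests", pd.concat(tests, ignore_index=True))

    if tables["followers"] is not None:
        net = FollowerNetwork.from_edges(tables["followers"])
        counts, percent = net.shared_matrix()
        emit("network_shared_counts", counts.reset_index(names="influencer"))
        emit("network_shared_percent", percent.reset_index(names="influencer"))
        emit("network_edges", net.edge_list())
        indices = net.interaction_indices().rename_axis("influencer").reset_index()
        emit("interaction_indices", indices)
        overall = net.overall_interaction_index()
        summary["overall_interaction_index"] = overall
        summary["expected_interactions"] = expected_interactions(overall, config.mean_posts)

    if tables["series"] is not None:
        emit("uplift", uplift(tables["series"]))

    log = {
        "package": "radonshift",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "kappa": config.kappa,
        "alpha": config.alpha,
        "summary": summary,
        "inputs": {k: str(v) for k, v in config.inputs.items()},
        "outputs": {k: _sha256(v) for k, v in written.items()},
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True), encoding="utf-8")
    written["run_log"] = log_path
    return written
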