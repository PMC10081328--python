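"""Synthetic-cohort generators: determinism, calibration, structure."""
import numpy as np
import pandas as pd
import pytest

from radonshift.activity import annual_hours, validate_diaries
from radonshift.errors import ConfigurationError
from radonshift.seasons import ENVIRONMENTS
from radonshift.stats import geometric_mean, geometric_se_factor
from radonshift.synthetic import (
    CohortConfig,
    Period,
    construction_era,
    generate_cohort,
    generate_diaries,
    generate_intervention_series,
    generate_radon,
)

HOUR_COLS = [f"h_{e}" for e in ENVIRONMENTS]


class TestCohortConfig:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_households": 0}, "n_households"),
            ({"radon_gm": -1.0}, "radon_gm"),
            ({"radon_gsd": 0.5}, "radon_gsd"),
            ({"pre_home_fraction_mean": 1.2}, "pre_home_fraction_mean"),
            ({"post_home_fraction_mean": 0.0}, "post_home_fraction_mean"),
            ({"rural_radon_multiplier": 0.0}, "rural_radon_multiplier"),
            ({"shift_age_gradient": -0.1}, "shift_age_gradient"),
        ],
    )
    def test_invalid_values_name_the_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            CohortConfig(**kwargs)


class TestGenerateCohort:
    def test_minimal_cohort_complete_row(self):
        row = generate_cohort(CohortConfig(n_households=1, seed=1)).iloc[0]
        assert row.notna().all()
        assert row["age"] >= 18
        assert row["occupants"] >= 1

    def test_seed_determinism_bit_identical(self):
        cfg = CohortConfig(n_households=500, seed=7)
        pd.testing.assert_frame_equal(generate_cohort(cfg), generate_cohort(cfg))

    def test_geometric_mean_age_recovers_calibration(self):
        cohort = generate_cohort(CohortConfig(seed=7))
        gm = geometric_mean(cohort["age"])
        tol = geometric_se_factor(cohort["age"]) ** 3
        assert 53.9 / tol <= gm <= 53.9 * tol

    def test_newer_homes_hold_younger_working_households(self):
        cohort = generate_cohort(CohortConfig(seed=3))
        era = construction_era(cohort["construction_year"].to_numpy())
        by_era = cohort.assign(era=era).groupby("era")
        ages = by_era["age"].mean()
        assert ages["2006-2020"] < ages["1900-1949"]
        working = by_era.apply(
            lambda g: (g["employment_status"] == "work_education").mean(), include_groups=False
        )
        assert working["2006-2020"] > working["1900-1949"]
        assert by_era["occupants"].mean()["2006-2020"] > by_era["occupants"].mean()["1900-1949"]


class TestGenerateRadon:
    def test_degenerate_dispersion_hits_stratum_medians(self):
        cfg = CohortConfig(n_households=800, radon_gsd=1.0, seed=2)
        cohort = generate_cohort(cfg)
        radon = generate_radon(cohort, cfg)
        era = construction_era(cohort["construction_year"].to_numpy())
        df = pd.DataFrame(
            {"era": era, "community": cohort["community"], "radon": radon["radon_bqm3"]}
        )
        df["rural"] = df["community"] == "rural_isolated"
        for _, grp in df.groupby(["era", "rural"]):
            assert grp["radon"].nunique() == 1

    def test_geometric_mean_recovery(self):
        cfg = CohortConfig(seed=11)
        cohort = generate_cohort(cfg)
        values = generate_radon(cohort, cfg)["radon_bqm3"]
        assert np.all(values > 0)
        gm = geometric_mean(values)
        tol = geometric_se_factor(values) ** 3
        assert 105.3 / tol <= gm <= 105.3 * tol

    def test_rural_multiplier_scales_stratum_geometric_mean(self):
        cfg = CohortConfig(n_households=4000, radon_gsd=1.0, rural_radon_multiplier=1.5, seed=4)
        cohort = generate_cohort(cfg)
        df = cohort.assign(radon=generate_radon(cohort, cfg)["radon_bqm3"])
        gm_rural = geometric_mean(df.loc[df["community"] == "rural_isolated", "radon"])
        gm_urban = geometric_mean(df.loc[df["community"] == "urban", "radon"])
        assert gm_rural / gm_urban == pytest.approx(1.5, rel=0.05)


class TestGenerateDiaries:
    def test_every_day_sums_to_24(self, study_bundle):
        sums = study_bundle["diaries"][HOUR_COLS].sum(axis=1)
        assert np.allclose(sums, 24.0, atol=1e-9)

    def test_non_working_diaries_identical_across_periods(self):
        cfg = CohortConfig(n_households=600, shift_age_gradient=0.0, seed=9)
        cohort = generate_cohort(cfg)
        diaries = generate_diaries(cohort, cfg)
        retirees = cohort.loc[cohort["employment_status"] == "retired", "person_id"]
        assert len(retirees) > 0
        sub = diaries[diaries["person_id"].isin(retirees)]
        pre = sub[sub["period"] == "pre"].drop(columns="period").reset_index(drop=True)
        post = sub[sub["period"] == "post"].drop(columns="period").reset_index(drop=True)
        pd.testing.assert_frame_equal(pre, post)

    def test_mean_home_shift_recovers_calibration(self, study_bundle):
        occ = study_bundle["occupancy"]
        pre = occ[occ["period"] == "pre"].set_index("person_id")["pct_primary_residence"]
        post = occ[occ["period"] == "post"].set_index("person_id")["pct_primary_residence"]
        shift = (post - pre) / 100.0
        se = shift.std() / np.sqrt(len(shift))
        assert abs(shift.mean() - 0.106) <= 3 * se + 1e-9

    def test_seed_determinism(self):
        cfg = CohortConfig(n_households=200, seed=13)
        cohort = generate_cohort(cfg)
        pd.testing.assert_frame_equal(generate_diaries(cohort, cfg), generate_diaries(cohort, cfg))

    def test_diaries_pass_validation(self, study_bundle):
        validate_diaries(study_bundle["diaries"])  # should not raise

    def test_shift_concentrated_in_younger_working_urban(self, study_bundle):
        occ = study_bundle["occupancy"]
        cohort = study_bundle["cohort"]
        pre = occ[occ["period"] == "pre"].set_index("person_id")["T_home"]
        post = occ[occ["period"] == "post"].set_index("person_id")["T_home"]
        shift = (post - pre).rename("shift").reset_index()
        merged = shift.merge(cohort, on="person_id")
        working = merged["employment_status"] == "work_education"
        assert merged.loc[working, "shift"].mean() > merged.loc[~working, "shift"].mean()
        young = merged["age"] < 45
        assert merged.loc[working & young, "shift"].mean() > merged.loc[
            working & ~young, "shift"
        ].mean()
        urbanish = merged["community"].isin(["urban", "suburban"])
        assert merged.loc[working & urbanish, "shift"].mean() > merged.loc[
            working & ~urbanish, "shift"
        ].mean()


class TestInterventionSeries:
    PERIODS = [
        Period("control_before", "2020-04-01", "2020-08-31"),
        Period("case", "2021-04-01", "2021-08-31"),
        Period("control_after", "2022-04-01", "2022-08-31"),
    ]

    def test_unit_uplift_indistinguishable_means(self):
        series = generate_intervention_series(
            {"kit_orders": 40.0}, {"kit_orders": 1.0}, self.PERIODS, seed=2
        )
        means = series.groupby("period_label")["count"].mean()
        se = np.sqrt(40.0 / 153)
        assert abs(means["case"] - means["control_before"]) < 4 * se * np.sqrt(2)

    def test_uplift_recovery(self):
        from radonshift.network import uplift

        series = generate_intervention_series(
            {"kit_orders": 50.0}, {"kit_orders": 1.5}, self.PERIODS, seed=8
        )
        out = uplift(series)
        assert out["uplift_percent"].to_numpy() == pytest.approx(50.0, abs=10.0)

    def test_zero_length_period_is_error(self):
        with pytest.raises(ConfigurationError, match="empty"):
            generate_intervention_series(
                {"m": 5.0}, {}, [Period("case", "2021-05-01", "2021-04-01")], seed=0
            )

    def test_overlapping_periods_are_error(self):
        periods = [
            Period("control_before", "2021-01-01", "2021-03-01"),
            Period("case", "2021-02-15", "2021-04-01"),
        ]
        with pytest.raises(ConfigurationError, match="overlap"):
            generate_intervention_series({"m": 5.0}, {}, periods, seed=0)

    def test_seed_determinism(self):
        a = generate_intervention_series({"m": 9.0}, {"m": 2.0}, self.PERIODS, seed=4)
        b = generate_intervention_series({"m": 9.0}, {"m": 2.0}, self.PERIODS, seed=4)
        pd.testing.assert_frame_equal(a, b)


def test_radon_determinism_full_stack():
    cfg = CohortConfig(n_households=300, seed=21)
    cohort = generate_cohort(cfg)
    pd.testing.assert_frame_equal(generate_radon(cohort, cfg), generate_radon(cohort, cfg))


def test_occupancy_conserves_annual_hours(study_bundle):
    occ = study_bundle["occupancy"]
    totals = occ[[f"T_{e}" for e in ENVIRONMENTS]].sum(axis=1)
    assert np.allclose(totals, 8760.0, atol=1e-6)
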