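import numpy as np
import pandas as pd
import pytest

import sirscan
from sirscan.cohort import build_pseudo_observations
from sirscan.dose import (
    _poisson_loglik,
    aggregate_scenario_dose,
    assign_groups,
    fit_group_poisson,
    fit_individual_dose_model,
)
from sirscan.errors import (
    InvalidArgumentError,
    MissingDataError,
    SingularDesignError,
)
from sirscan.simulate import HazardParams, SimConfig, generate_cohort, \
    simulate_outcomes


def scenarios(rows):
    return pd.DataFrame(rows, columns=["region_id", "dose_mGy"])


class TestScenarioAggregation:
    @pytest.mark.parametrize(
        "doses,method,expected",
        [
            ([1, 3, 9], "median", 3.0),
            ([4.2], "median", 4.2),
            ([4.2], "min", 4.2),
            ([4.2], "max", 4.2),
            ([2, 8], "median", 5.0),
            ([1, 3, 9], "min", 1.0),
            ([1, 3, 9], "max", 9.0),
        ],
    )
    def test_order_statistics(self, doses, method, expected):
        sc = scenarios([(0, d) for d in doses])
        out = aggregate_scenario_dose(sc, method)
        assert out["dose_mGy"].item() == pytest.approx(expected)

    def test_empty_scenarios_rejected(self):
        with pytest.raises(MissingDataError):
            aggregate_scenario_dose(scenarios([]), "median")

    def test_unknown_method_rejected(self):
        with pytest.raises(InvalidArgumentError):
            aggregate_scenario_dose(scenarios([(0, 1.0)]), "mean")


class TestGroupAssignment:
    @pytest.mark.parametrize(
        "dose,group",
        [
            (0.0, "lowest"),
            (1.9, "lowest"),
            (2.0, "middle-low"),
            (4.9, "middle-low"),
            (5.0, "middle-high"),
            (9.9, "middle-high"),
            (10.0, "highest"),
            (50.0, "highest"),
        ],
    )
    def test_half_open_cutpoints(self, dose, group):
        out = assign_groups(pd.DataFrame({"region_id": [0], "dose_mGy": [dose]}))
        assert out["group"].item() == group

    def test_exactly_one_dummy_per_region(self):
        out = assign_groups(
            pd.DataFrame({"region_id": range(4), "dose_mGy": [1, 3, 7, 20]})
        )
        dummies = out[[c for c in out.columns if c.startswith("z_")]]
        assert (dummies.sum(axis=1) == 1).all()

    def test_negative_dose_rejected(self):
        with pytest.raises(InvalidArgumentError):
            assign_groups(pd.DataFrame({"region_id": [0], "dose_mGy": [-1.0]}))


def region_frame(o, e, gidx):
    return pd.DataFrame(
        {"region_id": np.arange(len(o)), "observed": o, "expected": e,
         "group_index": gidx}
    )


class TestGroupPoisson:
    def test_single_group_recovers_global_sir(self):
        df = region_frame([3.0, 5.0, 2.0], [2.0, 4.0, 2.0], [0, 0, 0])
        res = fit_group_poisson(df)
        assert res.table.loc[0, "rr"] == pytest.approx(10 / 8, rel=1e-8)

    def test_balanced_group_has_unit_rr(self):
        df = region_frame([4.0, 2.0, 6.0], [3.0, 3.0, 6.0], [0, 0, 1])
        res = fit_group_poisson(df)
        assert res.table.loc[0, "rr"] == pytest.approx(1.0, rel=1e-8)
        assert res.table.loc[1, "rr"] == pytest.approx(1.0, rel=1e-8)

    def test_rrs_equal_groupwise_ratio_exactly(self):
        rng = np.random.default_rng(2)
        e = rng.uniform(1, 5, 40)
        gidx = rng.integers(0, 4, 40)
        o = rng.poisson(e * (1 + gidx * 0.4)).astype(float)
        res = fit_group_poisson(region_frame(o, e, gidx))
        for k in range(4):
            m = gidx == k
            assert res.table.loc[k, "rr"] == pytest.approx(
                o[m].sum() / e[m].sum(), rel=1e-8
            )

    def test_loglik_matches_direct_evaluation(self):
        rng = np.random.default_rng(3)
        e = rng.uniform(1, 5, 30)
        gidx = rng.integers(0, 4, 30)
        o = rng.poisson(e * 1.2).astype(float)
        res = fit_group_poisson(region_frame(o, e, gidx))
        rr = res.table["rr"].to_numpy()[gidx]
        assert res.loglik == pytest.approx(
            _poisson_loglik(o, e * rr), abs=1e-8
        )
        assert res.aic == pytest.approx(2 * 4 - 2 * res.loglik)
        assert res.null_aic == pytest.approx(-2 * _poisson_loglik(o, e))

    def test_aic_gap_invariant_to_region_order(self):
        rng = np.random.default_rng(4)
        e = rng.uniform(1, 5, 25)
        gidx = rng.integers(0, 4, 25)
        o = rng.poisson(e).astype(float)
        res = fit_group_poisson(region_frame(o, e, gidx))
        perm = rng.permutation(25)
        res2 = fit_group_poisson(region_frame(o[perm], e[perm], gidx[perm]))
        assert res.aic - res.null_aic == pytest.approx(
            res2.aic - res2.null_aic, abs=1e-9
        )

    def test_empty_group_reported_undefined(self):
        df = region_frame([3.0, 5.0], [2.0, 4.0], [0, 1])
        res = fit_group_poisson(df)
        assert np.isnan(res.table.loc[3, "rr"])
        assert res.table.loc[3, "n_regions"] == 0
        assert res.table.loc[3, "observed"] == 0.0

    def test_trend_test_calibrated_under_null(self):
        """Score-based trend test rejects at ~5% under homogeneous risk."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_data = 500
        e = rng.uniform(1, 5, 40)
        gidx = rng.integers(0, 4, 40)
        for _ in range(n_data):
            o = rng.poisson(e).astype(float)
            if o.sum() == 0:
                continue
            res = fit_group_poisson(region_frame(o, e, gidx))
            rejections += res.trend_p < 0.05
        assert 0.03 <= rejections / n_data <= 0.07


@pytest.fixture(scope="module")
def cohort_pseudo(planar12):
    cfg = SimConfig(n_subjects=60_000, seed=21, bmi_error_rate=0.0)
    cohort = simulate_outcomes(
        generate_cohort(cfg, planar12), HazardParams(), planar12, seed=21
    )
    return build_pseudo_observations(cohort)


class TestIndividualDoseModel:
    def test_constant_group_dummy_is_singular(self, cohort_pseudo):
        groups = assign_groups(
            pd.DataFrame({"region_id": range(12), "dose_mGy": 20.0})
        )
        with pytest.raises(SingularDesignError):
            fit_individual_dose_model(cohort_pseudo, groups)

    def test_unassigned_region_rejected(self, cohort_pseudo):
        groups = assign_groups(
            pd.DataFrame({"region_id": range(6), "dose_mGy": 1.0})
        )
        with pytest.raises(MissingDataError):
            fit_individual_dose_model(cohort_pseudo, groups)

    def test_group_hazard_ratios_cover_null(self, planar12):
        """With no true group effect, group HR CIs cover 1 in ~95% of fits."""
        rng = np.random.default_rng(17)
        doses = pd.DataFrame(
            {"region_id": range(12),
             "dose_mGy": [1, 1, 1, 3, 3, 3, 7, 7, 7, 15, 15, 15]}
        )
        groups = assign_groups(doses)
        cover = 0
        n_rep = 40
        for r in range(n_rep):
            n = 40_000
            pseudo = pd.DataFrame(
                {
                    "y": np.zeros(n, dtype=int),
                    "d": rng.uniform(1.5, 2.5, n),
                    "sex": rng.integers(0, 2, n).astype(float),
                    "log_age": np.log(rng.uniform(4, 25, n)),
                    "log_bmi": np.log(rng.uniform(14, 30, n)),
                    "round3": rng.integers(0, 2, n).astype(float),
                    "region_id": rng.integers(0, 12, n),
                }
            )
            eta = -9.5 + 0.25 * pseudo["sex"] + 0.8 * pseudo["log_age"]
            lam = 1 - np.exp(-pseudo["d"] * np.exp(eta))
            pseudo["y"] = (rng.random(n) < lam).astype(int)
            if pseudo["y"].sum() < 5:
                continue
            fit = fit_individual_dose_model(
                pseudo, groups, covariates=("sex", "log_age")
            )
            hr = fit.hazard_ratios().set_index("term")
            dose_terms = [t for t in hr.index if t.startswith("dose_")]
            cover += all(
                hr.loc[t, "hr_lo"] <= 1.0 <= hr.loc[t, "hr_hi"]
                for t in dose_terms
            )
        # joint coverage of three 95% intervals: expect ~0.86-0.99
        assert cover / n_rep >= 0.8
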