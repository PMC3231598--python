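"""RMSE, comparison regressions, single-ISE baseline, paired t-test."""

from dataclasses import replace

import numpy as np
import pytest
import scipy.stats

from etongue.activity import ActivityModelParams
from etongue.characterize import fit_calibration
from etongue.design import DEFAULT_IONS, single_ion_calibration
from etongue.errors import InputError
from etongue.evaluate import (
    comparison_regression,
    paired_t_test,
    relative_errors,
    rmse,
    single_ise_baseline,
)
from etongue.sensors import SensorSpec, array_response
from etongue.tables import make_sample_table

CLO4, S = DEFAULT_IONS


class TestRmse:
    def test_perfect_prediction_is_zero(self):
        x = np.array([[1e-4, 2e-4], [3e-5, 5e-5]])
        res = rmse(x, x)
        assert res.pooled == 0.0

    def test_hand_value(self):
        # single-ion pairs (0, 3e-5) and (4e-5, 0): sqrt((9+16)/2)·1e-5
        pred = np.array([[0.0], [4e-5]])
        exp = np.array([[3e-5], [0.0]])
        res = rmse(pred, exp, ion_names=("x",))
        assert res.pooled == pytest.approx(np.sqrt(12.5) * 1e-5, rel=1e-12)

    def test_invariant_under_permutation(self, rng):
        pred = rng.uniform(0, 3e-4, (12, 2))
        exp = rng.uniform(0, 3e-4, (12, 2))
        perm = rng.permutation(12)
        assert rmse(pred, exp).pooled == pytest.approx(
            rmse(pred[perm], exp[perm]).pooled, rel=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            rmse(np.zeros((3, 2)), np.zeros((4, 2)))


class TestComparisonRegression:
    def test_identity_data(self):
        x = np.linspace(1e-5, 3e-4, 10)
        reg = comparison_regression(x, x)
        assert reg.slope == pytest.approx(1.0, abs=1e-12)
        assert reg.intercept == pytest.approx(0.0, abs=1e-16)
        assert reg.r == pytest.approx(1.0, abs=1e-12)
        assert reg.contains_unity_slope and reg.contains_zero_intercept

    def test_confidence_intervals_match_statsmodels(self, rng):
        import statsmodels.api as sm

        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.9])
        reg = comparison_regression(y, x)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        ci = fit.conf_int(alpha=0.05)
        assert reg.intercept_ci == pytest.approx(tuple(ci[0]), rel=1e-9)
        assert reg.slope_ci == pytest.approx(tuple(ci[1]), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            comparison_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestSingleIseBaseline:
    @pytest.fixture()
    def fitted_electrode(self):
        params = ActivityModelParams(fixed_background_ionic_strength=0.05)
        sensor = SensorSpec(
            id="E", primary_ion=CLO4, e0=180.0, slope=-57.0,
            background_activity=4e-6,
        )
        cal = single_ion_calibration(CLO4, n_points=12, c_min=1e-6, c_max=1e-3)
        E = array_response([sensor], cal, DEFAULT_IONS, params)["E"]
        fit = fit_calibration(
            E.to_numpy(), table=cal, ion=CLO4, params=params, sensor_id="E"
        )
        return sensor, fit, params

    def test_identity_on_single_ion_samples_across_four_decades(
        self, fitted_electrode
    ):
        sensor, fit, params = fitted_electrode
        conc = np.geomspace(1e-6, 1e-2, 12)
        samples = make_sample_table(
            DEFAULT_IONS, np.column_stack([conc, np.zeros_like(conc)])
        )
        pot = array_response([sensor], samples, DEFAULT_IONS, params)
        pred, flags = single_ise_baseline(
            pot, {"E": fit}, {"ClO4": "E"}, DEFAULT_IONS, params
        )
        assert np.allclose(pred["ClO4"].to_numpy(), conc, rtol=1e-6)

    def test_interference_at_parity_doubles_the_estimate(self, fitted_electrode):
        sensor, fit, params = fitted_electrode
        sensor2 = replace(sensor, selectivity={"S": -2.0})
        # choose sulfide so that k·a_S^(1/2) equals the perchlorate activity
        c_p = 1e-4
        from etongue.sensors import sample_activities

        probe = make_sample_table(DEFAULT_IONS, [[c_p, 0.0]])
        a_p = sample_activities(probe, DEFAULT_IONS, params)[0, 0]
        target_a_s = (a_p / 10.0**-2.0) ** 2
        # iterate the sulfide concentration to hit the target activity
        c_s = target_a_s
        for _ in range(30):
            t = make_sample_table(DEFAULT_IONS, [[c_p, c_s]])
            a_s = sample_activities(t, DEFAULT_IONS, params)[0, 1]
            c_s *= target_a_s / a_s
        pot = array_response([sensor2], t, DEFAULT_IONS, params)
        pred, _ = single_ise_baseline(
            pot, {"E": fit}, {"ClO4": "E"}, DEFAULT_IONS, params
        )
        assert pred["ClO4"].iloc[0] == pytest.approx(2 * c_p, rel=0.02)

    def test_out_of_span_readings_flagged(self, fitted_electrode):
        sensor, fit, params = fitted_electrode
        samples = make_sample_table(DEFAULT_IONS, [[5e-2, 0.0], [1e-8, 0.0]])
        pot = array_response([sensor], samples, DEFAULT_IONS, params)
        _, flags = single_ise_baseline(
            pot, {"E": fit}, {"ClO4": "E"}, DEFAULT_IONS, params
        )
        assert flags["ClO4"].to_numpy().all()


class TestRelativeErrors:
    def test_exact_and_five_percent(self):
        pred = np.array([[1e-4, 1.05e-4]])
        exp = np.array([[1e-4, 1.0e-4]])
        rep = relative_errors(pred, exp, ion_names=("a", "b"))
        assert rep.aggregate["ET"]["a"] == 0.0
        assert rep.aggregate["ET"]["b"] == pytest.approx(5.0, rel=1e-9)

    def test_zero_expected_rows_excluded_and_counted(self):
        pred = np.array([[1e-4, 1e-4], [1e-4, 1e-4]])
        exp = np.array([[1e-4, 0.0], [0.0, 2e-4]])
        rep = relative_errors(pred, exp)
        assert rep.n_excluded == 2
        assert len(rep.table) == 2


class TestPairedTTest:
    def test_identical_pairs_give_zero(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert not res.significant

    def test_critical_value_df5_95(self):
        res = paired_t_test(np.zeros(6), np.zeros(6))
        assert res.df == 5
        assert res.critical == pytest.approx(2.57, abs=0.005)

    def test_hand_three_pair_toy(self):
        pred = np.array([1.0, 2.0, 4.0])
        nom = np.array([0.9, 2.2, 3.5])
        d = pred - nom
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        res = paired_t_test(pred, nom)
        assert res.t == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_on_random_datasets(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 12))
            a = rng.normal(0, 1, n)
            b = a + rng.normal(0, 0.5, n)
            res = paired_t_test(a, b)
            oracle = scipy.stats.ttest_rel(a, b)
            assert res.t == pytest.approx(oracle.statistic, abs=1e-9)

    def test_zero_variance_nonzero_mean_reports_infinite_t(self):
        res = paired_t_test([1.0, 2.0], [2.0, 3.0])
        assert np.isinf(res.t)
        assert res.significant
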