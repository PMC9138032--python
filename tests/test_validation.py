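"""LOO cross-validation, conformity regression, precision study, matrix effect."""

import numpy as np
import pandas as pd
import pytest

import sulfispec as s


def _table(conc, area):
    return pd.DataFrame({"conc_um": conc, "area_au": area, "day": 1, "replicate": 1})


class TestLooCV:
    def test_noiseless_data_recalculates_exactly(self, noiseless_standards):
        recalc = s.loo_cv(noiseless_standards, "linear")
        np.testing.assert_allclose(recalc, noiseless_standards["area_au"], atol=1e-9)

    def test_matches_fold_by_fold_oracle_on_toy_set(self):
        conc = np.array([1.0, 2.0, 3.0, 4.0])
        area = np.array([1.0, 2.1, 2.9, 4.2])
        recalc = s.loo_cv(_table(conc, area), "linear")
        # independent oracle: refit each fold explicitly
        oracle = []
        for i in range(4):
            keep = np.arange(4) != i
            b, a = np.polyfit(conc[keep], area[keep], 1)
            oracle.append(a + b * conc[i])
        np.testing.assert_allclose(recalc, oracle, atol=1e-10)

    @pytest.mark.parametrize("kind", ["linear", "parabolic"])
    def test_matches_fold_by_fold_oracle_on_seeded_table(self, kind):
        table = s.gen_calibration_dataset(noise_sd=0.514, replicates_per_level=2, n_days=1, seed=9)
        recalc = s.loo_cv(table, kind)
        conc = table["conc_um"].to_numpy()
        area = table["area_au"].to_numpy()
        deg = 1 if kind == "linear" else 2
        oracle = []
        for i in range(len(table)):
            keep = np.arange(len(table)) != i
            coefs = np.polyfit(conc[keep], area[keep], deg)
            oracle.append(np.polyval(coefs, conc[i]))
        np.testing.assert_allclose(recalc, oracle, atol=1e-8)

    def test_order_equivariance(self, noisy_standards):
        recalc = s.loo_cv(noisy_standards, "linear")
        perm = np.random.default_rng(0).permutation(len(noisy_standards))
        shuffled = noisy_standards.iloc[perm].reset_index(drop=True)
        np.testing.assert_allclose(s.loo_cv(shuffled, "linear"), recalc[perm], atol=1e-10)

    def test_recalculated_value_independent_of_own_response(self, noisy_standards):
        i = 7
        recalc = s.loo_cv(noisy_standards, "linear")
        tampered = noisy_standards.copy()
        tampered.loc[i, "area_au"] = 1e4
        assert s.loo_cv(tampered, "linear")[i] == pytest.approx(recalc[i], rel=1e-12)


class TestRecalcRegression:
    def test_identity_conforms(self):
        y = np.random.default_rng(1).normal(10, 3, size=20)
        cv = s.validate_recalc_regression(y, y)
        assert cv.conforms
        assert cv.line_intercept == pytest.approx(0.0, abs=1e-10)
        assert cv.line_slope == pytest.approx(1.0, abs=1e-12)

    def test_doubled_responses_fail_slope_test(self):
        y = np.linspace(1, 20, 25)
        cv = s.validate_recalc_regression(y, 2 * y + np.random.default_rng(0).normal(0, 0.1, 25))
        assert not cv.conforms

    def test_noiseless_cv_line_is_exactly_zero_one(self, noiseless_standards):
        recalc = s.loo_cv(noiseless_standards, "linear")
        cv = s.validate_recalc_regression(noiseless_standards["area_au"].to_numpy(), recalc)
        assert (cv.line_intercept, cv.line_slope) == (pytest.approx(0.0, abs=1e-9), pytest.approx(1.0, abs=1e-9))
        assert cv.conforms

    def test_calibration_mode_r_squared_equals_fit_r_squared(self, noisy_standards):
        model = s.fit_calibration(noisy_standards, "linear")
        fitted = s.predict_area(model, noisy_standards["conc_um"].to_numpy())
        cv = s.validate_recalc_regression(
            noisy_standards["area_au"].to_numpy(), fitted, mode="calibration"
        )
        assert cv.r_squared == pytest.approx(model.r_squared, rel=1e-10)

    def test_zero_variance_experimental_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            s.validate_recalc_regression(np.ones(5), np.arange(5.0))

    def test_joint_ellipse_option_agrees_on_clear_cases(self):
        y = np.linspace(1, 20, 25)
        rng = np.random.default_rng(3)
        good = y + rng.normal(0, 0.05, 25)
        assert s.validate_recalc_regression(y, good, joint=True).conforms
        assert not s.validate_recalc_regression(y, 2 * y + rng.normal(0, 0.05, 25), joint=True).conforms


class TestPrecisionStudy:
    def test_identical_areas_degenerate_but_pass(self):
        table = pd.DataFrame(
            {
                "conc_um": np.repeat([1.0, 2.0, 4.0], 6),
                "area_au": np.repeat([3.0, 6.0, 12.0], 6),
                "day": np.tile([1, 1, 2, 2, 3, 3], 3),
                "replicate": np.tile([1, 2] * 3, 3),
            }
        )
        report = s.precision_study(table)
        assert (report.intra_day["cv_percent"] == 0).all()
        assert "zero_variance" in report.flags
        assert report.passes

    def test_t_statistic_matches_pooled_variance_formula(self, linear_truth):
        table = s.gen_calibration_dataset(
            linear_truth, conc_levels=[3.0], replicates_per_level=5, n_days=2,
            noise_sd=0.5, seed=21,
        )
        report = s.precision_study(table)
        x = table.loc[table["day"] == 1, "area_au"].to_numpy()
        y = table.loc[table["day"] == 2, "area_au"].to_numpy()
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (len(x) + len(y) - 2)
        t_oracle = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        assert report.t_tests["t_statistic"].iloc[0] == pytest.approx(t_oracle, abs=1e-10)

    def test_large_day_offsets_fail_at_alpha(self, linear_truth):
        # day offsets at 5x the replicate noise must surface as significant
        table = s.gen_calibration_dataset(
            linear_truth, conc_levels=[0.8, 1.6, 3.0, 6.0], replicates_per_level=5,
            n_days=3, noise_sd=0.1, day_effect_sd=0.5, seed=2,
        )
        report = s.precision_study(table)
        assert not report.passes

    def test_single_day_flags_missing_interday(self, linear_truth):
        table = s.gen_calibration_dataset(linear_truth, n_days=1, seed=0)
        report = s.precision_study(table)
        assert report.inter_day is None and "single_day" in report.flags


class TestMatrixEffect:
    def test_reference_pairs_reproduce_recoveries_and_verdict(self):
        result = s.matrix_effect_assess(
            {5.0: 25.0, 12.5: 180.0, 25.0: 400.0},
            {5.0: 22.0, 12.5: 100.0, 25.0: 200.0},
        )
        np.testing.assert_allclose(
            result.recoveries["recovery"], [0.88, 0.5556, 0.50], atol=5e-4
        )
        assert result.concentration_dependent
        assert result.verdict == "concentration-dependent trapping"

    def test_identical_maps_give_unit_recovery_no_trapping(self):
        areas = {5.0: 25.0, 12.5: 180.0, 25.0: 400.0}
        result = s.matrix_effect_assess(areas, dict(areas))
        assert (result.recoveries["recovery"] == 1.0).all()
        assert not result.concentration_dependent

    def test_small_fluctuations_within_tolerance_are_negative(self):
        result = s.matrix_effect_assess(
            {1.0: 100.0, 2.0: 100.0, 3.0: 100.0},
            {1.0: 90.0, 2.0: 88.0, 3.0: 91.0},
        )
        assert not result.concentration_dependent

    def test_zero_standard_area_rejected(self):
        with pytest.raises(ValueError, match="zero standard area"):
            s.matrix_effect_assess({5.0: 0.0}, {5.0: 1.0})
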