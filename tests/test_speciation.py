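"""Three-pool arithmetic, arm quantification, cohort statistics, mass check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import sulfispec as s
from sulfispec.speciation import dunnett_max_abs_t_cdf


class TestSpeciate:
    def test_difference_arithmetic(self):
        r = s.speciate(1.0, 3.0, 7.0)
        assert (r.acid_labile, r.bound_sulfane) == (2.0, 4.0)
        assert not r.flags

    def test_equal_levels_give_zero_pools(self):
        r = s.speciate(2.0, 2.0, 2.0)
        assert r.acid_labile == r.bound_sulfane == 0.0

    def test_negative_difference_flagged_not_clipped(self):
        r = s.speciate(2.0, 1.0, 5.0)
        assert r.acid_labile == -1.0
        assert "negative_difference" in r.flags

    def test_below_loq_flagged(self):
        r = s.speciate(0.3, 1.0, 2.0, loq=0.9)
        assert "below_loq" in r.flags

    @settings(max_examples=100, derandomize=True)
    @given(
        free=st.floats(0, 50, allow_nan=False),
        acid=st.floats(0, 50, allow_nan=False),
        total=st.floats(0, 50, allow_nan=False),
    )
    def test_conservation_for_all_inputs(self, free, acid, total):
        r = s.speciate(free, acid, total)
        assert r.free + r.acid_labile + r.bound_sulfane == pytest.approx(r.total, abs=1e-9)


class TestQuantifyArm:
    def test_identical_injections_equal_single_inversion(self, linear_truth):
        single = s.invert_calibration(linear_truth, 10.0).conc
        arm = s.quantify_arm(linear_truth, [10.0, 10.0, 10.0])
        assert arm.conc == pytest.approx(single, rel=1e-12)
        assert arm.sd < s.invert_calibration(linear_truth, 10.0).sd

    def test_roundtrip_through_forward_prediction(self, linear_truth):
        area = s.predict_area(linear_truth, 2.0)
        arm = s.quantify_arm(linear_truth, [area] * 3)
        assert arm.conc == pytest.approx(2.0, rel=1e-12)

    def test_out_of_range_area_flagged_not_dropped(self, linear_truth):
        arm = s.quantify_arm(linear_truth, [1e3, 1e3, 1e3])
        assert "out_of_range" in arm.flags
        assert np.isfinite(arm.conc)

    @pytest.mark.parametrize("n_seeds", [200])
    def test_recovery_within_propagated_sd(self, linear_truth, n_seeds):
        """Seeded noisy injections: truth within 3 propagated SD nearly always."""
        truth = 3.0
        mu = s.predict_area(linear_truth, truth)
        hits = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            arm = s.quantify_arm(linear_truth, mu + rng.normal(0, 0.514, size=3))
            hits += abs(arm.conc - truth) <= 3 * arm.sd
        assert hits / n_seeds >= 0.99


class TestCohortStats:
    def test_constant_cohort_is_degenerate_with_zero_change(self):
        cohort = pd.DataFrame(
            {
                "patient_id": np.repeat(["P1", "P2", "P3"], 3),
                "timepoint": np.tile(["T0", "T1", "T2"], 3),
                "species": "total",
                "concentration_um": 2.0,
            }
        )
        out = s.cohort_stats(cohort)
        assert (out["percent_change"] == 0).all()
        assert out["zero_variance"].all()
        assert out["dunnett_p"].isna().all()

    def test_missing_cell_rejected_by_name(self):
        cohort = s.gen_serum_cohort(s.CohortScenario(seed=0))
        broken = cohort[~((cohort["patient_id"] == "P2") & (cohort["timepoint"] == "T1"))]
        with pytest.raises(ValueError, match="P2.*T1"):
            s.cohort_stats(broken)

    def test_two_timepoint_dunnett_reduces_to_paired_t(self):
        cohort = s.gen_serum_cohort(s.CohortScenario(seed=3))
        two = cohort[cohort["timepoint"].isin(["T0", "T2"])]
        out = s.cohort_stats(two, species=["free"])
        wide = two[two["species"] == "free"].pivot_table(
            index="patient_id", columns="timepoint", values="concentration_um"
        )
        t_oracle = stats.ttest_rel(wide["T2"], wide["T0"])
        got = out.loc[out["timepoint"] == "T2", "dunnett_p"].iloc[0]
        assert got == pytest.approx(t_oracle.pvalue, abs=1e-6)

    def test_reference_percent_change_is_zero(self):
        cohort = s.cohort_with_total(s.gen_serum_cohort(s.CohortScenario(seed=7)))
        out = s.cohort_stats(cohort)
        ref = out[out["timepoint"] == "T0"]
        assert (ref["percent_change"] == 0).all()

    def test_rm_anova_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        cohort = s.gen_serum_cohort(s.CohortScenario(seed=11))
        out = s.cohort_stats(cohort, species=["bound_sulfane"])
        sub = cohort[cohort["species"] == "bound_sulfane"]
        oracle = pg.rm_anova(
            data=sub, dv="concentration_um", within="timepoint", subject="patient_id"
        )["p_unc"].iloc[0]
        assert out["rm_anova_p"].iloc[0] == pytest.approx(oracle, rel=1e-6)

    def test_synthetic_effect_detected_for_total_only(self):
        cohort = s.cohort_with_total(
            s.gen_serum_cohort(s.CohortScenario(t2_total_increase=0.4, seed=11))
        )
        out = s.cohort_stats(cohort, species=["total", "free"])
        total_t2 = out[(out["species"] == "total") & (out["timepoint"] == "T2")].iloc[0]
        free_t2 = out[(out["species"] == "free") & (out["timepoint"] == "T2")].iloc[0]
        assert 35 <= total_t2["percent_change"] <= 45
        assert total_t2["dunnett_p"] < 0.05
        assert free_t2["dunnett_p"] >= 0.05


class TestDunnettDistribution:
    @pytest.mark.parametrize("df,rho,k,u", [(3, 0.5, 2, 2.5), (10, 0.3, 3, 2.0)])
    def test_quadrature_matches_monte_carlo_oracle(self, df, rho, k, u):
        rng = np.random.default_rng(2024)
        n = 200_000
        R = np.full((k, k), rho)
        np.fill_diagonal(R, 1.0)
        X = rng.standard_normal((n, k)) @ np.linalg.cholesky(R).T
        S = np.sqrt(rng.chisquare(df, n) / df)
        mc = np.mean(np.max(np.abs(X / S[:, None]), axis=1) <= u)
        assert dunnett_max_abs_t_cdf(u, df, rho, k) == pytest.approx(mc, abs=0.01)

    def test_single_contrast_is_exact_student_t(self):
        assert dunnett_max_abs_t_cdf(2.0, 5, 0.5, 1) == pytest.approx(
            2 * stats.t.cdf(2.0, 5) - 1, abs=1e-12
        )


class TestMonoisotopicMass:
    # independent oracle: hand-summed NIST monoisotopic masses
    MASSES = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048, "O": 15.99491461956, "S": 31.972071}

    def test_sdb_molecular_ion(self):
        counts = {"C": 20, "H": 22, "N": 4, "O": 4, "S": 1}
        oracle = sum(self.MASSES[e] * n for e, n in counts.items()) + 1.00727646
        assert s.monoisotopic_mz(s.SDB_FORMULA) == pytest.approx(round(oracle, 2))
        assert s.monoisotopic_mz(s.SDB_FORMULA) == 415.14

    def test_neutral_hydrogen_sulfide_mass(self):
        h2s = s.ElementalFormula({"H": 2, "S": 1})
        oracle = 2 * self.MASSES["H"] + self.MASSES["S"]
        assert s.monoisotopic_mz(h2s, decimals=4) == pytest.approx(round(oracle, 4))
        assert s.monoisotopic_mz(h2s, decimals=4) == 33.9877

    def test_empty_formula_rejected(self):
        with pytest.raises(ValueError):
            s.ElementalFormula({})

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="Xx"):
            s.monoisotopic_mz(s.ElementalFormula({"Xx": 1}))

    def test_charge_division(self):
        doubly = s.ElementalFormula({"C": 20, "H": 22, "N": 4, "O": 4, "S": 1}, adduct="plus_H", charge=2)
        singly = s.monoisotopic_mz(s.SDB_FORMULA, decimals=None)
        assert s.monoisotopic_mz(doubly, decimals=None) < singly
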