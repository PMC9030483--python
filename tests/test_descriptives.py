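"""Summary tables, POD ANOVA, correlations, and zero-RPP fractions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rppdecay import (
    GeneratorConfig,
    anova_rpp,
    correlation_matrix,
    simulate_cohort,
    summarize_cohort,
    zero_rpp_fraction,
)
from rppdecay.descriptives import summary_frame, volumes_at_pod
from conftest import make_cohort


class TestSummarize:
    def test_hand_arithmetic(self):
        table = make_cohort({"A": {3: 1.0}, "B": {3: 2.0}, "C": {3: 3.0}})
        rows = {r.variable: r for r in summarize_cohort(table)}
        r = rows["rpp_pod3_mL"]
        assert (r.n, r.mean, r.median) == (3, 2.0, 2.0)
        assert (r.iqr_low, r.iqr_high) == (1.5, 2.5)  # linear-interpolation quantiles

    def test_missing_value_reduces_n(self):
        table = make_cohort({f"P{i}": {3: float(i + 1)} for i in range(5)})
        table.patients.loc[0, "insufflation_min"] = np.nan
        rows = {r.variable: r for r in summarize_cohort(table)}
        assert rows["insufflation_min"].n == 4
        assert rows["age"].n == 5

    def test_resolved_patients_imputed_as_zero(self):
        table = make_cohort({"A": {3: 0.0}, "B": {3: 4.0, 5: 2.0}})
        table.measurements = table.measurements  # A has no POD-5 row
        rows = {r.variable: r for r in summarize_cohort(table)}
        assert rows["rpp_pod5_mL"].n == 2
        assert rows["rpp_pod5_mL"].mean == pytest.approx(1.0)  # (0 + 2) / 2

    def test_order_invariance(self):
        table = simulate_cohort(GeneratorConfig(n_patients=200, seed=14))
        shuffled = make_like = table
        perm = np.random.default_rng(0).permutation(len(table.measurements))
        shuffled.measurements = table.measurements.iloc[perm].reset_index(drop=True)
        a = summary_frame(summarize_cohort(table))
        b = summary_frame(summarize_cohort(shuffled))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_cohort_rejected(self):
        table = make_cohort({"A": {3: 1.0}})
        table.patients = table.patients.iloc[:0]
        table.measurements = table.measurements.iloc[:0]
        with pytest.raises(ValueError):
            summarize_cohort(table)


class TestAnova:
    def test_identical_values_give_f_zero_p_one(self):
        table = make_cohort({p: {3: 5.0, 5: 5.0, 7: 5.0} for p in "ABCD"})
        res = anova_rpp(table)
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_two_groups_f_is_squared_t(self):
        table = make_cohort(
            {p: {3: v3, 5: v5} for p, v3, v5 in
             [("A", 3.0, 1.0), ("B", 5.0, 2.0), ("C", 4.0, 1.5), ("D", 6.0, 2.5)]}
        )
        res = anova_rpp(table, scale="raw")
        g3 = [3.0, 5.0, 4.0, 6.0]
        g5 = [1.0, 2.0, 1.5, 2.5]
        t, _ = stats.ttest_ind(g3, g5)
        assert res.f_statistic == pytest.approx(t**2)
        assert (res.df_between, res.df_within) == (1, 6)

    def test_three_group_fixture_matches_hand_anova(self):
        # groups (1,2,3), (2,3,4), (4,5,6): SSB = 14, SSW = 6, F = (14/2)/(6/6) = 7
        table = make_cohort(
            {
                "A": {3: 1.0, 5: 2.0, 7: 4.0},
                "B": {3: 2.0, 5: 3.0, 7: 5.0},
                "C": {3: 3.0, 5: 4.0, 7: 6.0},
            }
        )
        res = anova_rpp(table, scale="raw")
        assert res.f_statistic == pytest.approx(7.0)
        assert res.p_value == pytest.approx(stats.f.sf(7.0, 2, 6))

    def test_matches_statsmodels_on_log_scale(self):
        """Independent cross-check of the default log-shift ANOVA."""
        import statsmodels.formula.api as smf
        import statsmodels.api as sm

        table = simulate_cohort(GeneratorConfig(n_patients=150, seed=15))
        res = anova_rpp(table)
        df = table.measurements.assign(y=np.log1p(table.measurements["volume_mL"]))
        fit = smf.ols("y ~ C(pod)", df).fit()
        aov = sm.stats.anova_lm(fit)
        assert res.f_statistic == pytest.approx(float(aov["F"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(aov["PR(>F)"].iloc[0]), rel=1e-9)

    def test_single_group_rejected(self):
        table = make_cohort({"A": {3: 1.0}, "B": {3: 2.0}})
        with pytest.raises(ValueError):
            anova_rpp(table)

    def test_default_calibration_decay_is_significant(self):
        table = simulate_cohort(GeneratorConfig(n_patients=500, seed=16))
        assert anova_rpp(table).p_value < 1e-10


class TestCorrelation:
    def test_unit_diagonal_and_symmetry(self):
        table = simulate_cohort(GeneratorConfig(n_patients=60, seed=17))
        cm = correlation_matrix(table)
        assert np.allclose(np.diag(cm.corr), 1.0)
        assert np.allclose(cm.corr, cm.corr.T, equal_nan=True)

    def test_perfect_anticorrelation(self):
        table = make_cohort({f"P{i}": {3: 1.0 + i} for i in range(6)})
        table.patients["age"] = [50.0 + i for i in range(6)]
        table.patients["op_duration_min"] = [300.0 - (50.0 + i) for i in range(6)]
        cm = correlation_matrix(table)
        assert cm.corr.loc["age", "op_duration_min"] == pytest.approx(-1.0)

    def test_constant_variable_flagged_not_zeroed(self):
        table = make_cohort({f"P{i}": {3: 1.0 + i} for i in range(6)})
        # height is constant in the hand-built fixture
        with pytest.warns(UserWarning, match="constant"):
            cm = correlation_matrix(table)
        assert "height_cm" in cm.degenerate
        assert np.isnan(cm.corr.loc["height_cm", "age"])

    def test_bmi_negatively_correlated_with_pod3_volume(self):
        """The generator encodes the obesity effect seen in the cohort."""
        table = simulate_cohort(GeneratorConfig(n_patients=3000, seed=18))
        cm = correlation_matrix(table)
        assert cm.corr.loc["bmi", "rpp_pod3_mL"] < -0.05
        assert cm.pvalues.loc["bmi", "rpp_pod3_mL"] < 0.001

    def test_spearman_option(self):
        table = simulate_cohort(GeneratorConfig(n_patients=100, seed=19))
        cm = correlation_matrix(table, method="spearman")
        assert np.allclose(np.diag(cm.corr), 1.0)


class TestZeroFraction:
    def test_ten_of_thirtyone(self):
        vols = {f"P{i:02d}": {3: 0.0 if i < 10 else 5.0} for i in range(31)}
        table = make_cohort(vols)
        assert zero_rpp_fraction(table, 3) == pytest.approx(10 / 31)

    def test_extremes(self):
        assert zero_rpp_fraction(make_cohort({"A": {3: 0.0}, "B": {3: 0.0}}), 3) == 1.0
        assert zero_rpp_fraction(make_cohort({"A": {3: 1.0}, "B": {3: 2.0}}), 3) == 0.0

    def test_resolved_patient_counts_as_zero_later(self):
        table = make_cohort({"A": {3: 0.0}, "B": {3: 4.0, 5: 2.0}})
        assert zero_rpp_fraction(table, 5) == pytest.approx(0.5)
        vols = volumes_at_pod(table, 5)
        assert vols["A"] == 0.0 and vols["B"] == 2.0

    def test_uninformative_pod_rejected(self):
        table = make_cohort({"A": {3: 1.0}})
        with pytest.raises(ValueError, match="no information"):
            zero_rpp_fraction(table, 6)

    def test_monotone_rise_under_default_calibration(self):
        table = simulate_cohort(GeneratorConfig(n_patients=30_000, seed=20))
        fracs = [zero_rpp_fraction(table, pod) for pod in (3, 5, 7)]
        assert fracs[0] < fracs[1] < fracs[2]
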