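"""Conditional-independence tests: oracle identities, calibration,
symmetry, and the Bonferroni decision rule."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from asecausal.ci import (
    CiTestResult,
    DegenerateInputError,
    bonferroni_decide,
    gcm_test,
    kci_test,
    micg_test,
    results_to_frame,
)
from asecausal.graph import CiStatement

from conftest import seeds


def _micg_lr_oracle(table, x, y, z_cont, z_disc):
    """Twice the log-likelihood ratio of stratum-wise Gaussian regressions
    of y on (x + continuous z) versus (continuous z) alone."""
    total = 0.0
    groups = table.groupby(z_disc) if z_disc else [(None, table)]
    for _, grp in groups:
        zc = grp[z_cont].to_numpy() if z_cont else np.empty((len(grp), 0))
        full = sm.OLS(grp[y].to_numpy(),
                      sm.add_constant(np.column_stack([grp[x].to_numpy(), zc]))
                      ).fit()
        restricted = sm.OLS(grp[y].to_numpy(),
                            sm.add_constant(zc) if zc.size else
                            np.ones((len(grp), 1))).fit()
        total += 2.0 * (full.llf - restricted.llf)
    return total


class TestMicg:
    def test_statistic_equals_likelihood_ratio_oracle(self, default_cohort):
        cases = [
            ("M", "S", ["A"], ["G"]),
            ("F", "S", ["A", "M"], ["G"]),
            ("M", "D", ["A", "F"], ["G"]),
            ("M", "S", ["A"], []),  # no discrete conditioning
        ]
        for x, y, zc, zd in cases:
            stmt = CiStatement(x, y, set(zc) | set(zd))
            res = micg_test(default_cohort, stmt)
            oracle = _micg_lr_oracle(default_cohort, x, y, zc, zd)
            assert res.statistic == pytest.approx(oracle, rel=1e-10)
            assert res.df == (2 if zd else 1)

    def test_symmetric_in_x_and_y(self, default_cohort):
        a = micg_test(default_cohort, CiStatement("M", "S", {"A", "G"}))
        b = micg_test(default_cohort, CiStatement("S", "M", {"A", "G"}))
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_exact_copy_is_degenerate(self, default_cohort):
        t = default_cohort.copy()
        t["M2"] = t["M"]
        with pytest.raises(DegenerateInputError):
            micg_test(t, CiStatement("M", "M2", {"A", "G"}))

    def test_small_stratum_raises(self, default_cohort):
        t = default_cohort.head(8).copy()
        # one gender stratum is tiny relative to |continuous z| + 3
        with pytest.raises(DegenerateInputError):
            micg_test(t, CiStatement("F", "S", {"A", "G", "M"}))

    def test_p_value_is_chi2_upper_tail(self, default_cohort):
        res = micg_test(default_cohort, CiStatement("M", "S", {"A", "G"}))
        assert res.p_value == pytest.approx(
            stats.chi2.sf(res.statistic, res.df))

    def test_discrete_override(self, default_cohort):
        # forcing all conditioners continuous yields a single stratum
        res = micg_test(default_cohort, CiStatement("M", "S", {"A", "G"}),
                        discrete=[])
        assert res.df == 1


# 6-row worked table: values chosen by hand, small integers
WORKED = pd.DataFrame({
    "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
    "y": [2.0, 1.0, 4.0, 3.0, 6.0, 5.0],
    "z": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
})


class TestGcm:
    def test_worked_example_matches_hand_computed_oracle(self):
        # explicit least-squares residuals, then the normalized mean of
        # their products — computed here with raw linear algebra
        Z = sm.add_constant(WORKED["z"].to_numpy())
        rx = WORKED["x"] - Z @ np.linalg.lstsq(Z, WORKED["x"], rcond=None)[0]
        ry = WORKED["y"] - Z @ np.linalg.lstsq(Z, WORKED["y"], rcond=None)[0]
        R = (rx * ry).to_numpy()
        expected = np.sqrt(6) * R.mean() / R.std()
        res = gcm_test(WORKED, CiStatement("x", "y", {"z"}), regressor="linear")
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.p_value == pytest.approx(
            2 * stats.norm.sf(abs(expected)), rel=1e-12)

    def test_null_calibration_linear(self):
        # independent Gaussians: |T| < 3 in at least 99% of seeds
        extreme = 0
        for s in seeds(77, 200):
            rng = np.random.default_rng(s)
            df = pd.DataFrame(rng.normal(size=(500, 3)), columns=["x", "y", "z"])
            res = gcm_test(df, CiStatement("x", "y", {"z"}), regressor="linear")
            extreme += abs(res.statistic) >= 3
        assert extreme <= 2

    def test_empty_z_is_covariance_test(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.normal(size=200)})
        df["y"] = 0.5 * df["x"] + rng.normal(size=200)
        res = gcm_test(df, CiStatement("x", "y"), regressor="linear")
        rx = df["x"] - df["x"].mean()
        ry = df["y"] - df["y"].mean()
        R = (rx * ry).to_numpy()
        assert res.statistic == pytest.approx(
            np.sqrt(200) * R.mean() / R.std(), rel=1e-12)
        assert res.p_value < 0.01

    def test_affine_invariance_linear(self, default_cohort):
        stmt = CiStatement("M", "S", {"A", "G"})
        base = gcm_test(default_cohort, stmt, regressor="linear")
        t = default_cohort.copy()
        t["M"] = 3.0 * t["M"] - 7.0
        t["S"] = -2.0 * t["S"] + 11.0
        scaled = gcm_test(t, stmt, regressor="linear")
        # statistic flips sign with one negative rescaling, same magnitude
        assert abs(scaled.statistic) == pytest.approx(
            abs(base.statistic), rel=1e-9)
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-9)

    def test_symmetric_in_x_and_y(self, default_cohort):
        stmt = CiStatement("M", "S", {"A", "G"})
        rev = CiStatement("S", "M", {"A", "G"})
        a = gcm_test(default_cohort, stmt, regressor="linear")
        b = gcm_test(default_cohort, rev, regressor="linear")
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_boosted_learner_runs(self, default_cohort):
        res = gcm_test(default_cohort, CiStatement("M", "S", {"A", "G"}),
                       regressor="boosted", seed=3)
        assert 0.0 <= res.p_value <= 1.0

    def test_boosted_needs_twenty_rows(self, default_cohort):
        with pytest.raises(DegenerateInputError):
            gcm_test(default_cohort.head(10), CiStatement("M", "S"),
                     regressor="boosted")


class TestKci:
    def test_null_calibration_unconditional(self):
        rejected = 0
        for s in seeds(123, 200):
            rng = np.random.default_rng(s)
            df = pd.DataFrame({"x": rng.normal(size=300),
                               "y": rng.normal(size=300)})
            rejected += kci_test(df, CiStatement("x", "y")).p_value < 0.05
        # binomial 4-sigma band around the nominal 0.05
        assert 0.05 - 4 * np.sqrt(0.05 * 0.95 / 200) <= rejected / 200 \
            <= 0.05 + 4 * np.sqrt(0.05 * 0.95 / 200)

    def test_power_on_near_copy(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x": rng.normal(size=100)})
        df["y"] = df["x"] + 0.3 * rng.normal(size=100)
        assert kci_test(df, CiStatement("x", "y")).p_value < 0.01

    def test_conditional_blocks_common_cause(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=400)
        df = pd.DataFrame({
            "z": z,
            "x": z + rng.normal(size=400),
            "y": -z + rng.normal(size=400),
        })
        dependent = kci_test(df, CiStatement("x", "y"))
        conditioned = kci_test(df, CiStatement("x", "y", {"z"}))
        assert dependent.p_value < 0.01  # marginally dependent
        assert conditioned.p_value > 0.01  # independent given the cause

    def test_deterministic(self, default_cohort):
        stmt = CiStatement("F", "S", {"A", "G", "M"})
        a = kci_test(default_cohort, stmt, seed=1)
        b = kci_test(default_cohort, stmt, seed=2)  # seed is interface-only
        assert a.statistic == b.statistic and a.p_value == b.p_value

    def test_constant_column_is_degenerate(self, default_cohort):
        t = default_cohort.copy()
        t["C"] = 1.0
        with pytest.raises(DegenerateInputError):
            kci_test(t, CiStatement("C", "M"))


class TestBonferroni:
    def _result(self, p):
        return CiTestResult("GCM", CiStatement("x", "y"), 0.0, p, 60)

    def test_family_of_five(self):
        decided = bonferroni_decide(
            [self._result(0.001), self._result(0.0101)], 5, 0.05)
        assert decided[0].rejected is True
        assert decided[1].rejected is False
        assert decided[0].alpha == pytest.approx(0.01)

    def test_family_of_one_is_plain_alpha(self):
        decided = bonferroni_decide([self._result(0.04)], 1, 0.05)
        assert decided[0].rejected is True

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_decide([self._result(0.5)], 5, 1.5)


class TestResultContainers:
    def test_df_only_for_micg(self):
        with pytest.raises(ValueError):
            CiTestResult("GCM", CiStatement("x", "y"), 0.0, 0.5, 60, df=2)
        with pytest.raises(ValueError):
            CiTestResult("MIcg", CiStatement("x", "y"), 0.0, 0.5, 60)

    def test_tidy_frame(self, default_cohort):
        res = bonferroni_decide(
            [micg_test(default_cohort, CiStatement("M", "S", {"A", "G"}))],
            5, 0.05)
        frame = results_to_frame(res)
        assert list(frame.columns) == [
            "x", "y", "z", "method", "statistic", "df", "p_value", "n",
            "alpha", "rejected"]
        assert frame.loc[0, "z"] == "A,G"
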