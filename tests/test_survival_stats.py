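import numpy as np
import pandas as pd
import pytest
from scipy import stats

from repeatratio import (
    cox_fit,
    cox_score_test,
    forest_table,
    km_estimate,
    logrank_test,
)


def km_product_limit_oracle(time, event):
    """Brute-force product-limit: S(t) = prod over event times (1 - d/n)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    out_t, out_s = [], []
    s = 1.0
    for t in np.unique(time[event == 1]):
        n_at_risk = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1 - d / n_at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


class TestKaplanMeier:
    def test_three_event_toy(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.times, [1, 2, 3])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(curve.at_risk, [3, 2, 1])

    def test_all_censored_is_flat_one(self):
        curve = km_estimate([5, 8, 13], [0, 0, 0])
        assert curve.times.size == 0 and curve.survival.size == 0

    def test_censoring_shrinks_risk_set_without_step(self):
        # censor at t=1.5: the t=2 step divides by 2 instead of 3
        curve = km_estimate([1, 1.5, 2, 3], [1, 0, 1, 1])
        np.testing.assert_allclose(curve.survival, [3 / 4, 3 / 8, 0.0])

    def test_matches_product_limit_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(3, 25)
            time = np.round(rng.exponential(10, n), 1) + 0.1
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            curve = km_estimate(time, event)
            ot, os_ = km_product_limit_oracle(time, event)
            np.testing.assert_allclose(curve.times, ot)
            np.testing.assert_allclose(curve.survival, os_, atol=1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        time = rng.exponential(5, 40) + 0.01
        curve = km_estimate(time, np.ones(40, dtype=int))
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((time > t).mean(), abs=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_are_null(self):
        t = [1, 2, 3, 4.0]
        e = [1, 1, 0, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0, abs=1e-12)
        assert p == pytest.approx(1, abs=1e-12)

    def test_hand_computed_observed_minus_expected(self):
        # groups (1,2) vs (3,4), all events: O_A=2, E_A=1/2+1/3=5/6,
        # V=1/4+2/9=17/36, chi2=(7/6)^2/(17/36)=49/17
        chi2, p = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx(49 / 17, rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(49 / 17, 1), rel=1e-9)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(3)
        ta, tb = rng.exponential(5, 20), rng.exponential(9, 25)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        ea[0] = 1
        ab = logrank_test(ta, ea, tb, eb)
        ba = logrank_test(tb, eb, ta, ea)
        assert ab == pytest.approx(ba)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="at least one event"):
            logrank_test([1, 2], [0, 0], [3], [0])

    def test_null_type_one_error_calibrated(self):
        """Equal exponential groups: rejection rate near nominal 0.05."""
        rng = np.random.default_rng(17)
        rejections = 0
        reps = 400
        for _ in range(reps):
            ta, tb = rng.exponential(1, 30), rng.exponential(1, 30)
            _, p = logrank_test(ta, np.ones(30), tb, np.ones(30))
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestCox:
    def _sim(self, rng, n=100, beta=1.0):
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(np.exp(-beta * x))
        return pd.DataFrame({"time": t, "event": 1, "x": x})

    def test_score_test_equals_logrank_without_ties(self):
        rng = np.random.default_rng(5)
        df = self._sim(rng, n=60)
        chi2_lr, _ = logrank_test(
            df.loc[df.x == 0, "time"], df.loc[df.x == 0, "event"],
            df.loc[df.x == 1, "time"], df.loc[df.x == 1, "event"],
        )
        chi2_score, p = cox_score_test(df["time"], df["event"], df["x"])
        assert chi2_score == pytest.approx(chi2_lr, abs=1e-6)
        assert 0 <= p <= 1

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(6)
        df = self._sim(rng, n=400, beta=1.0)
        fit = cox_fit(df, ["x"])
        assert fit.summary.loc["x", "coef"] == pytest.approx(1.0, abs=0.3)
        assert fit.converged

    def test_ci_reproduces_coef_pm_1p96_se(self):
        rng = np.random.default_rng(7)
        fit = cox_fit(self._sim(rng, n=120), ["x"])
        row = fit.summary.loc["x"]
        assert row["ci_low"] == pytest.approx(
            np.exp(row["coef"] - 1.96 * row["se"]), abs=1e-9
        )
        assert row["ci_high"] == pytest.approx(
            np.exp(row["coef"] + 1.96 * row["se"]), abs=1e-9
        )

    def test_categorical_reference_coding(self):
        rng = np.random.default_rng(8)
        df = self._sim(rng, n=90)
        df["risk"] = rng.choice(["favorable", "intermediate", "adverse"], 90)
        fit = cox_fit(df, ["x", "risk"],
                      reference_levels={"risk": "favorable"})
        assert fit.reference_levels == {"risk": "favorable"}
        assert {"risk[intermediate]", "risk[adverse]", "x"} == set(
            fit.summary.index
        )

    def test_constant_covariate_named_in_error(self):
        df = pd.DataFrame(
            {"time": [1.0, 2, 3, 4], "event": [1, 1, 1, 1], "flat": 1.0}
        )
        with pytest.raises(ValueError, match="flat"):
            cox_fit(df, ["flat"])

    def test_rows_with_missing_covariates_dropped_and_logged(self, caplog):
        rng = np.random.default_rng(9)
        df = self._sim(rng, n=50)
        df.loc[:2, "x"] = np.nan
        with caplog.at_level("WARNING"):
            fit = cox_fit(df, ["x"])
        assert fit.n == 47
        assert "dropping 3" in caplog.text

    def test_null_covariate_ci_coverage(self):
        """CI for a no-effect covariate covers HR=1 at roughly 95%."""
        rng = np.random.default_rng(10)
        covered = 0
        reps = 200
        for _ in range(reps):
            n = 80
            x = rng.integers(0, 2, n).astype(float)
            df = pd.DataFrame(
                {"time": rng.exponential(1, n), "event": 1, "x": x}
            )
            row = cox_fit(df, ["x"]).summary.loc["x"]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert 0.90 <= covered / reps <= 0.99


class TestForestTable:
    def test_reference_levels_listed_at_unit_hazard(self):
        rng = np.random.default_rng(12)
        n = 100
        grp = rng.choice(["low", "mid", "high"], n)
        df = pd.DataFrame(
            {
                "time": rng.exponential(np.where(grp == "low", 0.4, 1.0)),
                "event": 1,
                "stratum": grp,
            }
        )
        fit = cox_fit(df, ["stratum"], reference_levels={"stratum": "mid"})
        table = forest_table(fit)
        assert table.loc["stratum[mid] (reference)", "hr"] == 1.0
        assert len(table) == 3
        for name in ("stratum[low]", "stratum[high]"):
            row = fit.summary.loc[name]
            assert table.loc[name, "ci_low"] == pytest.approx(
                np.exp(row["coef"] - 1.96 * row["se"]), abs=1e-9
            )
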