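"""Cox PH, Kaplan-Meier, log-rank and maxstat against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import stimscreen as ss
from stimscreen.survival import standardized_logrank


def breslow_neg_loglik(beta, time, x):
    # tie-free data: Breslow == Efron
    ll = 0.0
    for i in range(len(time)):
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return -ll


class TestCox:
    def test_toy_matches_partial_likelihood_maximiser(self):
        """Non-separable 4-record toy vs golden-section oracle to 1e-6."""
        df = pd.DataFrame(
            {"time_days": [1.0, 2, 3, 4], "event": [1, 1, 1, 1], "x": [0.0, 1, 0, 1]}
        )
        cox = ss.fit_cox(df, ["x"])
        oracle = minimize_scalar(
            breslow_neg_loglik,
            args=(df.time_days.to_numpy(), df.x.to_numpy()),
            bounds=(-10, 10),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert cox.loc["x", "coef"] == pytest.approx(oracle.x, abs=1e-6)

    def test_time_scale_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "time_days": rng.exponential(100, 80),
                "event": 1,
                "x": rng.integers(0, 2, 80).astype(float),
            }
        )
        a = ss.fit_cox(df, ["x"]).loc["x", "coef"]
        df2 = df.assign(time_days=df.time_days * 37.0)
        b = ss.fit_cox(df2, ["x"]).loc["x", "coef"]
        assert a == pytest.approx(b, abs=1e-8)

    def test_constant_covariate_errors(self):
        df = pd.DataFrame({"time_days": [1.0, 2, 3], "event": [1, 1, 1], "x": 1.0})
        with pytest.raises(ValueError, match="constant"):
            ss.fit_cox(df, ["x"])

    def test_categorical_reference_coding(self):
        rng = np.random.default_rng(2)
        n = 300
        grp = rng.choice(["C3", "C4"], n)
        rate = np.where(grp == "C3", 2.0, 1.0)
        df = pd.DataFrame(
            {"time_days": rng.exponential(1 / rate), "event": 1, "cluster": grp}
        )
        cox = ss.fit_cox(df, ["cluster"], reference={"cluster": "C4"})
        assert "cluster[C3]" in cox.index
        assert cox.loc["cluster[C3]", "coef"] == pytest.approx(np.log(2), abs=0.25)


class TestKaplanMeier:
    def test_hand_example_no_censoring(self):
        df = pd.DataFrame({"time_days": [1.0, 2, 3], "event": [1, 1, 1]})
        km = ss.kaplan_meier(df)["all"].set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(2 / 3)
        assert km.loc[2.0] == pytest.approx(1 / 3)
        assert km.loc[3.0] == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        df = pd.DataFrame({"time_days": [5.0, 7, 9], "event": [0, 0, 0]})
        km = ss.kaplan_meier(df)["all"]
        assert np.allclose(km["survival"], 1.0)

    def test_monotone_within_unit_interval(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "time_days": rng.exponential(10, 50),
                "event": rng.integers(0, 2, 50),
            }
        )
        km = ss.kaplan_meier(df)["all"]["survival"].to_numpy()
        assert np.all(np.diff(km) <= 1e-12)
        assert km.min() >= 0 and km.max() <= 1

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(5, 40)
        df = pd.DataFrame({"time_days": t, "event": 1})
        km = ss.kaplan_meier(df)["all"].set_index("time")["survival"]
        for time_point in np.sort(t):
            assert km.loc[time_point] == pytest.approx((t > time_point).mean())


class TestLogrank:
    def test_equals_cox_score_test_at_zero(self):
        """U and V match the Breslow partial-likelihood score and information."""
        rng = np.random.default_rng(5)
        n = 40
        time = rng.exponential(1, n)  # continuous: no ties
        group = rng.integers(0, 2, n)
        _, u, v = standardized_logrank(time, np.ones(n, int), group)
        order = np.argsort(time)
        t, x = time[order], group[order].astype(float)
        score = 0.0
        info = 0.0
        for i in range(n):
            risk = t >= t[i]
            m1 = x[risk].mean()
            m2 = (x[risk] ** 2).mean()
            score += x[i] - m1
            info += m2 - m1**2
        assert u == pytest.approx(score, abs=1e-8)
        assert v == pytest.approx(info, abs=1e-8)


class TestMaxstat:
    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(6)
        n = 50
        marker = rng.normal(size=n)
        time = np.where(marker > np.median(marker), rng.exponential(1, n),
                        rng.exponential(4, n))
        rec = pd.DataFrame({"time_days": time, "event": 1})
        res = ss.maxstat_cutpoint(marker, rec, n_perm=50, seed=0)
        qlo, qhi = np.quantile(marker, [0.1, 0.9])
        best = max(
            (
                abs(standardized_logrank(time, np.ones(n, int), (marker > c).astype(int))[0])
                for c in np.unique(marker)
                if qlo <= c <= qhi and c < marker.max()
            ),
        )
        assert res.statistic == pytest.approx(best, abs=0.0)
        # the chosen cutpoint separates the two planted marker groups
        assert abs(res.cutpoint - np.median(marker)) < np.quantile(np.abs(marker), 0.5)

    def test_null_marker_permutation_p_not_small(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n = 40
            rec = pd.DataFrame(
                {"time_days": rng.exponential(1, n), "event": 1}
            )
            marker = rng.normal(size=n)
            res = ss.maxstat_cutpoint(marker, rec, n_perm=200, seed=seed)
            hits += res.p_value > 0.05
        assert hits >= 18  # null p rarely small

    def test_constant_marker_errors(self):
        rec = pd.DataFrame({"time_days": np.arange(1.0, 13.0), "event": 1})
        with pytest.raises(ValueError, match="constant"):
            ss.maxstat_cutpoint(np.ones(12), rec)


class TestTTest:
    def test_paired_identical_is_exact_null(self):
        x = np.array([1.0, 2, 3])
        res = ss.two_sample_t_test(x, x, paired=True)
        assert res.t == 0.0 and res.p == 1.0

    def test_hand_example(self):
        res = ss.two_sample_t_test([0.9, 1.0, 1.1], [-0.1, 0.0, 0.1])
        assert res.t == pytest.approx(12.2474487, abs=1e-6)
        assert res.df == 4

    def test_degenerate_flagged(self):
        res = ss.two_sample_t_test([1.0, 1.0], [2.0, 2.0])
        assert res.degenerate and np.isnan(res.p)
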