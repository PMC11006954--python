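"""Stability-selection LASSO clock: selection, calibration, acceleration, LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import glycoage as ga


def cd_lasso_oracle(X, y, lam, n_iter=2000):
    """Independent coordinate-descent LASSO at fixed penalty.

    Minimises (1/2n)||y - Xb||^2 + lam * ||b||_1 on centered data
    (no intercept); X assumed standardized.
    """
    n, p = X.shape
    yc = y - y.mean()
    b = np.zeros(p)
    col_sq = (X**2).sum(axis=0) / n
    for _ in range(n_iter):
        for j in range(p):
            r = yc - X @ b + X[:, j] * b[j]
            rho = X[:, j] @ r / n
            b[j] = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_sq[j]
    return b


def signal_frame(n=200, p_noise=5, beta=2.0, noise=0.5, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, 1 + p_noise)),
        columns=["x1"] + [f"n{i}" for i in range(p_noise)],
    )
    y = beta * X["x1"].to_numpy() + rng.normal(0, noise, n)
    return X, y


class TestCvLassoRound:
    def test_strong_signal_recovery(self):
        X, y = signal_frame()
        _, selected = ga.cv_lasso_round(X, y, seed=1)
        assert "x1" in selected
        assert len(selected) <= 3  # one-SE rule keeps the model sparse

    def test_pure_noise_selects_nearly_nothing(self):
        """At lambda_1se a null response keeps any noise feature rarely."""
        rates = {f: 0 for f in "abcdef"}
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.normal(size=(200, 6)), columns=list("abcdef"))
            y = rng.normal(size=200)
            _, selected = ga.cv_lasso_round(X, y, seed=seed)
            for f in selected:
                rates[f] += 1
        assert all(r / n_seeds < 0.4 for r in rates.values())

    def test_full_fit_matches_coordinate_descent_oracle(self):
        """The penalized fit behind selection agrees with an independent
        coordinate-descent solver at the same penalty."""
        from sklearn.linear_model import Lasso

        X, y = signal_frame(n=120, p_noise=3, seed=4)
        Xs = (X - X.mean()) / X.std(ddof=0)
        lam = 0.1
        skl = Lasso(alpha=lam, max_iter=50_000, tol=1e-10).fit(Xs, y)
        oracle = cd_lasso_oracle(Xs.to_numpy(), np.asarray(y), lam)
        assert np.allclose(skl.coef_, oracle, atol=1e-6)

    def test_path_monotonicity(self):
        """Selected-set size is non-increasing as the penalty grows."""
        from sklearn.linear_model import lasso_path

        X, y = signal_frame(n=150, seed=7)
        Xs = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        lams = np.logspace(0.5, -3, 40)
        _, coefs, _ = lasso_path(Xs, y - y.mean(), alphas=lams)
        counts = (coefs != 0).sum(axis=0)  # lams decreasing along axis 1
        assert np.all(np.diff(counts) >= 0)

    def test_constant_response_errors(self):
        X, _ = signal_frame(n=50)
        with pytest.raises(ValueError, match="constant"):
            ga.cv_lasso_round(X, np.ones(50))

    def test_too_few_rows_errors(self):
        X, y = signal_frame(n=8)
        with pytest.raises(ValueError, match="at least"):
            ga.cv_lasso_round(X, y, n_folds=5)


class TestStabilitySelect:
    def test_degenerate_single_round(self):
        X, y = signal_frame(seed=2)
        freq, final = ga.stability_select(X, y, rounds=1, keep_threshold=1, base_seed=5)
        _, one_round = ga.cv_lasso_round(X, y, seed=5)
        assert final == one_round
        assert all(freq[f] == 1 for f in one_round)

    def test_planted_signal_recovered(self):
        """2 informative + 8 noise features: informatives selected >= 80/100,
        noise features < 80/100."""
        rng = np.random.default_rng(42)
        n = 300
        X = pd.DataFrame(
            rng.normal(size=(n, 10)),
            columns=["s1", "s2"] + [f"n{i}" for i in range(8)],
        )
        y = X["s1"] + X["s2"] + rng.normal(0, 0.5, n)
        freq, final = ga.stability_select(X, y, rounds=100, keep_threshold=80, base_seed=17)
        assert freq["s1"] >= 80 and freq["s2"] >= 80
        assert {"s1", "s2"} <= set(final)
        assert all(freq[f"n{i}"] < 80 for i in range(8))

    def test_reproducible_given_base_seed(self):
        X, y = signal_frame(seed=3)
        out1 = ga.stability_select(X, y, rounds=5, keep_threshold=4, base_seed=9)
        out2 = ga.stability_select(X, y, rounds=5, keep_threshold=4, base_seed=9)
        assert out1 == out2

    def test_empty_selection_warns(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = rng.normal(size=100)
        with pytest.warns(UserWarning, match="no features"):
            ga.stability_select(X, y, rounds=3, keep_threshold=3, base_seed=1)

    def test_bad_parameters(self):
        X, y = signal_frame(n=60)
        with pytest.raises(ValueError):
            ga.stability_select(X, y, rounds=0)
        with pytest.raises(ValueError):
            ga.stability_select(X, y, rounds=10, keep_threshold=11)


class TestFitClock:
    def test_exact_linear_fit(self):
        X = pd.DataFrame({"x": np.arange(20.0)})
        age = 50.0 + 1.0 * X["x"]
        model = ga.fit_clock(X, age, ("x",))
        assert model.intercept == pytest.approx(50.0, abs=1e-9)
        assert model.coefficients[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(model.predict(X), age)

    def test_zero_mean_calibration(self, small_bundle):
        """Mean(predicted - chronological) on training controls is 0."""
        cohort, profiles = small_bundle.cohort, small_bundle.profiles
        ctrl = cohort[(cohort.sex == "M") & (cohort.hiv == "negative")]
        cols = ["A2", "FA2", "FA2B", "A2G2S2"]
        model = ga.fit_clock(profiles.loc[ctrl.index, cols], ctrl.age, cols)
        resid = model.predict(profiles.loc[ctrl.index, cols]) - ctrl.age
        assert abs(resid.mean()) < 1e-8

    def test_matches_lstsq_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
        age = 55 + rng.normal(size=80)
        model = ga.fit_clock(X, age, ("a", "b", "c"))
        D = np.column_stack([np.ones(80), X.to_numpy()])
        beta, *_ = np.linalg.lstsq(D, age, rcond=None)
        assert np.allclose([model.intercept, *model.coefficients], beta, atol=1e-8)

    def test_collinear_features_error(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="collinear"):
            ga.fit_clock(X, np.arange(10.0), ("a", "b"))


class TestAgeAcceleration:
    def test_null_cases(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=300)})
        age = 55 + 5 * X["x"] + rng.normal(0, 1, 300)
        model = ga.fit_clock(X.iloc[:150], age[:150], ("x",))
        res = ga.age_acceleration(
            model, X.iloc[150:], age[150:], X.iloc[:150], age[:150]
        )
        assert abs(res.group_mean) < 1.0
        assert res.p_value > 0.01

    def test_single_sample_delta_is_definition(self):
        model = ga.ClockModel(features=("x",), coefficients=(2.0,), intercept=10.0)
        X = pd.DataFrame({"x": [3.0]})
        res = ga.age_acceleration(model, X, [12.0])
        assert res.per_sample_delta[0] == pytest.approx(10 + 6 - 12)

    def test_missing_feature_errors(self):
        model = ga.ClockModel(features=("x",), coefficients=(1.0,), intercept=0.0)
        with pytest.raises(KeyError, match="missing"):
            model.predict(pd.DataFrame({"y": [1.0]}))

    def test_planted_offset_recovered_on_bundle(self):
        """A 3.5-year planted displacement is read back by the clock chain."""
        cfg = ga.GeneratorConfig(
            n_per_group={("M", "negative"): 200, ("M", "positive"): 200},
            planted_acceleration=3.5,
            seed=21,
        )
        b = ga.generate_cohort(cfg)
        cohort, profiles = b.cohort, b.profiles
        cols = [c for c in profiles.columns if c != "UNIDENTIFIED"]
        ctrl = cohort[cohort.hiv == "negative"]
        case = cohort[cohort.hiv == "positive"]
        _, selected = ga.cv_lasso_round(profiles.loc[ctrl.index, cols], ctrl.age, seed=2)
        model = ga.fit_clock(profiles.loc[ctrl.index, cols], ctrl.age, selected)
        res = ga.age_acceleration(
            model, profiles.loc[case.index, cols], case.age,
            profiles.loc[ctrl.index, cols], ctrl.age,
        )
        assert res.group_mean == pytest.approx(3.5, abs=1.0)
        assert res.p_value < 0.001


class TestNestedLrt:
    def test_identical_models_lr_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=list("ab"))
        y = X["a"] + rng.normal(0, 0.5, 50)
        small = ga.fit_clock(X, y, ("a",))
        large = ga.fit_clock(X, y, ("a", "b"))
        lr, df, p = ga.nested_lrt(small, large, X, y)
        assert lr >= 0 and df == 1

    def test_non_nested_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=list("ab"))
        y = rng.normal(size=30)
        m1 = ga.fit_clock(X, y, ("a",))
        m2 = ga.fit_clock(X, y, ("b",))
        with pytest.raises(ValueError, match="subset"):
            ga.nested_lrt(m1, m2, X, y)

    def test_lr_nonnegative_always(self, rng):
        """Adding features never increases RSS."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(40, 3)), columns=list("abc"))
            y = r.normal(size=40)
            small = ga.fit_clock(X, y, ("a",))
            large = ga.fit_clock(X, y, ("a", "b", "c"))
            lr, _, _ = ga.nested_lrt(small, large, X, y)
            assert lr >= 0

    def test_null_distribution_matches_chisq(self):
        """Under the null (extra features are noise) the LR statistic follows
        chi-square(df): KS p > 0.01 over 1,000 simulations."""
        rng = np.random.default_rng(123)
        n, df_extra = 400, 2
        lrs = np.empty(1000)
        for i in range(1000):
            X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
            y = 2 * X["a"].to_numpy() + rng.normal(size=n)
            small = ga.fit_clock(X, y, ("a",))
            large = ga.fit_clock(X, y, ("a", "b", "c"))
            lrs[i], _, _ = ga.nested_lrt(small, large, X, y)
        ks = sps.kstest(lrs, sps.chi2(df_extra).cdf)
        assert ks.pvalue > 0.01


def test_screen_markers_by_age(small_bundle):
    """Markers loaded on age-trending glycan groups pass the FDR gate;
    unloaded markers mostly do not."""
    cohort, markers = small_bundle.cohort, small_bundle.markers
    women = cohort[cohort.sex == "F"]
    screen = ga.screen_markers_by_age(markers.loc[women.index], women.age)
    screen = screen.set_index("marker")
    assert screen.loc["CXCL9", "selected"]
    assert screen.loc["IP-10", "selected"]
    unloaded = ["IL-2", "IL-8", "MCP-1", "GM-CSF"]
    assert screen.loc[unloaded, "selected"].sum() <= 1
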