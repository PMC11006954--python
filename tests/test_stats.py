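"""Group tests, BH FDR, interaction models, Spearman matrices.

Where a spec'd quantity has a closed form, the expected value is computed
here by an independent route (hand formula, hand ranks, statsmodels'
multiple-testing routine) rather than by the code under test.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import glycoage as ga


def welch_oracle(a, b):
    """Hand-coded Welch t test (statistic, df, two-sided p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (b.mean() - a.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


class TestTwoGroupTest:
    def test_identical_groups(self):
        vals = np.r_[np.arange(10.0), np.arange(10.0)]
        labels = ["a"] * 10 + ["b"] * 10
        res = ga.two_group_test(vals, labels)
        assert res.estimate == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups(self, rng):
        vals = np.r_[rng.normal(0, 1e-6, 50), 1 + rng.normal(0, 1e-6, 50)]
        labels = ["a"] * 50 + ["b"] * 50
        res = ga.two_group_test(vals, labels)
        assert res.p_value < 1e-20
        assert res.estimate == pytest.approx(1.0, abs=1e-5)

    def test_matches_hand_welch_oracle(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        res = ga.two_group_test(np.r_[a, b], ["a"] * 50 + ["b"] * 50)
        t, df, p = welch_oracle(a, b)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.estimate == pytest.approx(b.mean() - a.mean(), abs=1e-12)

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            ga.two_group_test([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestBhFdr:
    def test_hand_computed_vector(self):
        # step-up by hand: all q = 0.04
        q = ga.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert ga.bh_fdr([0.37]) == pytest.approx([0.37])

    def test_all_ones(self):
        assert np.allclose(ga.bh_fdr([1.0] * 5), 1.0)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(size=200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ga.bh_fdr(p), q_sm, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ga.bh_fdr([0.5, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_properties(self, ps):
        q = ga.bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-15)          # q >= p
        assert np.all(q <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-15)           # monotone in p
        perm = np.random.default_rng(0).permutation(len(ps))
        assert np.allclose(ga.bh_fdr(np.asarray(ps)[perm]), q[perm])  # equivariant


class TestInteractionModel:
    @staticmethod
    def _toy(n=200, inter=0.0, noise=0.0, seed=5):
        rng = np.random.default_rng(seed)
        age = rng.uniform(40, 70, n)
        hiv = rng.integers(0, 2, n)
        y = 1 + 2 * age + 3 * hiv + inter * age * hiv + rng.normal(0, noise, n)
        return pd.DataFrame({"y": y, "age": age, "hiv": hiv})

    def test_null_interaction_noiseless(self):
        tab = ga.interaction_model(self._toy(inter=0.0), "y", "age", "hiv")
        term = tab.attrs["interaction_terms"][0]
        assert tab.loc[term, "coef"] == pytest.approx(0.0, abs=1e-10)

    def test_exact_interaction_noiseless(self):
        tab = ga.interaction_model(self._toy(inter=0.5), "y", "age", "hiv")
        term = tab.attrs["interaction_terms"][0]
        assert tab.loc[term, "coef"] == pytest.approx(0.5, abs=1e-10)

    def test_matches_lstsq_oracle(self):
        """Coefficients and SEs match a hand-built OLS on the same design."""
        df = self._toy(n=400, inter=0.25, noise=1.0, seed=9)
        tab = ga.interaction_model(df, "y", "age", "hiv")
        X = np.column_stack(
            [np.ones(len(df)), df.age, df.hiv, df.age * df.hiv]
        )
        beta, *_ = np.linalg.lstsq(X, df.y.to_numpy(), rcond=None)
        resid = df.y.to_numpy() - X @ beta
        sigma2 = resid @ resid / (len(df) - X.shape[1])
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        got = tab.loc[["Intercept", "age", "hiv", "age:hiv"]]
        assert np.allclose(got["coef"].to_numpy(), beta, atol=1e-8)
        assert np.allclose(got["se"].to_numpy(), se, atol=1e-8)

    def test_categorical_covariates_adjusted(self, small_bundle):
        traits = ga.derive_traits_frame(small_bundle.profiles)
        df = traits.join(small_bundle.cohort)
        df["sexnum"] = (df.sex == "M").astype(int)
        tab = ga.interaction_model(
            df, "agalactosylated", "hiv", "sexnum",
            covariates=("age", "ethnicity", "bmi"),
            categorical=("hiv", "ethnicity"),
        )
        assert "n_used" in tab.columns
        assert tab.attrs["interaction_terms"]

    def test_collinear_design_rejected(self):
        df = self._toy()
        df["age2"] = df["age"]
        with pytest.raises(ValueError, match="rank-deficient"):
            ga.interaction_model(df, "y", "age", "hiv", covariates=("age2",))


class TestSlopeDifference:
    @staticmethod
    def _trend(slope_a, slope_b, noise=0.0, n=100, seed=3):
        rng = np.random.default_rng(seed)
        age = np.r_[rng.uniform(40, 70, n), rng.uniform(40, 70, n)]
        status = np.array(["neg"] * n + ["pos"] * n)
        slope = np.where(status == "neg", slope_a, slope_b)
        y = slope * age + rng.normal(0, noise, 2 * n)
        return pd.DataFrame({"y": y, "age": age, "hiv": status})

    def test_equal_slopes_null(self):
        res = ga.slope_difference(self._trend(1.0, 1.0), "y")
        assert res["interaction_coef"] == pytest.approx(0.0, abs=1e-10)

    def test_slope_difference_exact(self):
        res = ga.slope_difference(self._trend(1.0, 2.0), "y")
        assert res["interaction_coef"] == pytest.approx(1.0, abs=1e-10)
        assert res["slope_difference"] == pytest.approx(1.0, abs=1e-10)

    def test_monotone_rho_extreme(self):
        res = ga.slope_difference(self._trend(1.0, -1.0), "y")
        assert res["groups"]["neg"]["rho"] == pytest.approx(1.0)
        assert res["groups"]["pos"]["rho"] == pytest.approx(-1.0)

    def test_constant_age_errors(self):
        df = pd.DataFrame(
            {"y": [1, 2, 3, 4], "age": [50, 50, 40, 60], "hiv": ["n", "n", "p", "p"]}
        )
        with pytest.raises(ValueError, match="constant age"):
            ga.slope_difference(df, "y")


class TestSpearmanMatrix:
    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=60)
        df_x = pd.DataFrame({"x": x})
        for transform in (np.exp, np.cbrt, lambda v: v**3):
            out = ga.spearman_matrix(df_x, pd.DataFrame({"y": transform(x)}))
            assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_antitone(self, rng):
        x = rng.normal(size=30)
        out = ga.spearman_matrix(
            pd.DataFrame({"x": x}), pd.DataFrame({"y": -np.exp(x)})
        )
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_hand_rank_ties(self):
        # ranks of x: (1.5, 1.5, 3.5, 3.5); ranks of y: (1.5, 3.5, 1.5, 3.5)
        # centered products cancel -> rho = 0
        out = ga.spearman_matrix(
            pd.DataFrame({"x": [1, 1, 2, 2]}), pd.DataFrame({"y": [1, 2, 1, 2]})
        )
        assert out.loc[0, "rho"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_nan_sentinel(self, rng):
        out = ga.spearman_matrix(
            pd.DataFrame({"x": np.ones(10)}),
            pd.DataFrame({"y": rng.normal(size=10)}),
        )
        assert np.isnan(out.loc[0, "rho"])

    def test_q_family_is_whole_matrix(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        Y = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("wxyz"))
        out = ga.spearman_matrix(X, Y)
        assert len(out) == 12
        assert np.allclose(out["q"], ga.bh_fdr(out["p"].to_numpy()))

    def test_partial_on_confounder(self, rng):
        """Partialling out a shared driver removes a spurious correlation."""
        z = rng.normal(size=300)
        x = z + rng.normal(0, 0.3, 300)
        y = z + rng.normal(0, 0.3, 300)
        plain = ga.spearman_matrix(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))
        partial = ga.spearman_matrix(
            pd.DataFrame({"x": x}), pd.DataFrame({"y": y}),
            partial_on=pd.DataFrame({"z": z}),
        )
        assert plain.loc[0, "rho"] > 0.8
        assert abs(partial.loc[0, "rho"]) < 0.2


class TestStratifiedRun:
    def test_three_strata_three_results(self, rng):
        df = pd.DataFrame(
            {
                "v": rng.normal(size=90),
                "g": ["a", "b"] * 45,
                "stratum": ["pre"] * 30 + ["peri"] * 30 + ["post"] * 30,
            }
        )
        res = ga.stratified_run(
            lambda d: ga.two_group_test(d["v"], d["g"]), df, "stratum"
        )
        assert set(res) == {"pre", "peri", "post", "skipped"}

    def test_small_stratum_skipped_with_warning(self, rng):
        df = pd.DataFrame(
            {"v": rng.normal(size=33), "g": ["a", "b"] * 16 + ["a"],
             "stratum": ["big"] * 30 + ["tiny"] * 3}
        )
        with pytest.warns(UserWarning, match="tiny"):
            res = ga.stratified_run(
                lambda d: ga.two_group_test(d["v"], d["g"]), df, "stratum"
            )
        assert ("tiny", 3) in res["skipped"]
        assert "big" in res

    def test_identical_strata_identical_results(self, rng):
        v = rng.normal(size=40)
        g = ["a", "b"] * 20
        df = pd.DataFrame(
            {"v": np.r_[v, v], "g": g + g, "stratum": ["s1"] * 40 + ["s2"] * 40}
        )
        res = ga.stratified_run(
            lambda d: ga.two_group_test(d["v"], d["g"]).p_value, df, "stratum"
        )
        assert res["s1"] == res["s2"]


def test_global_null_calibration(rng):
    """Under 1,000 independent null two-group tests the p < 0.05 fraction
    stays inside the binomial 99% envelope around 0.05."""
    hits = 0
    n_tests = 1000
    for _ in range(n_tests):
        vals = rng.normal(size=40)
        if ga.two_group_test(vals, ["a"] * 20 + ["b"] * 20).p_value < 0.05:
            hits += 1
    lo, hi = sps.binom.ppf([0.005, 0.995], n_tests, 0.05)
    assert lo <= hits <= hi


def test_significance_stars():
    assert ga.significance_stars(0.2) == ""
    assert ga.significance_stars(0.04) == "*"
    assert ga.significance_stars(0.009) == "**"
    assert ga.significance_stars(0.0009) == "***"
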