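"""Oracle checks for the shared statistical machinery.

Each route is verified against an independent computation: normal
equations for OLS, brute-force nested re-fits for sequential ANOVA,
direct numerical integration of the studentized-range distribution for
Tukey p-values, and closed-form formulas (plus scipy/statsmodels
cross-checks) for the t-tests.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phagestress import stats_engine as se


def random_design(rng, n=20, p=4):
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)])
    X["x0"] = 1.0
    y = rng.normal(size=n)
    return X, y


class TestFitOLS:
    def test_intercept_only_is_mean(self):
        y = np.array([1.0, 4.0, 7.0])
        fit = se.fit_ols(pd.DataFrame({"c": [1.0, 1.0, 1.0]}), y)
        assert fit.coefficients["c"] == pytest.approx(y.mean())

    def test_saturated_line_has_zero_residual(self):
        X = pd.DataFrame({"i": [1.0, 1.0], "t": [0.0, 1.0]})
        fit = se.fit_ols(X, np.array([2.0, 5.0]))
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-20)
        assert fit.residual_df == 0

    def test_matches_normal_equations_on_random_designs(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            X, y = random_design(rng)
            fit = se.fit_ols(X, y)
            Xm = X.to_numpy()
            beta = np.linalg.solve(Xm.T @ Xm, Xm.T @ y)
            np.testing.assert_allclose(fit.coefficients.to_numpy(), beta,
                                       atol=1e-10)
            # residual orthogonality to the design
            resid = y - Xm @ beta
            np.testing.assert_allclose(Xm.T @ resid, 0, atol=1e-10)

    def test_rank_deficiency_names_aliased_column(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0],
                          "c": [0.0, 1.0, 0.0]})
        with pytest.raises(se.RankDeficientError, match="b"):
            se.fit_ols(X, np.zeros(3))

    def test_nan_response_rejected(self):
        with pytest.raises(ValueError):
            se.fit_ols(pd.DataFrame({"c": [1.0, 1.0]}), np.array([1.0, np.nan]))


def nested_rss_oracle(design, y, terms):
    """Brute-force: RSS of each nested model by direct lstsq."""
    cols = []
    rss = []
    X0 = np.ones((len(y), 1))
    for _, tcols in terms:
        cols.extend(tcols)
        X = np.hstack([X0, design[cols].to_numpy()])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss.append(float(r @ r))
    r0 = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
    return [float(r0 @ r0)] + rss


class TestSequentialAnova:
    @staticmethod
    def _random_problem(rng):
        n = int(rng.integers(12, 25))
        g = rng.choice(["a", "b", "c"], size=n)
        t = rng.normal(size=n)
        y = rng.normal(size=n) + (g == "b") * 1.0 + t * 0.5
        design = pd.DataFrame({
            "gb": (g == "b").astype(float), "gc": (g == "c").astype(float),
            "t": t,
            "gbt": (g == "b") * t, "gct": (g == "c") * t})
        terms = [("group", ["gb", "gc"]), ("t", ["t"]),
                 ("group:t", ["gbt", "gct"])]
        return design, y, terms

    def test_matches_nested_refits(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            design, y, terms = self._random_problem(rng)
            table = se.sequential_anova(design, y, terms)
            rss_seq = nested_rss_oracle(design, y, terms)
            expected_ss = [rss_seq[k] - rss_seq[k + 1]
                           for k in range(len(terms))]
            got = table[table["term"] != "Residual"]["sum_sq"].to_numpy()
            np.testing.assert_allclose(got, expected_ss, atol=1e-10)
            assert table[table["term"] == "Residual"]["sum_sq"].iloc[0] == \
                pytest.approx(rss_seq[-1], abs=1e-10)

    def test_matches_statsmodels_type1(self):
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm
        rng = np.random.default_rng(8)
        design, y, terms = self._random_problem(rng)
        df = pd.DataFrame({"y": y,
                           "g": np.where(design["gb"] == 1, "b",
                                         np.where(design["gc"] == 1, "c", "a")),
                           "t": design["t"]})
        sm_tab = anova_lm(ols("y ~ C(g) + t + C(g):t", data=df).fit(), typ=1)
        table = se.sequential_anova(design, y, terms)
        np.testing.assert_allclose(table["sum_sq"].to_numpy(),
                                   sm_tab["sum_sq"].to_numpy(), atol=1e-8)
        np.testing.assert_allclose(table["F"].to_numpy()[:-1],
                                   sm_tab["F"].to_numpy()[:-1], atol=1e-8)

    def test_decomposition_sums_to_total(self):
        rng = np.random.default_rng(9)
        design, y, terms = self._random_problem(rng)
        table = se.sequential_anova(design, y, terms)
        total = float(((y - y.mean()) ** 2).sum())
        assert table["sum_sq"].sum() == pytest.approx(total, rel=1e-10)

    def test_saturated_model_rejected(self):
        design = pd.DataFrame({"x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="[Ss]aturated"):
            se.sequential_anova(design, np.array([1.0, 2.0]), [("x", ["x"])])


def studentized_range_cdf_oracle(q, k, df):
    """P(Q <= q) by direct double numerical integration.

    Inner integral: P(range of k std normals <= r) =
    k * Int phi(z) [Phi(z) - Phi(z - r)]^(k-1) dz; outer integral over the
    scale s ~ sqrt(chi2_df / df).
    """
    from scipy.integrate import quad

    def range_cdf(r):
        if r <= 0:
            return 0.0
        f = lambda z: stats.norm.pdf(z) * (
            stats.norm.cdf(z) - stats.norm.cdf(z - r)) ** (k - 1)
        val, _ = quad(f, -8, 8, limit=200)
        return k * val

    def outer(s):
        return stats.chi.pdf(s * np.sqrt(df), df) * np.sqrt(df) * range_cdf(q * s)

    val, _ = quad(outer, 1e-8, 8, limit=200)
    return val


class TestTukey:
    def test_identical_means_give_p_one(self):
        comps = se.tukey_hsd({"a": 1.0, "b": 1.0, "c": 1.0},
                             {"a": 3, "b": 3, "c": 3}, mse=2.0, df_resid=6)
        assert all(c.q_stat == 0 for c in comps)
        assert all(c.p_adj == pytest.approx(1.0) for c in comps)

    def test_two_groups_equal_pooled_t_test(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            a, b = rng.normal(size=6), rng.normal(1.0, 1.0, size=6)
            t, p_t = stats.ttest_ind(a, b, equal_var=True)
            n = 6
            sp2 = ((a.var(ddof=1) + b.var(ddof=1)) / 2)
            comps = se.tukey_hsd({"a": a.mean(), "b": b.mean()},
                                 {"a": n, "b": n}, mse=sp2, df_resid=2 * n - 2)
            assert comps[0].q_stat == pytest.approx(np.sqrt(2) * abs(t))
            assert comps[0].p_adj == pytest.approx(p_t, abs=1e-8)

    @pytest.mark.parametrize("k,df,q", [(3, 10, 2.5), (4, 8, 3.2), (5, 20, 1.7)])
    def test_p_matches_numerical_integration(self, k, df, q):
        p = float(stats.studentized_range.sf(q, k, df))
        oracle = 1.0 - studentized_range_cdf_oracle(q, k, df)
        assert p == pytest.approx(oracle, abs=1e-6)

    def test_matches_statsmodels_pairwise(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        rng = np.random.default_rng(14)
        y = np.concatenate([rng.normal(m, 1.0, size=5) for m in (0, 0.5, 2.0)])
        g = np.repeat(["a", "b", "c"], 5)
        sm_res = pairwise_tukeyhsd(y, g)
        means = {lev: y[g == lev].mean() for lev in "abc"}
        ns = {lev: 5 for lev in "abc"}
        mse = np.sum([(y[g == lev] - means[lev]) ** 2 for lev in "abc"]) / 12
        comps = se.tukey_hsd(means, ns, mse, 12)
        np.testing.assert_allclose([c.p_adj for c in comps],
                                   sm_res.pvalues, atol=1e-6)

    def test_zero_mse_rejected(self):
        with pytest.raises(ValueError):
            se.tukey_hsd({"a": 0, "b": 1}, {"a": 2, "b": 2}, 0.0, 2)


class TestCompactLetters:
    def test_sharing_relation_matches_nonsignificance(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            levels = ["t0", "t1", "t2", "t3"]
            comps = []
            for i in range(4):
                for j in range(i + 1, 4):
                    p = float(rng.uniform(0, 1))
                    comps.append(se.TukeyComparison(levels[i], levels[j],
                                                    0.0, 0.0, p, p < 0.05))
            letters = se.compact_letters(comps, levels)
            for c in comps:
                share = bool(set(letters[c.level_a]) & set(letters[c.level_b]))
                if c.p_adj >= 0.05:
                    assert share, (c, letters)
                else:
                    assert not share, (c, letters)


class TestWelch:
    def test_identical_samples(self):
        res = se.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0)
        assert res["p_two_sided"] == pytest.approx(1.0)

    def test_closed_form_satterthwaite(self):
        rng = np.random.default_rng(16)
        a = rng.normal(0, 1, size=6)
        b = rng.normal(1, 2, size=6)
        res = se.welch_t(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        df = (va / 6 + vb / 6) ** 2 / ((va / 6) ** 2 / 5 + (vb / 6) ** 2 / 5)
        assert res["df"] == pytest.approx(df, abs=1e-10)
        t_sp, p_sp = stats.ttest_ind(a, b, equal_var=False)
        assert res["t"] == pytest.approx(t_sp)
        assert res["p_two_sided"] == pytest.approx(p_sp)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            se.welch_t([1.0], [1.0, 2.0])


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [
        (0.3, 4, 1.0),
        (0.005, 4, 0.020),
        (0.42, 1, 0.42),
    ])
    def test_values(self, p, m, expected):
        assert se.bonferroni(p, m) == pytest.approx(expected)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            p = float(rng.uniform(1e-6, 1.0))
            m = int(rng.integers(1, 10))
            adj = se.bonferroni(p, m)
            assert p <= adj <= 1.0
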