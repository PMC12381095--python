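"""Repeated-measures battery vs independent oracles (pingouin/scipy/statsmodels)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from retromem import behavior as bh


def _cm(Y, labels=None):
    Y = np.asarray(Y, dtype=float)
    labels = labels or [f"c{j}" for j in range(Y.shape[1])]
    return bh.ConditionMatrix(Y, labels)


def _anova_ss_oracle(Y):
    """Brute-force sums-of-squares decomposition with explicit loops."""
    n, k = Y.shape
    grand = Y.mean()
    ss_cond = sum(n * (Y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (Y[i].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((Y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    F = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    eta = ss_cond / (ss_cond + ss_err)
    return F, eta


class TestRmAnova:
    def test_identical_conditions_give_zero_F(self):
        col = np.arange(6, dtype=float)
        res = bh.rm_anova_gg(_cm(np.stack([col] * 3, axis=1)))
        assert res.F == 0.0
        assert res.partial_eta_sq == 0.0

    def test_two_conditions_F_equals_squared_paired_t(self, rng):
        Y = rng.normal(size=(10, 2))
        res = bh.rm_anova_gg(_cm(Y))
        t = stats.ttest_rel(Y[:, 0], Y[:, 1])
        assert np.isclose(res.F, t.statistic**2)
        assert np.isclose(res.p_uncorrected, t.pvalue)

    def test_hand_table_matches_ss_oracle(self):
        Y = np.array(
            [
                [4.0, 6.0, 7.0],
                [3.0, 5.0, 8.0],
                [5.0, 5.0, 6.0],
                [2.0, 4.0, 9.0],
                [4.0, 7.0, 7.0],
                [3.0, 6.0, 8.0],
            ]
        )
        res = bh.rm_anova_gg(_cm(Y))
        F, eta = _anova_ss_oracle(Y)
        assert np.isclose(res.F, F)
        assert np.isclose(res.partial_eta_sq, eta)
        assert 1.0 / 2.0 <= res.epsilon_gg <= 1.0

    def test_matches_pingouin_including_gg_and_mauchly(self, rng):
        import pingouin as pg

        Y = rng.normal(size=(12, 4)) + np.array([0.0, 0.3, 0.6, 0.2])
        Y[:, 0] *= 2.0  # break sphericity
        res = bh.rm_anova_gg(_cm(Y))
        df = pd.DataFrame(
            {
                "y": Y.ravel(),
                "cond": list(range(4)) * 12,
                "subj": np.repeat(range(12), 4),
            }
        )
        aov = pg.rm_anova(df, dv="y", within="cond", subject="subj", correction=True)
        assert np.isclose(res.F, aov["F"][0])
        assert np.isclose(res.p_uncorrected, aov["p_unc"][0])
        assert np.isclose(res.p_corrected, aov["p_GG_corr"][0])
        assert np.isclose(res.epsilon_gg, aov["eps"][0])
        sph = pg.sphericity(df, dv="y", within="cond", subject="subj")
        assert np.isclose(res.mauchly_chi2, sph.chi2)
        # pingouin adds a second-order term to the chi-square approximation;
        # ours is the standard first-order version
        assert np.isclose(res.mauchly_p, sph.pval, atol=5e-3)

    def test_incomplete_matrix_rejected(self):
        Y = np.ones((4, 3))
        Y[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            _cm(Y)


class TestFriedman:
    def test_identical_columns_give_zero(self):
        Y = np.tile(np.arange(5, dtype=float)[:, None], (1, 3))
        chi2, p, w = bh.friedman_kendall_w(_cm(Y))
        assert chi2 == 0.0
        assert w == 0.0

    def test_perfect_concordance_gives_w_one(self):
        Y = np.tile([1.0, 2.0, 3.0, 4.0], (6, 1))
        chi2, p, w = bh.friedman_kendall_w(_cm(Y))
        assert np.isclose(w, 1.0)

    def test_statistic_matches_scipy_without_ties(self, rng):
        Y = rng.normal(size=(9, 4))
        chi2, p, _ = bh.friedman_kendall_w(_cm(Y))
        ref = stats.friedmanchisquare(*Y.T)
        assert np.isclose(chi2, ref.statistic)
        assert np.isclose(p, ref.pvalue)

    def test_small_table_chi2_p_close_to_exact_enumeration(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(0.0, 0.5, size=(4, 3)) + np.array([0.0, 1.5, 3.0])
        chi2_obs, p_approx, _ = bh.friedman_kendall_w(_cm(Y))
        n, k = Y.shape
        # exact null: enumerate all (k!)^n within-participant rank profiles
        perms = list(itertools.permutations(range(1, k + 1)))
        count = total = 0
        for profile in itertools.product(perms, repeat=n):
            R = np.array(profile, dtype=float)
            Rj = R.sum(axis=0)
            chi2 = 12.0 / (n * k * (k + 1)) * np.sum(Rj**2) - 3.0 * n * (k + 1)
            count += chi2 >= chi2_obs - 1e-9
            total += 1
        p_exact = count / total
        assert abs(p_exact - p_approx) < 0.05


class TestPairedT:
    def test_identical_vectors(self):
        x = np.arange(5, dtype=float)
        res = bh.paired_t_dav(x, x)
        assert res.t == 0.0 and res.p == 1.0 and res.d_av == 0.0
        assert res.ci95 == (0.0, 0.0)

    def test_constant_shift_dav_is_c_over_s(self, rng):
        x = rng.normal(0, 2.0, size=20)
        c = 1.5
        res = bh.paired_t_dav(x + c, x)
        assert np.isclose(res.d_av, c / x.std(ddof=1))

    def test_five_pair_closed_form(self):
        x = np.array([10.0, 12.0, 9.0, 14.0, 11.0])
        y = np.array([8.0, 11.0, 10.0, 12.0, 9.0])
        res = bh.paired_t_dav(x, y)
        d = x - y
        se = d.std(ddof=1) / np.sqrt(5)
        assert np.isclose(res.t, d.mean() / se)
        assert np.isclose(res.p, 2 * stats.t.sf(abs(res.t), 4))
        tcrit = stats.t.ppf(0.975, 4)
        assert np.isclose(res.ci95[0], d.mean() - tcrit * se)
        assert np.isclose(res.ci95[1], d.mean() + tcrit * se)
        assert np.isclose(res.d_av, d.mean() / ((x.std(ddof=1) + y.std(ddof=1)) / 2))


class TestWilcoxon:
    def test_symmetric_pairs_give_near_zero_z(self):
        x = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        res = bh.wilcoxon_signed_rank(x, np.zeros(6))
        assert abs(res.z) < 0.5
        assert res.p > 0.5

    def test_exact_p_matches_scipy_enumeration(self, rng):
        x = rng.normal(0.5, 1.0, size=6)
        y = rng.normal(0.0, 1.0, size=6)
        res = bh.wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, mode="exact")
        assert res.exact
        assert np.isclose(res.W, ref.statistic)
        assert np.isclose(res.p, ref.pvalue)

    def test_r_is_z_over_sqrt_n(self, rng):
        x = rng.normal(0.8, 1.0, size=25)
        y = rng.normal(0.0, 1.0, size=25)
        res = bh.wilcoxon_signed_rank(x, y)
        assert res.r == res.z / np.sqrt(25)

    def test_normal_approx_matches_scipy(self, rng):
        x = rng.normal(0.4, 1.0, size=30)
        y = rng.normal(0.0, 1.0, size=30)
        res = bh.wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, mode="approx", correction=True)
        assert not res.exact
        assert np.isclose(res.p, ref.pvalue)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            bh.wilcoxon_signed_rank(np.ones(5), np.ones(5))


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh.bh_fdr([0.03])[0] == 0.03

    def test_direct_formula_example(self):
        assert np.allclose(bh.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=12)
        assert np.allclose(bh.bh_fdr(p), multipletests(p, method="fdr_bh")[1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20)
    )
    def test_properties(self, p):
        p = np.array(p)
        adj = bh.bh_fdr(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)  # order-preserving


def _jzs_oracle(t, n, r=0.707):
    """Independent quadrature: Rouder's g-prior form of the JZS integral."""
    df = n - 1

    def integrand(g):
        return (
            (1 + n * g * r**2) ** -0.5
            * (1 + t**2 / ((1 + n * g * r**2) * df)) ** (-(df + 1) / 2)
            * (2 * np.pi) ** -0.5
            * g ** (-1.5)
            * np.exp(-1.0 / (2 * g))
        )

    num, _ = integrate.quad(integrand, 0, np.inf, limit=300)
    den = (1 + t**2 / df) ** (-(df + 1) / 2)
    return num / den


class TestJzsBayesFactor:
    def test_t_zero_favors_null(self):
        for n in (5, 20, 43):
            assert bh.jzs_bf_paired(0.0, n) < 1.0

    def test_monotone_in_abs_t(self):
        bfs = [bh.jzs_bf_paired(t, 20) for t in (0.0, 1.0, 2.0, 3.0, 4.0)]
        assert np.all(np.diff(bfs) > 0)

    @pytest.mark.parametrize(
        "t,n", [(0.5, 10), (2.0, 15), (2.5, 20), (4.0, 30), (6.51, 43)]
    )
    def test_matches_independent_quadrature_to_3_significant_figures(self, t, n):
        ours = bh.jzs_bf_paired(t, n)
        oracle = _jzs_oracle(t, n)
        assert np.isclose(ours, oracle, rtol=5e-4)

    def test_matches_pingouin(self):
        import pingouin as pg

        for t, n in [(2.5, 20), (6.51, 43)]:
            assert np.isclose(
                bh.jzs_bf_paired(t, n),
                float(pg.bayesfactor_ttest(t, n, paired=True)),
                rtol=1e-4,
            )

    def test_nonfinite_t_rejected(self):
        with pytest.raises(ValueError):
            bh.jzs_bf_paired(np.inf, 10)


class TestBattery:
    def test_pairwise_battery_shape_and_adjustment(self, rng):
        Y = rng.normal(size=(15, 3)) + np.array([0.0, 0.5, 1.0])
        pw = bh.pairwise_battery(_cm(Y, ["PT", "NP", "ABS"]))
        assert len(pw) == 3
        assert (pw["p_adj"] >= pw["p_raw"] - 1e-12).all()
        assert (pw["wilcoxon_p_adj"] >= pw["wilcoxon_p_raw"] - 1e-12).all()
        assert set(pw["contrast"]) == {"PT vs NP", "PT vs ABS", "NP vs ABS"}

    def test_condition_matrix_from_table(self):
        tab = pd.DataFrame(
            {
                "participant": np.repeat([0, 1, 2], 4),
                "condition": ["PT", "PT", "NP", "NP"] * 3,
                "accuracy": [1, 0, 1, 1, 1, 1, 0, 1, 0, 1, 1, 0],
            }
        )
        cm = bh.condition_matrix_from_table(tab, value="accuracy")
        assert cm.values.shape == (3, 2)
        assert np.isclose(cm.column("PT")[0], 0.5)
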