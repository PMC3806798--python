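"""Group-means fits, empirical-Bayes moderation, moderated t/F and BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import fshtri as ft


def _two_group(values_a, values_b, clones=None):
    a, b = np.atleast_2d(values_a), np.atleast_2d(values_b)
    data = np.hstack([a, b])
    cols = [f"A_{i}" for i in range(a.shape[1])] + [f"B_{i}" for i in range(b.shape[1])]
    values = pd.DataFrame(data, index=clones or [f"c{i}" for i in range(data.shape[0])], columns=cols)
    groups = pd.Series(["A"] * a.shape[1] + ["B"] * b.shape[1], index=cols)
    return values, groups


def _fake_fit(s2, df, n_per_group=(6, 6)):
    s2 = pd.Series(np.asarray(s2, dtype=float))
    means = pd.DataFrame(np.zeros((len(s2), len(n_per_group))), index=s2.index,
                         columns=[f"g{i}" for i in range(len(n_per_group))])
    return ft.LinearModelFit(
        group_means=means, s2=s2, df_residual=float(df),
        n_per_group=pd.Series(n_per_group, index=means.columns),
        groups=pd.Series(dtype=object),
    )


class TestFitGroupMeans:
    def test_constant_within_groups_zero_variance(self):
        values, groups = _two_group([[1.0, 1.0]], [[5.0, 5.0]])
        fit = ft.fit_group_means(values, groups)
        assert fit.s2.iloc[0] == 0.0

    def test_hand_residuals_and_df(self):
        values, groups = _two_group([[1.0, 3.0]], [[4.0, 4.0]])
        fit = ft.fit_group_means(values, groups)
        assert fit.group_means.loc["c0", "A"] == pytest.approx(2.0)
        # residual SS = (1-2)^2 + (3-2)^2 = 2, df = 4 - 2 = 2
        assert fit.df_residual == 2.0
        assert fit.s2.iloc[0] == pytest.approx(1.0)

    def test_four_by_six_df(self):
        rng = np.random.default_rng(0)
        cols = [f"{g}_{r}" for g in "WXYZ" for r in range(6)]
        values = pd.DataFrame(rng.normal(size=(3, 24)), columns=cols)
        groups = pd.Series([c[0] for c in cols], index=cols)
        assert ft.fit_group_means(values, groups).df_residual == 20.0

    def test_single_array_group_raises(self):
        values, groups = _two_group([[1.0, 2.0]], [[3.0]])
        with pytest.raises(ValueError):
            ft.fit_group_means(values, groups)


class TestEbayes:
    def test_equal_variances_give_infinite_prior(self):
        fit = _fake_fit(np.full(50, 2.5), df=10)
        mod = ft.ebayes_moderate(fit)
        assert np.isinf(mod.d0)
        assert mod.s02 == pytest.approx(2.5, rel=1e-6)
        assert np.allclose(mod.s2_post, 2.5)

    def test_forced_zero_prior_is_no_moderation(self):
        rng = np.random.default_rng(1)
        s2 = rng.chisquare(5, 40) / 5
        fit = _fake_fit(s2, df=5)
        mod = ft.ebayes_moderate(fit, d0=0)
        np.testing.assert_allclose(mod.s2_post.to_numpy(), s2)

    def test_posterior_between_prior_and_sample(self):
        rng = np.random.default_rng(2)
        s2 = rng.chisquare(8, 100) / 8
        fit = _fake_fit(s2, df=8)
        mod = ft.ebayes_moderate(fit)
        lo = np.minimum(s2, mod.s02)
        hi = np.maximum(s2, mod.s02)
        assert ((mod.s2_post >= lo - 1e-12) & (mod.s2_post <= hi + 1e-12)).all()

    def test_hyperparameter_recovery(self):
        """Moment matching recovers (d0, s0^2) from scaled inverse-chi2 draws."""
        d0_true, s02_true, dfres = 4.0, 1.0, 20.0
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            sigma2 = d0_true * s02_true / rng.chisquare(d0_true, 200)
            s2 = sigma2 * rng.chisquare(dfres, 200) / dfres
            mod = ft.ebayes_moderate(_fake_fit(s2, df=dfres))
            estimates.append((mod.d0, mod.s02))
        est = np.array(estimates)
        assert abs(est[:, 0].mean() - d0_true) < 1.5
        assert abs(est[:, 1].mean() - s02_true) < 0.3


class TestModeratedContrast:
    def test_zero_difference(self):
        values, groups = _two_group([[1.0, 1.0]], [[1.0, 1.0]])
        values.loc["c1"] = [0.0, 2.0, 1.0, 3.0]  # gives nonzero pooled variance
        fit = ft.fit_group_means(values, groups)
        mod = ft.ebayes_moderate(fit, d0=0)
        res = ft.moderated_contrast(fit, mod, ("A", "B"))
        assert res.loc["c0", "t"] == 0.0
        assert res.loc["c0", "p"] == 1.0

    def test_group_against_itself_is_null(self):
        values, groups = _two_group([[1.0, 2.0]], [[3.0, 4.0]])
        fit = ft.fit_group_means(values, groups)
        mod = ft.ebayes_moderate(fit, d0=0)
        res = ft.moderated_contrast(fit, mod, ("A", "A"))
        assert res.loc["c0", "p"] == 1.0

    def test_d0_zero_equals_classical_pooled_t(self):
        """No-moderation limit reproduces the classical two-sample t exactly."""
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(30, 6)), rng.normal(0.5, 1.0, size=(30, 6))
        values, groups = _two_group(a, b)
        fit = ft.fit_group_means(values, groups)
        mod = ft.ebayes_moderate(fit, d0=0)
        res = ft.moderated_contrast(fit, mod, ("A", "B"))
        t_ref, p_ref = stats.ttest_ind(b, a, axis=1)
        np.testing.assert_allclose(res["t"].to_numpy(), t_ref, atol=1e-10)
        np.testing.assert_allclose(res["p"].to_numpy(), p_ref, atol=1e-10)

    def test_p_monotone_in_effect(self):
        """Planted effect with vanishing noise drives p towards zero."""
        values, groups = _two_group([[0.0] * 6, [0.0] * 6], [[1.0] * 6, [0.01] * 6])
        noise = np.random.default_rng(3).normal(0, 1e-6, values.shape)
        values = values + noise
        fit = ft.fit_group_means(values, groups)
        mod = ft.ebayes_moderate(fit, d0=0)
        res = ft.moderated_contrast(fit, mod, ("A", "B"))
        assert res.loc["c0", "p"] < 1e-12
        assert res.loc["c0", "p"] < res.loc["c1", "p"]


class TestModeratedF:
    def test_equal_means_zero(self):
        values, groups = _two_group([[1.0, 1.0]], [[1.0, 1.0]])
        values.loc["c1"] = [0.0, 2.0, 1.0, 3.0]
        fit = ft.fit_group_means(values, groups)
        mod = ft.ebayes_moderate(fit, d0=0)
        assert ft.moderated_F(fit, mod).loc["c0", "F"] == 0.0

    def test_two_group_F_is_t_squared(self):
        rng = np.random.default_rng(11)
        values, groups = _two_group(rng.normal(size=(20, 5)), rng.normal(size=(20, 5)))
        fit = ft.fit_group_means(values, groups)
        mod = ft.ebayes_moderate(fit)
        F = ft.moderated_F(fit, mod)["F"].to_numpy()
        t = ft.moderated_contrast(fit, mod, ("A", "B"))["t"].to_numpy()
        np.testing.assert_allclose(F, t**2, rtol=1e-10)

    def test_hand_worked_anova(self):
        # clone c0: groups {1,3} and {5,7}: MS_between = 16, s2 = 2, F = 8
        values, groups = _two_group([[1.0, 3.0], [2.0, 2.0]], [[5.0, 7.0], [2.0, 4.0]])
        fit = ft.fit_group_means(values, groups)
        mod = ft.ebayes_moderate(fit, d0=0)
        res = ft.moderated_F(fit, mod)
        assert res.loc["c0", "F"] == pytest.approx(8.0)
        assert res.loc["c0", "p"] == pytest.approx(stats.f.sf(8.0, 1, 2))


class TestBHFdr:
    def test_worked_example(self):
        q = ft.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("p,expected", [([0.3], [0.3]), ([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])])
    def test_degenerate_cases(self, p, expected):
        np.testing.assert_allclose(ft.bh_fdr(np.array(p)), expected)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_q_dominates_p_and_is_monotone(self, pvals):
        p = np.array(pvals)
        q = ft.bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            ft.bh_fdr(np.array([0.5, 1.5]))


class TestFdrControl:
    def test_global_null_false_discovery_proportion(self):
        """Mean FDP at q<=0.01 over null simulations stays within the BH bound."""
        fdps = []
        for seed in range(25):
            design = ft.SyntheticDesign(
                n_clones=500, class_proportions={"null": 1.0}, seed=900 + seed
            )
            raw, _ = ft.generate_array_experiment(design)
            expr = ft.normalize(raw)
            fit = ft.fit_group_means(expr.values, expr.groups)
            mod = ft.ebayes_moderate(fit)
            q = ft.bh_fdr(ft.moderated_F(fit, mod)["p"])
            fdps.append(1.0 if (q <= 0.01).sum() > 0 else 0.0)
        fdps = np.array(fdps)
        mcse = fdps.std(ddof=1) / np.sqrt(len(fdps)) if len(fdps) > 1 else 0.0
        assert fdps.mean() <= 0.01 + 3 * mcse + 1e-12
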