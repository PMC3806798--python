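"""Steroid summaries, exact nonparametric tests, qPCR quantification, CLD."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fshtri as ft


class TestPercentInhibition:
    @pytest.mark.parametrize(
        "ref,trt,expected",
        [(134.00, 9.4, 93), (10.0, 10.0, 0), (10.0, 0.0, 100)],
    )
    def test_values(self, ref, trt, expected):
        assert round(ft.percent_inhibition(ref, trt)) == expected

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        base = ft.percent_inhibition(134.0, 9.4)
        assert ft.percent_inhibition(134.0 * c, 9.4 * c) == pytest.approx(base, rel=1e-9)

    def test_zero_reference_flagged(self):
        assert math.isnan(ft.percent_inhibition(0.0, 1.0))


class TestSummarizeSteroid:
    def test_noise_free_series_summary(self):
        params = ft.SteroidSeriesParams(replicate_cv=0.0, duplicate_cv=0.0, seed=0)
        series = ft.generate_steroid_series(params)
        summary = ft.summarize_steroid(series, "Fsh", "FshTri", period="48-96h")
        # period-2 means: Fsh = 26.8*5 = 134, FshTri = 134*(1-0.93) = 9.38
        assert summary.group_stats.loc["Fsh", "mean"] == pytest.approx(134.0)
        assert summary.group_stats.loc["FshTri", "mean"] == pytest.approx(9.38)
        assert round(summary.percent_inhibition) == 93

    def test_duplicates_averaged_before_replicate_stats(self):
        rows = []
        for rep, (d1, d2) in enumerate([(1.0, 3.0), (2.0, 2.0)], start=1):
            for d, v in enumerate((d1, d2), start=1):
                rows.append(
                    {"treatment": "Fsh", "period": "p", "replicate": rep, "duplicate": d,
                     "concentration": v, "censored": False}
                )
            rows.append(
                {"treatment": "Ctrl", "period": "p", "replicate": rep, "duplicate": 1,
                 "concentration": 4.0, "censored": False}
            )
        summary = ft.summarize_steroid(pd.DataFrame(rows), "Ctrl", "Fsh", period="p")
        assert summary.group_stats.loc["Fsh", "mean"] == pytest.approx(2.0)
        assert summary.group_stats.loc["Fsh", "sd"] == pytest.approx(0.0)


class TestMannWhitneyExact:
    def test_complete_separation_six_vs_six(self):
        res = ft.mann_whitney_exact([1, 2, 3, 4, 5, 6], [7, 8, 9, 10, 11, 12])
        assert res.exact
        assert res.p == pytest.approx(2 / 924)

    def test_identical_groups_p_one(self):
        res = ft.mann_whitney_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == pytest.approx(1.0)

    def test_two_vs_two(self):
        res = ft.mann_whitney_exact([1, 2], [3, 4])
        assert res.p == pytest.approx(2 / 6)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            ft.mann_whitney_exact([], [1.0])

    def test_matches_brute_force_for_all_small_sizes(self):
        """Oracle equivalence: direct enumeration over value permutations."""
        rng = np.random.default_rng(12)

        def brute_force(a, b):
            pooled = np.concatenate([a, b])
            na = len(a)
            from scipy.stats import rankdata

            ranks = rankdata(pooled)
            mu = na * len(b) / 2.0
            u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
            count = total = 0
            for idx in itertools.combinations(range(len(pooled)), na):
                u = ranks[list(idx)].sum() - na * (na + 1) / 2.0
                total += 1
                if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
                    count += 1
            return count / total

        for na in range(1, 6):
            for nb in range(1, 6):
                for tied in (False, True):
                    a = rng.integers(0, 4, na).astype(float) if tied else rng.normal(size=na)
                    b = rng.integers(0, 4, nb).astype(float) if tied else rng.normal(size=nb)
                    res = ft.mann_whitney_exact(a, b)
                    assert res.p == pytest.approx(brute_force(a, b), abs=1e-12), (a, b)


class TestKruskalWallis:
    def test_all_identical_returns_null(self):
        assert ft.kruskal_wallis([[2.0, 2.0], [2.0, 2.0]]) == (0.0, 1.0)

    def test_hand_computable_rank_toy(self):
        # groups occupy ranks 1-2 / 3-4 / 5-6: H = 12/(6*7) * 16 = 32/7
        h, _ = ft.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(32 / 7)

    def test_two_group_evidence_ordering_matches_mann_whitney(self):
        """In the 2-group case KW and U rank datasets by evidence identically."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(13)
        p_kw, p_mw = [], []
        for _ in range(15):
            a = rng.normal(size=6)
            b = rng.normal(rng.uniform(0, 2), 1.0, size=6)
            p_kw.append(ft.kruskal_wallis([a, b])[1])
            p_mw.append(ft.mann_whitney_exact(a, b).p)
        rho, _ = spearmanr(p_kw, p_mw)
        assert rho > 0.95

    def test_gate_blocks_pairwise_when_omnibus_ns(self):
        rng = np.random.default_rng(14)
        groups = {g: rng.normal(size=6) for g in "ABC"}
        (_, p), pmat = ft.kruskal_gated_pairwise(groups, alpha=1e-9)
        assert pmat is None

    def test_gate_opens_on_strong_difference(self):
        groups = {"A": [1, 2, 3, 4, 5, 6], "B": [11, 12, 13, 14, 15, 16], "C": [1.5, 2.5, 3.5, 4.5, 5.5, 6.5]}
        (_, p), pmat = ft.kruskal_gated_pairwise(groups)
        assert p < 0.05 and pmat is not None
        assert pmat.loc["A", "B"] < 0.05 < pmat.loc["A", "C"]


class TestRelativeExpression:
    @pytest.mark.parametrize(
        "ct_t,ct_r,expected", [(20.0, 20.0, 1.0), (19.0, 20.0, 2.0), (22.0, 20.0, 0.25)]
    )
    def test_pointwise(self, ct_t, ct_r, expected):
        assert ft.relative_expression(ct_t, ct_r) == pytest.approx(expected)

    @given(st.floats(min_value=-5, max_value=5))
    def test_shift_invariance(self, shift):
        base = ft.relative_expression(24.0, 20.0)
        assert ft.relative_expression(24.0 + shift, 20.0 + shift) == pytest.approx(base, rel=1e-9)

    def test_bad_efficiency_raises(self):
        with pytest.raises(ValueError):
            ft.relative_expression(20.0, 20.0, efficiency=2.5)

    def test_qpcr_chain_recovers_planted_fold_change(self):
        ds = ft.generate_qpcr_dataset(
            n_genes=2, planted_log2fc=1.0, ct_sd=0.0, duplicate_sd=0.0, seed=0
        )
        levels = ft.qpcr_relative_expression(ds.records)
        means = levels.groupby("group").mean()
        ratio = means.loc["Fsh", "gene_01"] / means.loc["Ctrl", "gene_01"]
        assert ratio == pytest.approx(2.0)


class TestLetterGrouping:
    def _pmat(self, entries, groups=("A", "B", "C")):
        pmat = pd.DataFrame(1.0, index=list(groups), columns=list(groups))
        for (g1, g2), p in entries.items():
            pmat.loc[g1, g2] = pmat.loc[g2, g1] = p
        return pmat

    def test_no_differences_single_letter(self):
        letters = ft.letter_grouping(self._pmat({}))
        assert set(letters.values()) == {"a"}

    def test_all_different_three_letters(self):
        pmat = self._pmat({("A", "B"): 0.001, ("A", "C"): 0.001, ("B", "C"): 0.001})
        letters = ft.letter_grouping(pmat)
        assert letters == {"A": "a", "B": "b", "C": "c"}

    def test_chain_case_shares_middle_letter(self):
        pmat = self._pmat({("A", "C"): 0.01})
        letters = ft.letter_grouping(pmat)
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_letters_encode_significance_graph(self):
        rng = np.random.default_rng(15)
        groups = list("ABCD")
        pmat = pd.DataFrame(1.0, index=groups, columns=groups)
        for g1, g2 in itertools.combinations(groups, 2):
            p = float(rng.uniform(0, 0.1))
            pmat.loc[g1, g2] = pmat.loc[g2, g1] = p
        letters = ft.letter_grouping(pmat, alpha=0.05)
        for g1, g2 in itertools.combinations(groups, 2):
            share = bool(set(letters[g1]) & set(letters[g2]))
            assert share == (pmat.loc[g1, g2] >= 0.05)
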