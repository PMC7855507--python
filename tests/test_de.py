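"""Unit and property tests for normalization, dispersion and the exact test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from regenseq import (
    CountMatrix,
    SimulationConfig,
    adjust_bh,
    estimate_dispersion,
    exact_conditional_pvalue,
    fpkm_matrix,
    nb_test,
    run_de_suite,
    simulate_counts,
    size_factors_median_of_ratios,
    size_factors_total_count,
    size_factors_upper_quartile,
)

from conftest import brute_force_bh


def _matrix(values, samples=None, groups=None):
    df = pd.DataFrame(values, dtype=np.int64)
    df.index = [f"g{i}" for i in range(len(df))]
    df.columns = samples or [f"s{j}" for j in range(df.shape[1])]
    if groups is None:
        half = df.shape[1] // 2
        groups = ["a"] * half + ["b"] * (df.shape[1] - half)
    return CountMatrix(counts=df, groups=pd.Series(groups, index=df.columns))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = _matrix(np.tile([[5], [10], [0], [20]], (1, 4)))
        for fn in (size_factors_upper_quartile, size_factors_median_of_ratios):
            np.testing.assert_allclose(fn(cm), 1.0)

    @pytest.mark.parametrize(
        "fn", [size_factors_upper_quartile, size_factors_median_of_ratios,
               size_factors_total_count]
    )
    def test_doubled_column_has_double_factor(self, fn):
        base = np.array([[5], [10], [3], [20]])
        cm = _matrix(np.hstack([base, 2 * base, base, base]))
        f = fn(cm)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0, rel=1e-12)

    def test_upper_quartile_matches_hand_computation(self):
        # genes nonzero in >=1 sample: all four rows; 75th percentile by
        # linear interpolation of [2, 4, 6, 100] is 6 + 0.25*94 = 29.5,
        # of [1, 2, 3, 50] is 3 + 0.25*47 = 14.75
        cm = _matrix([[2, 1], [4, 2], [6, 3], [100, 50]], groups=["a", "b"])
        raw = np.array([29.5, 14.75])
        expected = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(
            size_factors_upper_quartile(cm.counts), expected, rtol=1e-12
        )

    def test_median_of_ratios_excludes_zero_genes(self):
        vals = np.array([[10, 20], [4, 8], [0, 7], [9, 18]])
        cm = _matrix(vals, groups=["a", "b"])
        # brute-force median-of-ratios on the three all-positive genes
        ref = vals[[0, 1, 3]].astype(float)
        geo = np.exp(np.mean(np.log(ref), axis=1))
        expected = np.median(ref / geo[:, None], axis=0)
        np.testing.assert_allclose(
            size_factors_median_of_ratios(cm.counts), expected, rtol=1e-12
        )

    def test_all_zero_sample_is_rejected_by_name(self):
        cm = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="empty"):
            size_factors_upper_quartile(cm)

    def test_no_all_positive_gene_is_rejected(self):
        cm = pd.DataFrame({"s1": [0, 4], "s2": [3, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="reference"):
            size_factors_median_of_ratios(cm)

    def test_scale_equivariance_integer_multiple(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(40, size=(60, 4)) + 1
        for c in (2, 5):
            scaled = base.copy()
            scaled[:, 2] *= c
            for fn in (size_factors_upper_quartile, size_factors_median_of_ratios):
                f0 = fn(_matrix(base))
                f1 = fn(_matrix(scaled))
                assert f1.iloc[2] / f0.iloc[2] * f0.iloc[0] / f1.iloc[0] == pytest.approx(
                    c, rel=1e-9
                )


class TestFpkm:
    def test_definition(self):
        counts = pd.DataFrame({"s": [10, 0]}, index=["g1", "g2"])
        counts.loc["g3"] = 10**6 - 10
        lengths = pd.Series({"g1": 1000, "g2": 500, "g3": 1000})
        fp = fpkm_matrix(counts, lengths)
        assert fp.loc["g1", "s"] == pytest.approx(10.0)
        assert fp.loc["g2", "s"] == 0.0

    def test_arithmetic_oracle(self):
        counts = pd.DataFrame({"s": [250, 5 * 10**6 - 250]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 2500, "g2": 1000})
        expected = 250 * 1e9 / (2500 * 5e6)
        assert fpkm_matrix(counts, lengths).loc["g1", "s"] == pytest.approx(expected)

    def test_missing_length_names_gene(self):
        counts = pd.DataFrame({"s": [1, 2]}, index=["g1", "gX"])
        with pytest.raises(ValueError, match="gX"):
            fpkm_matrix(counts, pd.Series({"g1": 100}))


class TestDispersion:
    def test_constant_gene_has_zero_dispersion(self):
        cm = _matrix(np.full((5, 6), 7), groups=["a"] * 3 + ["b"] * 3)
        disp = estimate_dispersion(cm, pd.Series(1.0, index=cm.sample_ids), shrink=False)
        np.testing.assert_allclose(disp, 0.0)

    def test_poisson_data_has_near_zero_median(self):
        cfg = SimulationConfig(
            n_genes=800, n_replicates_per_group=25, dispersion=0.0,
            library_size_cv=0.0, fraction_de=0.0, seed=7,
        )
        inj, ctl, _ = simulate_counts(cfg)
        cm = CountMatrix.concat(inj, ctl)
        disp = estimate_dispersion(cm, pd.Series(1.0, index=cm.sample_ids), shrink=False)
        assert abs(float(np.median(disp))) < 0.01

    def test_nb_dispersion_recovered_with_many_replicates(self):
        cfg = SimulationConfig(
            n_genes=600, n_replicates_per_group=50, dispersion=0.2,
            library_size_cv=0.0, fraction_de=0.0, seed=11,
        )
        inj, ctl, _ = simulate_counts(cfg)
        cm = CountMatrix.concat(inj, ctl)
        disp = estimate_dispersion(cm, pd.Series(1.0, index=cm.sample_ids), shrink=False)
        assert 0.15 <= float(np.median(disp)) <= 0.25

    def test_single_replicate_group_is_rejected(self):
        cm = _matrix([[1, 2, 3]], groups=["a", "a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_dispersion(cm, pd.Series(1.0, index=cm.sample_ids))


class TestExactTest:
    def test_identical_group_means_are_null(self):
        cm = _matrix([[10, 10, 10, 10], [3, 3, 3, 3]])
        factors = pd.Series(1.0, index=cm.sample_ids)
        disp = pd.Series(0.0, index=cm.gene_ids)
        res = nb_test(cm, factors, disp)
        np.testing.assert_allclose(res.table["log2FC"], 0.0)
        np.testing.assert_allclose(res.table["pvalue"], 1.0)

    def test_poisson_limit_matches_binomial_oracle(self):
        # group totals 30 vs 10, equal depth, equal group sizes: conditional
        # law is Binomial(40, 1/2); two-sided p doubles the smaller tail.
        p = exact_conditional_pvalue(30, 40, n1=4, n2=4, dispersion=0.0)
        expected = min(1.0, 2.0 * min(binom.cdf(30, 40, 0.5), binom.sf(29, 40, 0.5)))
        assert p == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("a,t,n1,n2", [(0, 12, 3, 3), (7, 20, 4, 2), (55, 100, 5, 5)])
    def test_binomial_conditional_oracle_sweep(self, a, t, n1, n2):
        p = exact_conditional_pvalue(a, t, n1, n2, dispersion=0.0)
        pr = n1 / (n1 + n2)
        expected = min(1.0, 2.0 * min(binom.cdf(a, t, pr), binom.sf(a - 1, t, pr)))
        assert p == pytest.approx(expected, rel=1e-12)

    def test_pvalue_monotone_in_group_difference(self):
        pvals = [
            exact_conditional_pvalue(a, 60, 4, 4, dispersion=0.1)
            for a in range(30, 56, 5)
        ]
        assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(pvals, pvals[1:]))

    def test_more_than_two_groups_rejected(self):
        cm = _matrix([[1, 2, 3]], groups=["a", "b", "c"])
        with pytest.raises(ValueError, match="two groups"):
            nb_test(cm, pd.Series(1.0, index=cm.sample_ids),
                    pd.Series(0.0, index=cm.gene_ids))


class TestBH:
    def test_examples(self):
        assert adjust_bh(np.array([0.03]))[0] == pytest.approx(0.03)
        np.testing.assert_allclose(
            adjust_bh(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_bh(np.array([0.5, 1.2]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_brute_force_and_dominates_input(self, pvals):
        p = np.array(pvals)
        adj = adjust_bh(p)
        np.testing.assert_allclose(adj, brute_force_bh(p), rtol=1e-12, atol=1e-15)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestSuite:
    def test_equal_factors_make_uq_and_mor_agree(self):
        # identical columns => both factor estimators give all ones
        cm = _matrix(np.tile([[8], [15], [4], [30], [2]], (1, 8)))
        res = run_de_suite(cm)
        np.testing.assert_allclose(
            res["UQ"].table["pvalue"], res["MOR"].table["pvalue"]
        )

    def test_planted_genes_recovered_by_each_scorer(self, small_sim):
        cm, truth, _ = small_sim
        res = run_de_suite(cm, test_group="injured")
        de = truth.de_flags
        for method_id, r in res.items():
            hits = (r.table.loc[de[de].index, "padj"] <= 0.05) & (
                r.table.loc[de[de].index, "log2FC"].abs() >= 1
            )
            assert hits.mean() >= 0.70, method_id

    def test_log2fc_sign_tracks_planted_sign(self, small_sim):
        cm, truth, _ = small_sim
        res = run_de_suite(cm, test_group="injured")
        planted = truth.true_lfc[truth.de_flags]
        est = res["MOR"].table.loc[planted.index, "log2FC"]
        assert (np.sign(est) == np.sign(planted)).mean() > 0.95
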