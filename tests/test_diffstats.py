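"""Differential peak/gene calling, BH adjustment and FPKM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from moltseq.diffstats import (benjamini_hochberg, call_degs, call_deps, fpkm,
                               size_factors)
from moltseq.peaks import PeakRecord


def _peak(pid, fe):
    return PeakRecord(pid, "chr1", 0, 100, fold_enrich=fe)


class TestBenjaminiHochberg:
    def test_hand_worked_example(self):
        # step-up on (0.01, 0.02, 0.03, 0.04): min_j>=i 4*p_(j)/j = 0.04 each
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3])[0] == 0.3

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_step_up_definition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, int(rng.integers(1, 40)))
        m = len(p)
        # brute-force step-up definition
        order = np.argsort(p)
        expected = np.empty(m)
        for rank_pos, idx in enumerate(order):
            vals = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
            expected[idx] = min(1.0, min(vals))
        np.testing.assert_allclose(benjamini_hochberg(p), expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_statsmodels(self, seed):
        p = np.random.default_rng(seed).uniform(0, 1, 50)
        np.testing.assert_allclose(
            benjamini_hochberg(p),
            multipletests(p, method="fdr_bh")[1], atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    def test_permutation_equivariant(self, pvals, rand):
        p = np.array(pvals)
        perm = np.arange(len(p))
        rand.shuffle(perm)
        np.testing.assert_allclose(
            benjamini_hochberg(p)[perm], benjamini_hochberg(p[perm]), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestCallDeps:
    def _samples(self):
        return ["a1", "a2", "a3"], ["b1", "b2", "b3"]

    def test_twofold_shift_threshold_semantics(self):
        sa, sb = self._samples()
        jit = [0.99, 1.0, 1.01]
        peaks = [_peak("p1", {**{s: 4 * j for s, j in zip(sa, jit)},
                              **{s: 8 * j for s, j in zip(sb, jit)}}),
                 _peak("p2", {**{s: 4 * j for s, j in zip(sa, jit)},
                              **{s: 9 * j for s, j in zip(sb, jit)}})]
        table = call_deps(peaks, sa, sb)
        for _, row in table.iterrows():
            assert row.significant == (row.pvalue <= 0.05
                                       and abs(row.log2fc) >= 1)
        assert table.iloc[0].log2fc == pytest.approx(1.0, abs=0.01)
        # the pseudocount keeps an exact 2-fold ratio a hair under the
        # inclusive |log2fc| >= 1 boundary; a 2.25-fold shift clears it
        assert table.iloc[1].significant

    def test_identical_groups_not_significant(self):
        sa, sb = self._samples()
        peaks = [_peak("p1", {s: 4.0 for s in sa + sb})]
        row = call_deps(peaks, sa, sb).iloc[0]
        assert row.log2fc == 0
        assert row.pvalue == 1.0  # zero variance, equal means
        assert not row.significant

    def test_threshold_boundaries_inclusive(self):
        # rig the table: feature exactly at p = 0.05 and |lfc| = 1 counts
        sa, sb = self._samples()
        peaks = [_peak("p", {s: 1.0 for s in sa + sb})]
        table = call_deps(peaks, sa, sb)
        table.loc[0, ["pvalue", "log2fc"]] = [0.05, 1.0]
        sig = (table.pvalue <= 0.05) & (table.log2fc.abs() >= 1.0)
        assert bool(sig[0])

    def test_swapping_conditions_negates_log2fc_keeps_p(self):
        rng = np.random.default_rng(3)
        sa, sb = self._samples()
        peaks = [
            _peak(f"p{i}", {s: float(v) for s, v in
                            zip(sa + sb, rng.lognormal(1.5, 0.4, 6))})
            for i in range(30)
        ]
        fwd = call_deps(peaks, sa, sb)
        rev = call_deps(peaks, sb, sa)
        np.testing.assert_allclose(fwd.log2fc, -rev.log2fc, atol=1e-12)
        np.testing.assert_allclose(fwd.pvalue, rev.pvalue, atol=1e-12)

    def test_all_missing_condition_is_untested(self):
        sa, sb = self._samples()
        peaks = [_peak("p1", {s: 2.0 for s in sa})]  # absent from b entirely
        row = call_deps(peaks, sa, sb).iloc[0]
        assert not row.tested and not row.significant

    def test_partial_missing_treated_as_zero(self):
        sa, sb = self._samples()
        peaks = [_peak("p1", {**{s: 6.0 for s in sa}, "b1": 6.0})]
        row = call_deps(peaks, sa, sb).iloc[0]
        assert row.tested
        assert row.mean_b == pytest.approx(2.0)  # (6 + 0 + 0) / 3

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            call_deps([], ["a1"], ["b1", "b2"])

    def test_planted_effect_recall(self):
        """Planted |log2 effect| = 3 with sigma = 0.2 lognormal replicate
        noise is recovered in >= 90% of 500 peaks."""
        rng = np.random.default_rng(7)
        sa, sb = self._samples()
        peaks = []
        for i in range(500):
            base = rng.lognormal(1.5, 0.5)
            fe = {s: base * np.exp(rng.normal(0, 0.2)) for s in sa}
            fe |= {s: base * 8 * np.exp(rng.normal(0, 0.2)) for s in sb}
            peaks.append(_peak(f"p{i}", {k: float(v) for k, v in fe.items()}))
        table = call_deps(peaks, sa, sb)
        assert table.significant.mean() >= 0.9


class TestCallDegs:
    def _counts(self, rows, samples=("a1", "a2", "a3", "b1", "b2", "b3")):
        return pd.DataFrame(rows, columns=samples,
                            index=[f"g{i}" for i in range(len(rows))])

    def test_eightfold_gene_called_significant(self):
        rows = [[10, 12, 11, 80, 95, 88]]
        # small stable background so size factors are ~equal
        rng = np.random.default_rng(1)
        rows += rng.poisson(100, size=(20, 6)).tolist()
        table = call_degs(self._counts(rows), ["a1", "a2", "a3"],
                          ["b1", "b2", "b3"])
        row = table.iloc[0]
        assert row.log2fc == pytest.approx(3.0, abs=0.35)
        assert abs(row.log2fc) >= 1
        assert row.significant

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(2)
        rows = rng.poisson(50, size=(100, 6)).tolist()
        table = call_degs(self._counts(rows), ["a1", "a2", "a3"],
                          ["b1", "b2", "b3"])
        assert table.log2fc.abs().mean() < 0.3
        assert table.significant.sum() <= 5

    def test_all_zero_gene_untested(self):
        rows = [[0, 0, 0, 0, 0, 0], [10, 11, 9, 10, 12, 11]]
        table = call_degs(self._counts(rows), ["a1", "a2", "a3"],
                          ["b1", "b2", "b3"])
        assert not table.iloc[0].tested
        assert table.iloc[1].tested

    def test_swapping_conditions_negates_log2fc(self):
        rng = np.random.default_rng(4)
        rows = rng.poisson(60, size=(80, 6)).tolist()
        counts = self._counts(rows)
        fwd = call_degs(counts, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        rev = call_degs(counts, ["b1", "b2", "b3"], ["a1", "a2", "a3"])
        np.testing.assert_allclose(fwd.log2fc, -rev.log2fc, atol=1e-9)
        np.testing.assert_allclose(fwd.pvalue, rev.pvalue, atol=1e-9)

    def test_single_condition_is_error(self):
        with pytest.raises(ValueError):
            call_degs(self._counts([[1, 2, 3, 4, 5, 6]]), ["a1", "a2", "a3"], ["b1"])

    def test_padj_at_least_pvalue(self):
        rng = np.random.default_rng(9)
        rows = rng.poisson(40, size=(150, 6)).tolist()
        table = call_degs(self._counts(rows), ["a1", "a2", "a3"],
                          ["b1", "b2", "b3"])
        t = table[table.tested]
        assert (t.padj >= t.pvalue - 1e-12).all()


def test_size_factors_recover_depth_ratio():
    rng = np.random.default_rng(0)
    base = rng.poisson(100, size=(500, 1)).astype(float)
    counts = pd.DataFrame(
        np.round(base * np.array([1.0, 2.0, 0.5])),
        columns=["s1", "s2", "s3"])
    sf = size_factors(counts)
    ratios = sf / sf.iloc[0]
    np.testing.assert_allclose(ratios, [1.0, 2.0, 0.5], rtol=0.02)


class TestFpkm:
    def test_basic_identity(self):
        counts = pd.DataFrame({"s1": [10]}, index=["g1"])
        result = fpkm(counts, pd.Series({"g1": 1000}), pd.Series({"s1": 1_000_000}))
        assert result.loc["g1", "s1"] == pytest.approx(10.0)

    def test_doubling_library_halves_fpkm(self):
        counts = pd.DataFrame({"s1": [7, 3], "s2": [7, 3]}, index=["g1", "g2"])
        lens = pd.Series({"g1": 500, "g2": 1500})
        one = fpkm(counts, lens, pd.Series({"s1": 1e6, "s2": 2e6}))
        np.testing.assert_allclose(one["s1"], 2 * one["s2"])

    def test_matches_scalar_loop(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(rng.integers(0, 1000, size=(20, 4)),
                              index=[f"g{i}" for i in range(20)],
                              columns=[f"s{j}" for j in range(4)])
        lens = pd.Series(rng.integers(200, 5000, 20), index=counts.index)
        libs = pd.Series(rng.integers(10**5, 10**7, 4), index=counts.columns)
        result = fpkm(counts, lens, libs)
        for g in counts.index:
            for s in counts.columns:
                expected = counts.loc[g, s] * 1e9 / (lens[g] * libs[s])
                assert result.loc[g, s] == expected

    def test_zero_length_or_library_is_error(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(ValueError):
            fpkm(counts, pd.Series({"g1": 0}), pd.Series({"s1": 1e6}))
        with pytest.raises(ValueError):
            fpkm(counts, pd.Series({"g1": 100}), pd.Series({"s1": 0}))
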