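"""Pair filtering, binning, ICE balancing, subtraction, boundary calls."""
import numpy as np
import pandas as pd
import pytest

from oracles import decayed_block_matrix, enumeration_oracle
from tadquant.chic import (
    ContactMatrix,
    balance_ice,
    bin_pairs,
    call_boundaries,
    compare_submatrices,
    diamond_bin_signal,
    filter_pairs,
    observed_over_expected,
    subtract_matrices,
)
from tadquant.locus import GenomicInterval

SPAN = GenomicInterval("c", 0, 100_000, "capture")


def pairs_df(rows):
    return pd.DataFrame(
        rows, columns=["chrom1", "pos1", "chrom2", "pos2", "mapq1", "mapq2"]
    )


class TestFilterPairs:
    @pytest.mark.parametrize(
        "mapq1,mapq2,kept",
        [(30, 60, True), (29, 60, False), (60, 29, False), (30, 30, True)],
    )
    def test_threshold_inclusive(self, mapq1, mapq2, kept):
        pairs = pairs_df([("c", 100, "c", 5_000, mapq1, mapq2)])
        assert len(filter_pairs(pairs, SPAN)) == (1 if kept else 0)

    def test_mate_outside_span_dropped(self):
        pairs = pairs_df(
            [("c", 100, "c", 200_000, 60, 60), ("c", 100, "c", 5_000, 60, 60)]
        )
        kept = filter_pairs(pairs, SPAN)
        assert len(kept) == 1 and kept["pos2"].iloc[0] == 5_000

    def test_canonical_order(self):
        pairs = pairs_df([("c", 9_000, "c", 100, 40, 50)])
        kept = filter_pairs(pairs, SPAN)
        assert (kept["pos1"].iloc[0], kept["pos2"].iloc[0]) == (100, 9_000)
        assert (kept["mapq1"].iloc[0], kept["mapq2"].iloc[0]) == (50, 40)


class TestBinPairs:
    def test_symmetric_increment(self):
        pairs = pairs_df([("c", 25_000, "c", 75_000, 60, 60)])
        m = bin_pairs(pairs, SPAN, 10_000)
        assert m.counts[2, 7] == 1 and m.counts[7, 2] == 1
        assert m.counts.sum() == 2

    def test_diagonal_incremented_once(self):
        pairs = pairs_df([("c", 41_000, "c", 44_000, 60, 60)])
        m = bin_pairs(pairs, SPAN, 10_000)
        assert m.counts[4, 4] == 1
        assert m.counts.sum() == 1

    def test_additivity(self):
        pairs = pairs_df([("c", 25_000, "c", 75_000, 60, 60)] * 10)
        m = bin_pairs(pairs, SPAN, 10_000)
        assert m.counts[2, 7] == 10

    def test_outside_span_errors(self):
        pairs = pairs_df([("c", 25_000, "c", 200_000, 60, 60)])
        with pytest.raises(ValueError, match="outside span"):
            bin_pairs(pairs, SPAN, 10_000)


class TestBalanceICE:
    def test_equal_rowsum_matrix_is_fixed_point(self):
        counts = np.array([[0.0, 4.0], [4.0, 0.0]])
        m = ContactMatrix(span=GenomicInterval("c", 0, 10_000), bin_size=5_000,
                          counts=counts)
        out = balance_ice(m, min_marginal=1)
        # 2x2 closed form: equal marginals, scale fixes marginals to 1
        assert out.balanced == pytest.approx(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert out.weights == pytest.approx([0.5, 0.5])

    def test_zero_row_masked(self, rng):
        counts = rng.poisson(50.0, size=(6, 6)).astype(float)
        counts = np.triu(counts) + np.triu(counts, 1).T
        counts[3, :] = 0.0
        counts[:, 3] = 0.0
        m = ContactMatrix(span=GenomicInterval("c", 0, 60_000), bin_size=10_000,
                          counts=counts)
        out = balance_ice(m, min_marginal=1)
        assert out.bad_bins[3]
        assert np.isnan(out.balanced[3]).all()
        assert np.isnan(out.balanced[:, 3]).all()

    def test_unmasked_marginals_equal_within_tol(self, rng):
        counts = rng.poisson(30.0, size=(25, 25)).astype(float)
        counts = np.triu(counts) + np.triu(counts, 1).T
        m = ContactMatrix(span=GenomicInterval("c", 0, 250_000),
                          bin_size=10_000, counts=counts)
        out = balance_ice(m, tol=1e-6)
        marg = np.nansum(out.balanced, axis=1)[~out.bad_bins]
        assert marg.std() / marg.mean() < 1e-5
        assert marg.mean() == pytest.approx(1.0, rel=1e-5)

    def test_idempotent(self, rng):
        counts = rng.poisson(30.0, size=(20, 20)).astype(float)
        counts = np.triu(counts) + np.triu(counts, 1).T
        m = ContactMatrix(span=GenomicInterval("c", 0, 200_000),
                          bin_size=10_000, counts=counts)
        once = balance_ice(m, tol=1e-8)
        again_input = ContactMatrix(
            span=m.span, bin_size=m.bin_size,
            counts=np.nan_to_num(once.balanced))
        again = balance_ice(again_input, tol=1e-8, min_marginal=0.0)
        good = ~once.bad_bins
        ratio = again.balanced[np.ix_(good, good)] / \
            once.balanced[np.ix_(good, good)]
        ratio = ratio[np.isfinite(ratio)]
        assert ratio == pytest.approx(np.ones_like(ratio), rel=1e-4)

    def test_all_masked_errors(self):
        counts = np.ones((3, 3))
        m = ContactMatrix(span=GenomicInterval("c", 0, 30_000),
                          bin_size=10_000, counts=counts)
        with pytest.raises(ValueError, match="masked"):
            balance_ice(m, min_marginal=100)

    def test_symmetry_preserved(self, rng):
        counts = rng.poisson(40.0, size=(15, 15)).astype(float)
        counts = np.triu(counts) + np.triu(counts, 1).T
        m = ContactMatrix(span=GenomicInterval("c", 0, 150_000),
                          bin_size=10_000, counts=counts)
        out = balance_ice(m)
        good = ~out.bad_bins
        sub = out.balanced[np.ix_(good, good)]
        assert sub == pytest.approx(sub.T)


def _random_balanced(rng, n=18):
    counts = rng.poisson(40.0, size=(n, n)).astype(float)
    counts = np.triu(counts) + np.triu(counts, 1).T
    m = ContactMatrix(span=GenomicInterval("c", 0, n * 10_000),
                      bin_size=10_000, counts=counts)
    return balance_ice(m)


class TestSubtraction:
    def test_self_subtraction_zero(self, rng):
        a = _random_balanced(rng)
        diff = subtract_matrices(a, a)
        good = ~np.isnan(diff)
        assert diff[good] == pytest.approx(np.zeros(good.sum()), abs=1e-12)

    def test_antisymmetry(self, rng):
        a, b = _random_balanced(rng), _random_balanced(rng)
        ab, ba = subtract_matrices(a, b), subtract_matrices(b, a)
        good = ~np.isnan(ab)
        assert ab[good] == pytest.approx(-ba[good])

    def test_scale_invariance(self, rng):
        a, b = _random_balanced(rng), _random_balanced(rng)
        scaled = ContactMatrix(span=a.span, bin_size=a.bin_size,
                               counts=a.counts, balanced=a.balanced * 37.5,
                               bad_bins=a.bad_bins)
        ref, alt = subtract_matrices(a, b), subtract_matrices(scaled, b)
        good = ~np.isnan(ref)
        assert alt[good] == pytest.approx(ref[good])

    def test_shape_mismatch_errors(self, rng):
        a = _random_balanced(rng, 10)
        b = _random_balanced(rng, 12)
        with pytest.raises(ValueError, match="span"):
            subtract_matrices(a, b)


class TestCompareSubmatrices:
    def _balanced_from(self, values):
        n = values.shape[0]
        return ContactMatrix(span=GenomicInterval("c", 0, n * 10_000),
                             bin_size=10_000, balanced=values,
                             bad_bins=np.zeros(n, dtype=bool))

    def test_identical_matrices_degenerate(self, rng):
        a = _random_balanced(rng)
        with pytest.warns(UserWarning):
            res = compare_submatrices(
                a, a, GenomicInterval("c", 0, 50_000),
                GenomicInterval("c", 100_000, 180_000))
        assert res.p_value == 1.0

    def test_five_positive_differences(self):
        n = 20
        base = np.ones((n, n))
        other = base.copy()
        other[0, 10:15] += 1.0
        other[10:15, 0] += 1.0
        other[5, 15:20] -= 1.0  # keep totals equal so scaling cancels
        other[15:20, 5] -= 1.0
        a, b = self._balanced_from(base), self._balanced_from(other)
        res = compare_submatrices(
            a, b, GenomicInterval("c", 0, 10_000),
            GenomicInterval("c", 100_000, 150_000))
        assert res.n_pairs == 5
        assert res.p_value == pytest.approx(0.0625)

    def test_masked_bins_contribute_no_pairs(self, rng):
        a, b = _random_balanced(rng), _random_balanced(rng)
        rows = GenomicInterval("c", 0, 30_000)
        cols = GenomicInterval("c", 100_000, 150_000)
        full = compare_submatrices(a, b, rows, cols)
        a2 = ContactMatrix(span=a.span, bin_size=a.bin_size,
                           balanced=a.balanced, bad_bins=a.bad_bins.copy())
        a2.bad_bins[1] = True
        masked = compare_submatrices(a2, b, rows, cols)
        assert masked.n_pairs <= full.n_pairs - 1

    def test_exact_branch_matches_enumeration(self, rng):
        for _ in range(5):
            n = 20
            base = np.abs(rng.normal(1.0, 0.2, size=(n, n)))
            base = (base + base.T) / 2
            delta = rng.normal(0, 0.05, size=(n, n))
            delta = (delta + delta.T) / 2
            a = self._balanced_from(base)
            b = self._balanced_from(base + delta)
            rows = GenomicInterval("c", 0, 20_000)
            cols = GenomicInterval("c", 100_000, 140_000)
            res = compare_submatrices(a, b, rows, cols)
            sa = base / base.sum()
            sb = (base + delta) / (base + delta).sum()
            diffs = (sb - sa)[0:2, 10:14].ravel()
            w_ref, p_ref = enumeration_oracle(diffs)
            assert res.statistic == pytest.approx(w_ref)
            assert res.p_value == pytest.approx(p_ref)


class TestDiamondSignal:
    def _matrix(self, values):
        n = values.shape[0]
        return ContactMatrix(span=GenomicInterval("c", 0, n * 10_000),
                             bin_size=10_000, balanced=values.astype(float),
                             bad_bins=np.zeros(n, dtype=bool))

    def test_uniform_matrix_constant_interior(self):
        m = self._matrix(np.full((30, 30), 3.0))
        sig = diamond_bin_signal(m, 5)
        assert sig[:-1] == pytest.approx(np.full(29, 3.0))
        assert np.isnan(sig[-1])

    def test_two_block_minimum_at_boundary(self):
        n, k, h = 30, 15, 4.0
        values = np.zeros((n, n))
        values[:k, :k] = h
        values[k:, k:] = h
        sig = diamond_bin_signal(self._matrix(values), 5)
        assert sig[k - 1] == pytest.approx(0.0)
        assert np.nanargmin(sig) == k - 1

    def test_w1_is_first_offdiagonal(self, rng):
        values = rng.random((10, 10))
        values = (values + values.T) / 2
        sig = diamond_bin_signal(self._matrix(values), 1)
        for i in range(9):
            assert sig[i] == pytest.approx(values[i, i + 1])


class TestCallBoundaries:
    def _matrix(self, values):
        n = values.shape[0]
        m = ContactMatrix(span=GenomicInterval("c", 0, n * 10_000),
                          bin_size=10_000, counts=values.astype(float))
        return balance_ice(m, min_marginal=1)

    def test_uniform_matrix_no_boundaries(self):
        m = self._matrix(np.full((60, 60), 20.0))
        assert call_boundaries(m, w=5) == []

    def test_planted_two_block(self, rng):
        counts = decayed_block_matrix(80, [40], rng)
        calls = call_boundaries(self._matrix(counts), w=8)
        assert len(calls) == 1
        assert abs(calls[0].bin_index - 40) <= 1

    def test_three_equal_blocks(self, rng):
        counts = decayed_block_matrix(120, [40, 80], rng)
        calls = call_boundaries(self._matrix(counts), w=8)
        assert len(calls) == 2
        assert abs(calls[0].bin_index - 40) <= 1
        assert abs(calls[1].bin_index - 80) <= 1

    def test_too_small_matrix_warns_empty(self, rng):
        counts = decayed_block_matrix(20, [10], rng)
        with pytest.warns(UserWarning, match="too small"):
            assert call_boundaries(self._matrix(counts), w=10) == []

    def test_high_resolution_warns(self, rng):
        counts = decayed_block_matrix(80, [40], rng)
        m = ContactMatrix(span=GenomicInterval("c", 0, 80 * 5_000),
                          bin_size=5_000, counts=counts)
        with pytest.warns(UserWarning, match="resolution|gaps|bins"):
            call_boundaries(balance_ice(m, min_marginal=1), w=8)


def test_observed_over_expected_flattens_decay(rng):
    n = 50
    idx = np.arange(n)
    mu = 100.0 / np.maximum(np.abs(idx[:, None] - idx[None, :]), 1.0)
    oe = observed_over_expected(mu)
    good = ~np.isnan(oe)
    assert oe[good] == pytest.approx(np.ones(good.sum()))
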