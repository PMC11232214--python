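"""Proportionality rho, spatial quantile normalization, thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from norfnet.expression import ClrMatrix
from norfnet.proportionality import (CoexpressionMatrix, SpqnConfig,
                                     coverage_threshold, percentile_threshold,
                                     rho_matrix, rho_pair, spqn_normalize)


def _clr(values, ids=None):
    df = pd.DataFrame(np.asarray(values, dtype=float))
    df.index = ids or [f"orf{i}" for i in range(df.shape[0])]
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ClrMatrix(df)


def brute_rho(x, y):
    d = x - y
    return 1.0 - d.var(ddof=1) / (x.var(ddof=1) + y.var(ddof=1))


class TestRhoPair:
    def test_identical_is_one(self):
        x = np.random.default_rng(0).normal(size=50)
        assert rho_pair(x, x, min_shared=10) == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        x = np.random.default_rng(0).normal(size=50)
        assert rho_pair(x, -x, min_shared=10) == pytest.approx(-1.0)

    def test_399_shared_samples_missing(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        y[399:] = np.nan                  # 399 shared detected samples
        assert np.isnan(rho_pair(x, y, min_shared=400))
        y2 = rng.normal(size=500)
        y2[400:] = np.nan                 # exactly 400 -> defined
        assert np.isfinite(rho_pair(x, y2, min_shared=400))

    def test_independent_normals_near_zero(self):
        rng = np.random.default_rng(42)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert abs(rho_pair(x, y, min_shared=100)) < 0.05

    def test_zero_variance_missing(self):
        assert np.isnan(rho_pair(np.ones(20), np.arange(20.0), min_shared=5))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rho_pair(np.ones(3), np.ones(4))


class TestRhoMatrix:
    def test_matches_brute_force_dense(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            A = rng.normal(size=(20, 500))
            coex = rho_matrix(_clr(A), min_shared=10)
            R = coex.rho.to_numpy()
            for i in range(20):
                for j in range(i + 1, 20):
                    assert abs(R[i, j] - brute_rho(A[i], A[j])) < 1e-12

    def test_matches_rho_pair_with_missingness(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(8, 200))
        A[rng.random(A.shape) < 0.3] = np.nan
        coex = rho_matrix(_clr(A), min_shared=20)
        for i in range(8):
            for j in range(i + 1, 8):
                expect = rho_pair(A[i], A[j], min_shared=20)
                got = coex.rho.iloc[i, j]
                assert (np.isnan(got) and np.isnan(expect)) or \
                    got == pytest.approx(expect, abs=1e-12)

    def test_symmetry_range_and_shared_counts(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(30, 120))
        A[rng.random(A.shape) < 0.2] = np.nan
        coex = rho_matrix(_clr(A), min_shared=10)
        R = coex.rho.to_numpy()
        assert np.allclose(R, R.T, equal_nan=True)
        finite = R[np.isfinite(R)]
        assert finite.min() >= -1.0 and finite.max() <= 1.0
        i, j = 3, 7
        assert coex.n_shared.iloc[i, j] == \
            (~np.isnan(A[i]) & ~np.isnan(A[j])).sum()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(10, 80))
        coex = rho_matrix(_clr(A), min_shared=10)
        perm = rng.permutation(10)
        ids = [f"orf{i}" for i in perm]
        coex_p = rho_matrix(_clr(A[perm], ids=ids), min_shared=10)
        assert np.allclose(coex.rho.loc[ids, ids].to_numpy(),
                           coex_p.rho.to_numpy(), equal_nan=True)


def _block_coex(rng, n=200, n_groups=2, low=(0.0, 0.1), ref=(0.476, 0.15)):
    """rho matrix whose bins are N(low) except the ref x ref bin."""
    R = np.full((n, n), np.nan)
    me = pd.Series(np.arange(n, dtype=float),
                   index=[f"orf{i:03d}" for i in range(n)])
    half = n // n_groups
    iu, ju = np.triu_indices(n, k=1)
    vals = rng.normal(*low, iu.size)
    in_ref = (iu >= (n_groups - 1) * half) & (ju >= (n_groups - 1) * half)
    vals[in_ref] = rng.normal(*ref, in_ref.sum())
    R[iu, ju] = vals
    R[ju, iu] = vals
    np.fill_diagonal(R, 1.0)
    ids = me.index
    coex = CoexpressionMatrix(pd.DataFrame(R, index=ids, columns=ids),
                              pd.DataFrame(500, index=ids, columns=ids),
                              min_shared=10)
    return coex, me, half


class TestSpqn:
    def test_identity_when_bin_matches_reference(self):
        # bins (0,0) and (1,1) carry the same value multiset -> no change
        n = 40
        rng = np.random.default_rng(0)
        shared = rng.normal(size=190)
        R = np.full((n, n), np.nan)
        iu, ju = np.triu_indices(n, k=1)
        low = (iu < 20) & (ju < 20)
        hi = (iu >= 20) & (ju >= 20)
        mid = ~low & ~hi
        vals = np.empty(iu.size)
        vals[low] = shared
        vals[hi] = shared
        vals[mid] = rng.normal(0.3, 0.2, mid.sum())
        R[iu, ju] = vals
        R[ju, iu] = vals
        np.fill_diagonal(R, 1.0)
        ids = [f"o{i}" for i in range(n)]
        coex = CoexpressionMatrix(pd.DataFrame(R, index=ids, columns=ids),
                                  pd.DataFrame(500, index=ids, columns=ids))
        me = pd.Series(np.arange(n, dtype=float), index=ids)
        out = spqn_normalize(coex, me, SpqnConfig(n_groups=2))
        got = out.rho.to_numpy()[np.triu_indices(n, k=1)]
        assert np.nanmax(np.abs(got[low] - vals[low])) < 1e-6

    def test_low_bin_mapped_onto_reference(self):
        rng = np.random.default_rng(1)
        coex, me, half = _block_coex(rng)
        out = spqn_normalize(coex, me, SpqnConfig(n_groups=2))
        iu, ju = np.triu_indices(len(me), k=1)
        low_bin = (iu < half) & (ju < half)
        ref_bin = (iu >= half) & (ju >= half)
        before = coex.rho.to_numpy()[iu, ju]
        after = out.rho.to_numpy()[iu, ju]
        ks = sps.ks_2samp(after[low_bin], before[ref_bin]).statistic
        assert ks <= 0.05
        rank = sps.spearmanr(before[low_bin], after[low_bin]).statistic
        assert rank == pytest.approx(1.0)

    def test_missingness_and_symmetry_preserved(self):
        rng = np.random.default_rng(2)
        coex, me, _ = _block_coex(rng, n=60)
        R = coex.rho.to_numpy()
        R[2, 11] = R[11, 2] = np.nan
        out = spqn_normalize(coex, me, SpqnConfig(n_groups=3))
        O = out.rho.to_numpy()
        assert np.isnan(O[2, 11]) and np.isnan(O[11, 2])
        assert np.allclose(O, O.T, equal_nan=True)
        assert np.array_equal(np.isnan(O), np.isnan(R))


class TestThresholds:
    def test_percentile_quantile_arithmetic(self):
        n = 1001
        vals = np.concatenate([[1.0], np.arange(1, 1001, dtype=float)])
        # build a star-shaped matrix holding exactly the values 1..1000
        R = np.full((n, n), np.nan)
        R[0, 1:] = R[1:, 0] = vals[1:]
        np.fill_diagonal(R, 1.0)
        ids = [f"o{i}" for i in range(n)]
        coex = CoexpressionMatrix(pd.DataFrame(R, index=ids, columns=ids),
                                  pd.DataFrame(500, index=ids, columns=ids))
        thr = percentile_threshold(coex, top_fraction=0.002)
        assert thr.threshold == pytest.approx(998.002)
        assert thr.passes(vals[1:]).sum() == 2      # 999 and 1000

    def test_top_fraction_one_keeps_everything(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(10, 50))
        coex = rho_matrix(_clr(A), min_shared=10)
        thr = percentile_threshold(coex, top_fraction=1.0)
        v = coex.offdiag_values()
        assert thr.threshold == pytest.approx(v.min())
        # strict ">" leaves the minimum itself out
        assert thr.passes(v).sum() == (v > v.min()).sum()

    def test_coverage_order_statistic(self):
        m = np.array([0.99, 0.98, 0.97, 0.96, 0.95, 0.94, 0.93, 0.92,
                      0.91, 0.90])
        n = 11
        R = np.full((n, n), -1.0)
        R[0, 1:] = R[1:, 0] = m            # orf0 is everyone's best partner
        np.fill_diagonal(R, 1.0)
        ids = [f"o{i}" for i in range(n)]
        coex = CoexpressionMatrix(pd.DataFrame(R, index=ids, columns=ids),
                                  pd.DataFrame(500, index=ids, columns=ids))
        classes = pd.Series("canonical", index=ids)
        classes.iloc[0] = "noncanonical"   # 10 canonical ORFs with max = m
        thr = coverage_threshold(coex, classes, coverage=0.9)
        assert thr.threshold == pytest.approx(0.91)
        assert thr.coverage == pytest.approx(0.9)

    def test_coverage_one_takes_minimum(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(12, 60))
        coex = rho_matrix(_clr(A), min_shared=10)
        classes = pd.Series("canonical", index=coex.orf_ids)
        thr = coverage_threshold(coex, classes, coverage=1.0)
        R = coex.rho.to_numpy().copy()
        np.fill_diagonal(R, np.nan)
        assert thr.threshold == pytest.approx(np.nanmax(R, axis=1).min())
        assert thr.coverage == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_coverage_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(15, 80))
        coex = rho_matrix(_clr(A), min_shared=10)
        classes = pd.Series(rng.choice(["canonical", "noncanonical"], 15),
                            index=coex.orf_ids)
        if (classes == "canonical").sum() == 0:
            classes.iloc[0] = "canonical"
        target = 0.8
        thr = coverage_threshold(coex, classes, coverage=target)
        R = coex.rho.to_numpy().copy()
        np.fill_diagonal(R, np.nan)
        canon = (classes == "canonical").to_numpy()
        m = np.nanmax(R[canon], axis=1)
        # brute force: the largest candidate threshold reaching the target
        best = max((t for t in m if (m >= t).sum() / canon.sum() >= target),
                   default=None)
        assert thr.threshold == pytest.approx(best)
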