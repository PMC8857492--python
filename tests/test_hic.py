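"""Contact-matrix model: I/O, masking, balancing, normalization, SCC."""

import numpy as np
import pytest

from ifn3d import (
    ContactMatrix,
    expected_profile,
    ice_balance,
    log_ratio_map,
    mask_low_coverage,
    merge_matrices,
    observed_over_expected,
    read_matrix,
    scc,
    subsample_counts,
    write_matrix,
)
from ifn3d.hic import BalanceError

from conftest import decay_matrix, symmetric_poisson


class TestMatrixModel:
    def test_rejects_asymmetric_counts(self):
        with pytest.raises(ValueError, match="symmetric"):
            ContactMatrix("c", 10, np.array([[1.0, 2.0], [3.0, 1.0]]))

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            ContactMatrix("c", 10, np.array([[1.0, -2.0], [-2.0, 1.0]]))

    def test_total_counts_upper_triangle(self):
        m = ContactMatrix("c", 10, np.array([[1.0, 2.0], [2.0, 3.0]]))
        assert m.total == 6.0


class TestTsvRoundTrip:
    def test_write_read_identity(self, tmp_path, random_matrix):
        path = tmp_path / "m.tsv"
        write_matrix(random_matrix, path)
        back = read_matrix(path)
        assert back.chrom == random_matrix.chrom
        assert back.bin_size == random_matrix.bin_size
        np.testing.assert_array_equal(back.counts, random_matrix.counts)

    def test_upper_triangle_input_symmetrized(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("#chr1\t1000\t3\n0\t1\t5\n1\t2\t2\n")
        m = read_matrix(path)
        assert m.counts[1, 0] == 5 and m.counts[2, 1] == 2

    def test_out_of_range_bin_names_line(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("#chr1\t1000\t3\n0\t1\t5\n0\t7\t1\n")
        with pytest.raises(ValueError, match="line 3"):
            read_matrix(path)

    def test_conflicting_mirror_entries_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("#chr1\t1000\t3\n0\t1\t5\n1\t0\t6\n")
        with pytest.raises(ValueError, match="asymmetric"):
            read_matrix(path)

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("#chr1\t1000\t3\n0\t1\t-5\n")
        with pytest.raises(ValueError, match="negative"):
            read_matrix(path)


class TestMaskLowCoverage:
    def test_zero_row_masked(self):
        counts = np.full((4, 4), 2.0)
        counts[2, :] = 0
        counts[:, 2] = 0
        m = mask_low_coverage(ContactMatrix("c", 10, counts), 0.0)
        assert list(m.mask) == [False, False, True, False]

    def test_uniform_matrix_nothing_masked(self):
        m = mask_low_coverage(ContactMatrix("c", 10, np.full((5, 5), 3.0)), 0.0)
        assert not m.mask.any()

    def test_quantile_masks_low_tail(self):
        # 100 bins, one tenth at clearly low coverage; q = 0.1 masks ~them
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=(100, 100)).astype(float)
        base = np.triu(base) + np.triu(base, 1).T
        base[:10, :] *= 0.02
        base[:, :10] *= 0.02
        base = (base + base.T) / 2
        m = mask_low_coverage(ContactMatrix("c", 10, base), 0.1)
        marg = m.counts.sum(axis=0)
        thr = np.quantile(marg[marg > 0], 0.1)
        expected = (marg == 0) | (marg < thr)
        np.testing.assert_array_equal(m.mask, expected)
        assert m.mask[:10].all()


class TestIceBalance:
    def test_equal_row_sums_gives_equal_weights(self):
        m = ice_balance(ContactMatrix("c", 10, np.full((4, 4), 2.0)))
        w = m.weights
        assert np.allclose(w, w[0])

    def test_two_by_two_fixed_point(self):
        # independent fixed-point iteration oracle, run to 1e-12
        counts = np.array([[4.0, 2.0], [2.0, 1.0]])
        w = np.ones(2)
        for _ in range(10_000):
            s = (w[:, None] * w[None, :] * counts).sum(axis=1)
            if s.std() / s.mean() < 1e-12:
                break
            w /= s / s.mean()
        w /= np.sqrt(((w[:, None] * w[None, :] * counts).sum(axis=1)).mean())
        m = ice_balance(ContactMatrix("c", 10, counts), tol=1e-12)
        np.testing.assert_allclose(m.weights, w, rtol=1e-6)
        rows = m.balanced().sum(axis=1)
        assert rows.std() / rows.mean() < 1e-10

    def test_row_sum_cv_below_tol(self):
        m = ice_balance(mask_low_coverage(decay_matrix(60, seed=5), 0.0),
                        tol=1e-8)
        bal = m.balanced()
        valid = ~m.mask
        s = bal[np.ix_(valid, valid)].sum(axis=1)
        assert s.std() / s.mean() < 1e-8
        assert abs(s.mean() - 1.0) < 1e-9

    def test_masked_bin_has_undefined_weight(self):
        counts = np.full((4, 4), 2.0)
        counts[1, :] = 0
        counts[:, 1] = 0
        m = ice_balance(mask_low_coverage(ContactMatrix("c", 10, counts), 0.0))
        assert np.isnan(m.weights[1])
        assert np.isnan(m.balanced()[1, :]).all()

    def test_non_convergence_reports_cv(self):
        with pytest.raises(BalanceError, match="CV"):
            ice_balance(decay_matrix(40, seed=1), tol=1e-14, max_iter=2)


class TestExpected:
    def test_toeplitz_profile_exact(self):
        n = 8
        v = np.arange(1.0, n + 1)
        counts = v[np.abs(np.subtract.outer(np.arange(n), np.arange(n)))]
        E = expected_profile(ContactMatrix("c", 10, counts),
                             use_balanced=False)
        np.testing.assert_allclose(E, v)

    def test_matches_brute_force_enumeration(self, random_matrix):
        E = expected_profile(random_matrix, use_balanced=False)
        n = random_matrix.n_bins
        for d in range(n):
            vals = [random_matrix.counts[i, i + d] for i in range(n - d)]
            mirror = [random_matrix.counts[i + d, i] for i in range(n - d)]
            # full-matrix enumeration over |i-j| = d
            all_vals = vals if d == 0 else vals + mirror
            np.testing.assert_allclose(E[d], np.mean(all_vals))

    def test_single_unmasked_cell(self):
        counts = np.zeros((5, 5))
        counts[0, 3] = counts[3, 0] = 7.0
        m = ContactMatrix("c", 10, counts,
                          mask=np.array([False, True, True, False, True]))
        E = expected_profile(m, use_balanced=False)
        assert E[3] == 7.0


class TestObservedOverExpected:
    def test_toeplitz_gives_ones(self):
        n = 10
        v = np.linspace(2, 5, n)
        counts = v[np.abs(np.subtract.outer(np.arange(n), np.arange(n)))]
        oe = observed_over_expected(ContactMatrix("c", 10, counts),
                                    use_balanced=False)
        np.testing.assert_allclose(oe, 1.0)

    def test_diagonal_means_are_one(self, balanced_decay):
        oe = observed_over_expected(balanced_decay)
        for d in range(balanced_decay.n_bins):
            diag = np.diagonal(oe, d)
            if np.isfinite(diag).any():
                assert abs(np.nanmean(diag) - 1.0) < 1e-9


class TestMerge:
    def test_zero_matrix_is_identity(self, random_matrix):
        zero = ContactMatrix("chrT", random_matrix.bin_size,
                             np.zeros_like(random_matrix.counts))
        merged = merge_matrices([random_matrix, zero])
        np.testing.assert_array_equal(merged.counts, random_matrix.counts)

    def test_self_merge_doubles_and_conserves_total(self, random_matrix):
        merged = merge_matrices([random_matrix, random_matrix])
        np.testing.assert_array_equal(merged.counts, 2 * random_matrix.counts)
        assert merged.total == 2 * random_matrix.total

    def test_binning_mismatch_rejected(self, random_matrix):
        other = ContactMatrix("chrT", 999, random_matrix.counts)
        with pytest.raises(ValueError, match="binning"):
            merge_matrices([random_matrix, other])


class TestSubsample:
    def test_full_target_is_identity(self, random_matrix):
        out = subsample_counts(random_matrix, int(random_matrix.total), seed=0)
        np.testing.assert_array_equal(out.counts, random_matrix.counts)

    def test_zero_target_is_empty(self, random_matrix):
        out = subsample_counts(random_matrix, 0, seed=0)
        assert out.counts.sum() == 0

    def test_exact_total_and_symmetry(self, random_matrix):
        out = subsample_counts(random_matrix, 500, seed=3)
        assert out.total == 500
        np.testing.assert_array_equal(out.counts, out.counts.T)

    def test_target_above_total_rejected(self, random_matrix):
        with pytest.raises(ValueError, match="exceeds"):
            subsample_counts(random_matrix, int(random_matrix.total) + 1, 0)

    def test_cell_expectation_is_proportional_thinning(self):
        m = symmetric_poisson(8, 20.0, seed=11)
        total = m.total
        target = int(total // 2)
        cell = (1, 5)
        draws = [subsample_counts(m, target, seed=s).counts[cell]
                 for s in range(1000)]
        expect = m.counts[cell] * target / total
        p = m.counts[cell] / total
        se = np.sqrt(target * p * (1 - p) / 1000)
        assert abs(np.mean(draws) - expect) < 3 * se


class TestLogRatio:
    def test_identical_maps_give_zero(self, random_matrix):
        r = log_ratio_map(random_matrix, random_matrix, 1.0)
        np.testing.assert_allclose(r, 0.0)

    def test_scale_invariance(self, random_matrix):
        doubled = ContactMatrix("chrT", random_matrix.bin_size,
                                2 * random_matrix.counts)
        r = log_ratio_map(doubled, random_matrix, 1.0)
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_hand_computed_two_by_two(self):
        m1 = ContactMatrix("c", 10, np.array([[4.0, 2.0], [2.0, 0.0]]))
        m2 = ContactMatrix("c", 10, np.array([[1.0, 3.0], [3.0, 1.0]]))
        # scale = total2/total1 = 5/6
        s = 5.0 / 6.0
        expected = np.log2((m1.counts * s + 1) / (m2.counts + 1))
        np.testing.assert_allclose(log_ratio_map(m1, m2, 1.0), expected)


class TestSCC:
    def test_self_similarity_is_one(self, random_matrix):
        assert scc(random_matrix, random_matrix, h=1).scc == pytest.approx(1.0)

    def test_symmetry_in_arguments(self):
        a = symmetric_poisson(40, 10.0, seed=1)
        b = symmetric_poisson(40, 10.0, seed=2)
        assert scc(a, b, h=1).scc == pytest.approx(scc(b, a, h=1).scc)

    def test_independent_flat_law_draws_near_zero(self):
        vals = [scc(symmetric_poisson(60, 15.0, seed=s),
                    symmetric_poisson(60, 15.0, seed=1000 + s), h=1).scc
                for s in range(50)]
        assert abs(np.mean(vals)) < 0.05

    def test_monotone_degradation_with_noise(self):
        base = symmetric_poisson(60, 20.0, seed=42)
        rng = np.random.default_rng(0)
        vals = []
        for sd in (1.0, 5.0, 20.0):
            noise = rng.normal(0, sd, size=base.counts.shape)
            noise = np.triu(noise) + np.triu(noise, 1).T
            noisy = ContactMatrix("chrT", base.bin_size,
                                  np.clip(base.counts + noise, 0, None))
            vals.append(scc(base, noisy, h=1).scc)
        assert vals[0] > vals[1] > vals[2]

    def test_in_unit_interval(self):
        a = decay_matrix(50, seed=4)
        b = decay_matrix(50, seed=9)
        v = scc(a, b, h=1).scc
        assert -1.0 <= v <= 1.0

    def test_no_variance_raises(self):
        flat = ContactMatrix("c", 10, np.full((6, 6), 4.0))
        with pytest.raises(ValueError, match="variance"):
            scc(flat, flat, h=0, max_distance=50)
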