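"""Loop template scoring, detection, quantification and cluster stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ifn3d import (
    ContactMatrix,
    GenomeSpec,
    LoopSpec,
    PerturbationSpec,
    SyntheticHiCParams,
    classify_cluster_loops,
    detect_loops,
    gaussian_dot_kernel,
    ice_balance,
    loop_score_correlation,
    mask_low_coverage,
    quantify_loops,
    score_map,
    simulate_contact_pair,
)
from ifn3d.loops import LoopCall, LoopKernel, _log_oe, read_bedpe, write_bedpe
from ifn3d.intervals import GenomicInterval

from conftest import decay_matrix

BS = 10_000


def simulated_loop_matrix(seed, loops, depth=5e5, n=200):
    g = GenomeSpec(["chrT"], [n * BS], BS)
    params = SyntheticHiCParams(1.0, depth, 0.0, loops=loops, seed=seed)
    unt, _, _ = simulate_contact_pair(g, params, PerturbationSpec())
    return ice_balance(mask_low_coverage(unt["chrT"], 0.0))


class TestKernel:
    def test_standardized_and_center_enriched(self):
        k = gaussian_dot_kernel(9, 1.5)
        assert abs(k.values.mean()) < 1e-12
        assert k.values.std() == pytest.approx(1.0)
        border = np.concatenate([k.values[0], k.values[-1],
                                 k.values[:, 0], k.values[:, -1]])
        assert k.values[4, 4] > border.mean()

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            gaussian_dot_kernel(8)

    def test_unstandardized_template_rejected(self):
        with pytest.raises(ValueError, match="zero mean"):
            LoopKernel(np.ones((3, 3)))


class TestScoreMap:
    def test_score_equals_direct_pearson(self):
        m = simulated_loop_matrix(1, [LoopSpec("chrT", 60, 90, 5.0, 2.0)])
        kern = gaussian_dot_kernel(9, 1.5)
        scores = score_map(m, kern, min_dist=5 * BS, max_dist=2_000_000)
        L = _log_oe(m)
        for (i, j) in [(60, 90), (40, 70), (100, 140)]:
            win = L[i - 4:i + 5, j - 4:j + 5]
            expected = sps.pearsonr(kern.values.ravel(), win.ravel())[0]
            assert scores[i, j] == pytest.approx(expected, abs=1e-9)

    def test_affine_shifted_kernel_scores_one(self):
        # plant the kernel itself (affine-transformed) into a synthetic
        # log(1+O/E) map: Pearson correlation is affine-invariant
        n = 60
        kern = gaussian_dot_kernel(9, 1.5)
        L = np.zeros((n, n))
        i0, j0 = 20, 45
        L[i0 - 4:i0 + 5, j0 - 4:j0 + 5] = 0.3 * kern.values + 0.7
        from ifn3d.loops import _score_cells
        s = _score_cells(L, kern, (np.array([i0]), np.array([j0])))
        assert s[0] == pytest.approx(1.0)

    def test_flat_matrix_scores_undefined(self):
        n = 40
        counts = np.full((n, n), 5.0)
        m = ContactMatrix("chrT", BS, counts, weights=np.ones(n),
                          mask=np.zeros(n, bool))
        scores = score_map(m, gaussian_dot_kernel(9), 5 * BS, 300 * BS)
        assert np.isnan(scores).all()

    def test_invariant_to_count_scaling(self):
        m = simulated_loop_matrix(2, [LoopSpec("chrT", 50, 80, 5.0, 2.0)])
        kern = gaussian_dot_kernel(9, 1.5)
        s1 = score_map(m, kern, 5 * BS, 2_000_000)
        m2 = ice_balance(mask_low_coverage(
            ContactMatrix(m.chrom, m.bin_size, m.counts * 2.0), 0.0))
        s2 = score_map(m2, kern, 5 * BS, 2_000_000)
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_kernel_larger_than_matrix_rejected(self):
        m = simulated_loop_matrix(3, [], n=12)
        with pytest.raises(ValueError, match="kernel"):
            score_map(m, gaussian_dot_kernel(17), 0, 10_000_000)


class TestDetect:
    def test_threshold_filters_calls(self):
        scores = np.full((30, 30), np.nan)
        scores[5, 15] = 0.30
        scores[10, 25] = 0.40
        calls = detect_loops(scores, "chrT", BS, threshold=0.35)
        assert len(calls) == 1
        assert (calls[0].bin1, calls[0].bin2) == (10, 25)

    def test_close_maxima_suppressed_keeping_best(self):
        scores = np.full((30, 30), np.nan)
        scores[5, 15] = 0.50
        scores[5, 16] = 0.45
        calls = detect_loops(scores, "chrT", BS, 0.35, min_separation=3)
        assert len(calls) == 1 and calls[0].score == 0.50

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        scores = np.full((50, 50), np.nan)
        iu = np.triu_indices(50, k=3)
        scores[iu] = rng.uniform(-1, 1, size=iu[0].size)
        a = detect_loops(scores, "chrT", BS, 0.35)
        b = detect_loops(scores, "chrT", BS, 0.35)
        assert [(c.bin1, c.bin2, c.score) for c in a] == \
            [(c.bin1, c.bin2, c.score) for c in b]

    def test_injected_loops_recovered(self):
        rng = np.random.default_rng(99)
        wins = 0
        for seed in range(3):
            loops = []
            while len(loops) < 5:
                i = int(rng.integers(12, 130))
                j = i + int(rng.integers(15, 60))
                if j > 188:
                    continue
                if any(max(abs(i - l.bin1), abs(j - l.bin2)) < 10
                       for l in loops):
                    continue
                loops.append(LoopSpec("chrT", i, j, 5.0, 2.0))
            m = simulated_loop_matrix(seed, loops)
            scores = score_map(m, gaussian_dot_kernel(17), 5 * BS, 10_000_000)
            calls = detect_loops(scores, "chrT", BS, 0.35, min_separation=5)
            hits = sum(any(max(abs(c.bin1 - l.bin1), abs(c.bin2 - l.bin2)) <= 2
                           for c in calls) for l in loops)
            wins += hits == len(loops)
        assert wins >= 2


class TestQuantify:
    def test_identical_conditions_same_seed_identical_scores(self):
        loops = [LoopSpec("chrT", 40, 70, 5.0, 2.0)]
        m = simulated_loop_matrix(7, loops)
        raw = ContactMatrix(m.chrom, m.bin_size, m.counts)
        calls = [LoopCall("chrT", 40, 70, 1.0, BS)]
        tbl = quantify_loops(calls, {"a": raw, "b": raw.copy()},
                             gaussian_dot_kernel(9), seed=3, min_dist=5 * BS)
        # equal totals: subsampling is the identity, so scores match exactly
        assert tbl.loc["chrT:40-70", "a"] == tbl.loc["chrT:40-70", "b"]

    def test_intra_gain_raises_treated_scores(self):
        g = GenomeSpec(["chrT"], [200 * BS], BS)
        clusters = [GenomicInterval("chrT", 40 * BS, 90 * BS)]
        loops = [LoopSpec("chrT", 50, 70, 4.0, 2.0),
                 LoopSpec("chrT", 55, 80, 4.0, 2.0)]
        diffs = []
        for seed in range(3):
            params = SyntheticHiCParams(1.0, 5e5, 0.0, loops=loops, seed=seed)
            pert = PerturbationSpec(clusters=clusters, intra_gain=2.0)
            unt, tre, _ = simulate_contact_pair(g, params, pert)
            calls = [LoopCall("chrT", l.bin1, l.bin2, 1.0, BS) for l in loops]
            tbl = quantify_loops(calls, {"unt": unt["chrT"],
                                         "tre": tre["chrT"]},
                                 gaussian_dot_kernel(9), seed=seed,
                                 min_dist=5 * BS)
            diffs.append(tbl["tre"].mean() - tbl["unt"].mean())
        assert np.mean(diffs) > 0


class TestClusterClassification:
    def test_intra_inter_and_excluded(self):
        # 400-bp bins: anchor midpoints at bin*400+200
        cluster = GenomicInterval("chrT", 1000, 2000)
        intra = LoopCall("chrT", 3, 4, 0.4, 400)    # mids 1400, 1800: both in
        inter = LoopCall("chrT", 3, 12, 0.3, 400)   # 1400 in, 5000 out
        neither = LoopCall("chrT", 12, 15, 0.2, 400)
        stats = classify_cluster_loops([intra, inter, neither], [cluster],
                                       max_length=500_000)
        assert stats[0].intra_scores == [0.4]
        assert stats[0].inter_scores == [0.3]

    def test_median_ratio(self):
        cluster = GenomicInterval("chrT", 1000, 2000)
        intra = LoopCall("chrT", 2, 3, 0.4, 500)   # mids 1250, 1750: intra
        inter = LoopCall("chrT", 3, 9, 0.2, 500)   # 1750 in, 4750 out
        s = classify_cluster_loops([intra, inter], [cluster], 500_000)[0]
        assert s.ratio == pytest.approx(0.5)

    def test_long_loops_excluded(self):
        cluster = GenomicInterval("chrT", 0, 10_000)
        lp = LoopCall("chrT", 1, 900, 0.9, 1000)
        s = classify_cluster_loops([lp], [cluster], max_length=500_000)[0]
        assert not s.intra_scores and not s.inter_scores

    def test_bridging_two_clusters_excluded(self):
        c1 = GenomicInterval("chrT", 0, 5000)
        c2 = GenomicInterval("chrT", 20_000, 25_000)
        lp = LoopCall("chrT", 1, 21, 0.8, 1000)
        stats = classify_cluster_loops([lp], [c1, c2], 500_000)
        assert all(not s.intra_scores and not s.inter_scores for s in stats)

    def test_overlapping_clusters_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            classify_cluster_loops([], [GenomicInterval("chrT", 0, 100),
                                        GenomicInterval("chrT", 50, 150)],
                                   500_000)


class TestScoreCorrelation:
    def test_identical_tables(self):
        s = pd.Series([0.1, 0.5, 0.3, 0.9], index=list("abcd"))
        assert loop_score_correlation(s, s) == pytest.approx(1.0)

    def test_reversed_ranks(self):
        s = pd.Series([0.1, 0.5, 0.3, 0.9], index=list("abcd"))
        assert loop_score_correlation(s, -s) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(8)
        idx = [f"l{i}" for i in range(50)]
        a = pd.Series(rng.normal(size=50), index=idx)
        b = pd.Series(rng.normal(size=50), index=idx)
        ra = sps.rankdata(a.values)
        rb = sps.rankdata(b.values)
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert loop_score_correlation(a, b) == pytest.approx(oracle)

    def test_too_few_shared_scores_rejected(self):
        a = pd.Series([0.1, 0.2], index=["x", "y"])
        with pytest.raises(ValueError, match="at least 3"):
            loop_score_correlation(a, a)


class TestBedpe:
    def test_round_trip(self, tmp_path):
        calls = [LoopCall("chrT", 3, 9, 0.41, BS),
                 LoopCall("chrT", 12, 40, 0.87, BS)]
        path = tmp_path / "loops.bedpe"
        write_bedpe(calls, path)
        back = read_bedpe(path)
        assert [(c.bin1, c.bin2) for c in back] == [(3, 9), (12, 40)]
        assert back[0].score == pytest.approx(0.41)
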