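"""Reference experiments validating each analysis stage on synthetic data.

Every function here sets up a small, fully specified study — simulated
contact maps, peaks or differential tables with known ground truth — runs
the corresponding analysis through the public API, and returns summary
metrics (recovery rates, type-I error, test p-values). They serve both the
acceptance test-suite and the reproduction script, so the conditions are
fixed here in one place:

* compartment experiments: one 200-bin chromosome at 40 kb, checkerboard
  contrast c = 0.4 in ±1 blocks of 20 bins, 5x10^5 expected contacts —
  per-bin coverage comparable, after scale-down, to a deeply sequenced
  Hi-C library;
* loop experiments: one 200-250-bin chromosome at 10 kb, injected Gaussian
  dots (enrichment 5, sd 2 bins), 5x10^5 contacts;
* null-calibration experiments run many reduced-size replicates (smaller
  depth/bins) so that 400 repetitions stay cheap.
"""

from __future__ import annotations

import numpy as np

from .compartments import (
    compute_compartment_track,
    delta_pc1_regions,
    rank_sum_test,
    saddle_strength,
)
from .hic import (
    BinTrack,
    ContactMatrix,
    ice_balance,
    mask_low_coverage,
    merge_matrices,
    observed_over_expected,
    scc,
)
from .integration import ContingencyTable2x2, chi_square_2x2
from .intervals import GenomicInterval
from .loops import (
    LoopCall,
    classify_cluster_loops,
    detect_loops,
    gaussian_dot_kernel,
    quantify_loops,
    score_map,
)
from .reginter import (
    build_peak_pairs,
    paired_enrichment_test,
    select_regulatory_peaks,
)
from .simulate import (
    GenomeSpec,
    LoopSpec,
    PerturbationSpec,
    SyntheticHiCParams,
    simulate_contact_pair,
    simulate_differential_tables,
    simulate_gene_truth,
    simulate_peaks,
)
from .integration import (
    classify_accessibility_dependence,
    classify_type_specific,
    select_induced_groups,
)
from .simulate import peak_gene_map

# --------------------------------------------------------------- conditions

COMP_BS = 40_000
COMP_BINS = 200
COMP_DEPTH = 5e5
COMP_CONTRAST = 0.4
COMP_BLOCK = 20
# clusters inside A (+1) blocks, 1 Mb (25-bin) controls on-chromosome
COMP_CLUSTERS = [(64, 74), (104, 114), (144, 154)]

LOOP_BS = 10_000
LOOP_DEPTH = 5e5


def _prep(m: ContactMatrix, q: float = 0.02) -> ContactMatrix:
    return ice_balance(mask_low_coverage(m, q))


def _comp_setup():
    genome = GenomeSpec(["chrC"], [COMP_BINS * COMP_BS], COMP_BS)
    clusters = [GenomicInterval("chrC", a * COMP_BS, b * COMP_BS,
                                name=f"cluster{i}")
                for i, (a, b) in enumerate(COMP_CLUSTERS)]
    return genome, clusters


# ------------------------------------------------------------- experiments

def chi_square_worked_example() -> dict:
    """Chi-squared on the published ISGF3-dependence contingency counts.

    680 loci gained accessibility on type I IFN, 472 of them IRF9-dependent;
    457 gained on type II IFN, 153 IRF9-dependent.
    """
    table = ContingencyTable2x2(
        np.array([[472, 680 - 472], [153, 457 - 153]]),
        ("ifn_i", "ifn_gamma"), ("isgf3_dependent", "isgf3_independent"))
    chi2, p = chi_square_2x2(table)
    return {"chi2": chi2, "p": p, "n": int(table.counts.sum())}


def compartment_sign_recovery(seed: int, n_seeds: int = 20) -> dict:
    """Fraction of unmasked bins whose phased PC1 sign matches truth."""
    genome, _ = _comp_setup()
    rates = []
    for k in range(n_seeds):
        params = SyntheticHiCParams(1.0, COMP_DEPTH, COMP_CONTRAST,
                                    block_width=COMP_BLOCK, seed=seed + k)
        unt, _, truth = simulate_contact_pair(genome, params,
                                              PerturbationSpec())
        m = _prep(unt["chrC"])
        act = BinTrack("chrC", COMP_BS,
                       truth.compartment_labels["chrC"].astype(float))
        res = compute_compartment_track(m, act)
        valid = ~m.mask
        rates.append(float(np.mean(
            np.sign(res.pc1.values[valid])
            == truth.compartment_labels["chrC"][valid])))
    return {"rate": float(np.mean(rates)), "n": n_seeds * COMP_BINS}


def delta_pc1_direction(seed: int, n_seeds: int = 20,
                        comp_gain: float = 1.5) -> dict:
    """Fraction of perturbed clusters whose mean ΔPC1 beats both controls."""
    genome, clusters = _comp_setup()
    wins = tot = 0
    for k in range(n_seeds):
        params = SyntheticHiCParams(1.0, COMP_DEPTH, COMP_CONTRAST,
                                    block_width=COMP_BLOCK, seed=seed + k)
        pert = PerturbationSpec(clusters=clusters, comp_gain=comp_gain)
        unt, tre, truth = simulate_contact_pair(genome, params, pert)
        act = BinTrack("chrC", COMP_BS,
                       truth.compartment_labels["chrC"].astype(float))
        pu = compute_compartment_track(_prep(unt["chrC"]), act).pc1
        pt = compute_compartment_track(_prep(tre["chrC"]), act).pc1
        for s in delta_pc1_regions(pt, pu, clusters):
            tot += 1
            wins += bool(s.mean > s.control_up and s.mean > s.control_down)
    return {"rate": wins / tot, "n": tot}


def delta_pc1_null_type1(seed: int, n_reps: int = 400) -> dict:
    """Type-I error of the cluster-vs-control rank-sum test at alpha=0.05.

    Reduced replicate size: 140 bins, depth 2x10^5, six 5-bin regions.
    """
    bs = COMP_BS
    genome = GenomeSpec(["chrC"], [140 * bs], bs)
    clusters = [GenomicInterval("chrC", s0 * bs, (s0 + 5) * bs)
                for s0 in (30, 45, 60, 75, 90, 105)]
    rej = 0
    for k in range(n_reps):
        params = SyntheticHiCParams(1.0, 2e5, COMP_CONTRAST,
                                    block_width=COMP_BLOCK,
                                    seed=seed + 1000 + k)
        unt, tre, truth = simulate_contact_pair(
            genome, params, PerturbationSpec(clusters=clusters))
        act = BinTrack("chrC", bs,
                       truth.compartment_labels["chrC"].astype(float))
        pu = compute_compartment_track(_prep(unt["chrC"]), act).pc1
        pt = compute_compartment_track(_prep(tre["chrC"]), act).pc1
        stats = delta_pc1_regions(pt, pu, clusters)
        cl = [s.mean for s in stats if np.isfinite(s.mean)]
        ct = [v for s in stats
              for v, ok in ((s.control_up, s.control_up_valid),
                            (s.control_down, s.control_down_valid))
              if ok and np.isfinite(v)]
        rej += bool(rank_sum_test(cl, ct).pvalue < 0.05)
    return {"rate": rej / n_reps, "n": n_reps}


def saddle_contrast_curve(seed: int, contrasts=(0.1, 0.2, 0.4),
                          n_seeds: int = 10) -> dict:
    """Mean compartmentalization strength at each checkerboard contrast."""
    genome, _ = _comp_setup()
    means = []
    for c in contrasts:
        vals = []
        for k in range(n_seeds):
            params = SyntheticHiCParams(1.0, COMP_DEPTH, c,
                                        block_width=COMP_BLOCK, seed=seed + k)
            unt, _, truth = simulate_contact_pair(genome, params,
                                                  PerturbationSpec())
            m = _prep(unt["chrC"])
            act = BinTrack("chrC", COMP_BS,
                           truth.compartment_labels["chrC"].astype(float))
            pc1 = compute_compartment_track(m, act).pc1
            vals.append(saddle_strength(m, pc1, 10, 0.2).strength)
        means.append(float(np.mean(vals)))
    return {"strengths": means, "contrasts": list(contrasts),
            "n": n_seeds * len(contrasts)}


def _random_loops(rng, n_loops=6, lo=12, hi=188, min_sep=10,
                  strength=5.0, width=2.0):
    loops = []
    while len(loops) < n_loops:
        i = int(rng.integers(lo, hi - 15))
        j = i + int(rng.integers(15, 60))
        if j > hi:
            continue
        if any(max(abs(i - l.bin1), abs(j - l.bin2)) < min_sep
               for l in loops):
            continue
        loops.append(LoopSpec("chrL", i, j, strength, width))
    return loops


def loop_detection_performance(seed: int, n_seeds: int = 10) -> dict:
    """Recall/precision of injected-loop recovery at 2-bin tolerance."""
    genome = GenomeSpec(["chrL"], [200 * LOOP_BS], LOOP_BS)
    kern = gaussian_dot_kernel(17, 1.5)
    recalls, precisions = [], []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + 500 + k)
        loops = _random_loops(rng)
        params = SyntheticHiCParams(1.0, LOOP_DEPTH, 0.0, loops=loops,
                                    seed=seed + k)
        unt, _, _ = simulate_contact_pair(genome, params, PerturbationSpec())
        m = _prep(unt["chrL"], 0.0)
        scores = score_map(m, kern, 5 * LOOP_BS, 10_000_000)
        calls = detect_loops(scores, "chrL", LOOP_BS, 0.35, min_separation=5)
        hit = sum(any(max(abs(c.bin1 - l.bin1), abs(c.bin2 - l.bin2)) <= 2
                      for c in calls) for l in loops)
        tp = sum(any(max(abs(c.bin1 - l.bin1), abs(c.bin2 - l.bin2)) <= 2
                     for l in loops) for c in calls)
        recalls.append(hit / len(loops))
        precisions.append(tp / len(calls) if calls else 1.0)
    return {"recall": float(np.mean(recalls)),
            "precision": float(np.mean(precisions)), "n": n_seeds}


def loop_false_positive_rate(seed: int, n_seeds: int = 10) -> dict:
    """Calls per scanned cell on loop-free decay-only matrices."""
    genome = GenomeSpec(["chrL"], [200 * LOOP_BS], LOOP_BS)
    kern = gaussian_dot_kernel(17, 1.5)
    fps = cells = 0
    for k in range(n_seeds):
        params = SyntheticHiCParams(1.0, LOOP_DEPTH, 0.0, seed=seed + 900 + k)
        unt, _, _ = simulate_contact_pair(genome, params, PerturbationSpec())
        m = _prep(unt["chrL"], 0.0)
        scores = score_map(m, kern, 5 * LOOP_BS, 10_000_000)
        calls = detect_loops(scores, "chrL", LOOP_BS, 0.35, min_separation=5)
        fps += len(calls)
        cells += int(np.isfinite(scores).sum())
    return {"rate_per_cell": fps / cells, "n_calls": fps, "n": cells}


def _cluster_loop_setup():
    genome = GenomeSpec(["chrL"], [250 * LOOP_BS], LOOP_BS)
    clusters = [GenomicInterval("chrL", 40 * LOOP_BS, 80 * LOOP_BS,
                                name="cl1"),
                GenomicInterval("chrL", 150 * LOOP_BS, 190 * LOOP_BS,
                                name="cl2")]
    loops = []
    for c0 in (40, 150):
        loops += [LoopSpec("chrL", c0 + 5, c0 + 20, 5.0, 2.0),
                  LoopSpec("chrL", c0 + 12, c0 + 35, 5.0, 2.0),
                  LoopSpec("chrL", c0 + 22, c0 + 38, 5.0, 2.0),
                  LoopSpec("chrL", c0 + 10, c0 + 60, 5.0, 2.0),
                  LoopSpec("chrL", c0 - 25, c0 + 15, 5.0, 2.0),
                  LoopSpec("chrL", c0 + 30, c0 + 75, 5.0, 2.0)]
    return genome, clusters, loops


def ratio_shift(seed: int, n_seeds: int = 10, intra_gain: float = 2.0,
                inter_gain: float = 0.5) -> dict:
    """Fraction of clusters where treated inter/intra ratio < untreated.

    Full path: fusion map detection, equal-coverage quantification,
    cluster classification, median ratio per condition.
    """
    genome, clusters, loops = _cluster_loop_setup()
    kern = gaussian_dot_kernel(17, 1.5)
    ok = tot = 0
    for k in range(n_seeds):
        params = SyntheticHiCParams(1.0, LOOP_DEPTH, 0.0, loops=loops,
                                    seed=seed + k)
        pert = PerturbationSpec(clusters=clusters, intra_gain=intra_gain,
                                inter_gain=inter_gain)
        unt, tre, _ = simulate_contact_pair(genome, params, pert)
        fusion = _prep(merge_matrices([unt["chrL"], tre["chrL"]]), 0.0)
        scores = score_map(fusion, kern, 5 * LOOP_BS, 10_000_000)
        calls = detect_loops(scores, "chrL", LOOP_BS, 0.35, min_separation=5)
        tbl = quantify_loops(calls, {"unt": unt["chrL"], "tre": tre["chrL"]},
                             kern, seed=seed + 5000 + k,
                             min_dist=5 * LOOP_BS)
        ratios = {}
        for cond in ("unt", "tre"):
            scored = [LoopCall(c.chrom, c.bin1, c.bin2,
                               float(tbl.loc[c.id, cond]), c.resolution)
                      for c in calls if np.isfinite(tbl.loc[c.id, cond])]
            stats = classify_cluster_loops(scored, clusters, 500_000)
            ratios[cond] = {s.cluster.name: s.ratio for s in stats}
        for name in ratios["unt"]:
            if np.isfinite(ratios["unt"][name]) and \
                    np.isfinite(ratios["tre"][name]):
                tot += 1
                ok += bool(ratios["tre"][name] < ratios["unt"][name])
    return {"rate": ok / tot if tot else float("nan"), "n": tot}


def control_pair_null_type1(seed: int, n_reps: int = 400) -> dict:
    """Type-I error of the paired signed-rank test at alpha=0.05.

    Loop-free, compartment-free 150-bin matrices at depth 5x10^4 with
    8 randomly placed peaks in one 70-bin region.
    """
    genome = GenomeSpec(["chrR"], [150 * LOOP_BS], LOOP_BS)
    cluster = [GenomicInterval("chrR", 40 * LOOP_BS, 110 * LOOP_BS,
                               name="cl")]
    rej = 0
    for k in range(n_reps):
        params = SyntheticHiCParams(1.0, 5e4, 0.0, seed=seed + 10_000 + k)
        unt, _, _ = simulate_contact_pair(genome, params, PerturbationSpec())
        m = _prep(unt["chrR"], 0.0)
        peaks = simulate_peaks(genome, cluster, [], 8, seed=seed + 20_000 + k)
        pairs = build_peak_pairs(select_regulatory_peaks(peaks, cluster, []),
                                 m)
        rej += bool(paired_enrichment_test(pairs).pvalue < 0.05)
    return {"rate": rej / n_reps, "n": n_reps}


def control_pair_power(seed: int, n_seeds: int = 10,
                       intra_gain: float = 2.0) -> dict:
    """Rejection rate when peak pairs sit on real (gained) loops."""
    genome = GenomeSpec(["chrR"], [150 * LOOP_BS], LOOP_BS)
    cluster = [GenomicInterval("chrR", 40 * LOOP_BS, 110 * LOOP_BS,
                               name="cl")]
    sig = 0
    for k in range(n_seeds):
        peaks = simulate_peaks(genome, cluster, [], 6, seed=seed + 300 + k)
        pk_bins = sorted(p.interval.midpoint // LOOP_BS for p in peaks)
        loops = [LoopSpec("chrR", a, b, 3.0, 1.5)
                 for i, a in enumerate(pk_bins) for b in pk_bins[i + 1:]
                 if b - a >= 5]
        params = SyntheticHiCParams(1.0, LOOP_DEPTH, 0.0, loops=loops,
                                    seed=seed + k)
        pert = PerturbationSpec(clusters=cluster, intra_gain=intra_gain)
        _, tre, _ = simulate_contact_pair(genome, params, pert)
        m = _prep(tre["chrR"], 0.0)
        pairs = build_peak_pairs(select_regulatory_peaks(peaks, cluster, []),
                                 m)
        sig += bool(paired_enrichment_test(pairs).pvalue < 0.05)
    return {"significant": sig, "n": n_seeds, "rate": sig / n_seeds}


def exact_small_sample_stats(seed: int) -> dict:
    """Closed-form statistical identities on tiny inputs."""
    rs = rank_sum_test([1, 2, 3], [4, 5, 6])
    from .reginter import ControlSpec, Peak, PeakPair

    iv = GenomicInterval("c", 0, 100)
    ctrl = (ControlSpec(iv, iv, True), ControlSpec(iv, iv, True))
    pairs = [PeakPair(Peak(iv, "a"), Peak(GenomicInterval("c", 200, 300), "b"),
                      1.0 + 0.1 * i, ctrl, (0.5, 0.4)) for i in range(10)]
    sr = paired_enrichment_test(pairs)
    rng = np.random.default_rng(seed)
    raw = rng.poisson(10.0, size=(40, 40)).astype(float)
    m = ContactMatrix("c", 10_000, np.triu(raw) + np.triu(raw, 1).T)
    scc_self = scc(m, m, h=1).scc
    mb = ice_balance(mask_low_coverage(m, 0.0), tol=1e-8)
    oe = observed_over_expected(mb)
    dev = max(abs(np.nanmean(np.diagonal(oe, d)) - 1.0)
              for d in range(m.n_bins)
              if np.isfinite(np.diagonal(oe, d)).any())
    bal = mb.balanced()
    valid = ~mb.mask
    rows = bal[np.ix_(valid, valid)].sum(axis=1)
    return {"ranksum_p": rs.pvalue, "signed_rank_p": sr.pvalue,
            "scc_self": scc_self, "oe_diag_dev": float(dev),
            "ice_cv": float(rows.std() / rows.mean()), "n": 10}


def classification_recovery(seed: int, n_genes: int = 600,
                            noise_sd: float = 0.1) -> dict:
    """Agreement of every classification rule with synthetic truth labels."""
    truth = simulate_gene_truth(n_genes, seed=seed)
    tabs = simulate_differential_tables(truth, noise_sd=noise_sd,
                                        seed=seed + 1)
    cls = classify_type_specific(tabs["rna_a"], tabs["rna_b"])["class"]

    def want_type(t):
        if t.induced_a and t.induced_b:
            return "shared"
        if t.induced_a:
            return "a_specific"
        if t.induced_b:
            return "b_specific"
        return "none"

    type_agree = float(np.mean([cls[g] == want_type(t)
                                for g, t in truth.items()]))
    groups = select_induced_groups(tabs["rna_a"], "strata")
    strata_checks = []
    for g, t in truth.items():
        if t.induced_a and t.stratum == "extreme":
            strata_checks.append(g in groups["extreme"])
        elif t.induced_a and t.stratum == "moderate":
            strata_checks.append(g in groups["moderate"])
    strata_agree = float(np.mean(strata_checks))
    labels, _ = classify_accessibility_dependence(
        {"ifn_a": tabs["rna_a"], "ifn_b": tabs["rna_b"]},
        {"ifn_a": tabs["atac_a"], "ifn_b": tabs["atac_b"]},
        {"ifn_a": tabs["atac_ko_a"], "ifn_b": tabs["atac_ko_b"]},
        peak_gene_map(truth),
        rna_knockout=tabs["rna_ko"], atac_knockout_homeo=tabs["atac_ko"])
    cat = labels.set_index(["gene", "ifn_type"])["category"]

    def want_cat(t, ty):
        ind = t.induced_a if ty == "ifn_a" else t.induced_b
        dep = t.isgf3_dependent_a if ty == "ifn_a" else t.isgf3_dependent_b
        if ind and dep:
            return "induced_isgf3_dependent"
        if ind:
            return "induced_isgf3_independent"
        if t.homeostatic_dependent:
            return "homeostatic_isgf3_dependent"
        return "none"

    cat_agree = float(np.mean([cat[(g, ty)] == want_cat(t, ty)
                               for g, t in truth.items()
                               for ty in ("ifn_a", "ifn_b")]))
    return {"type_specific": type_agree, "strata": strata_agree,
            "four_category": cat_agree, "n": n_genes}
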