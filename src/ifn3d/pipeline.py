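"""End-to-end synthetic runs with a single config, fixed seeds and a manifest.

One call simulates a paired-condition dataset and pushes it through every
analysis stage — replicate similarity, compartments and ΔPC1, loop
detection/quantification and cluster ratios, regulatory control-pair
enrichment, and RNA/ATAC classification — writing plain-text outputs plus
a machine-readable manifest with parameter values and output checksums.
Identical config and seed give identical checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import (
    BinTrack,
    GenomeSpec,
    LoopSpec,
    PerturbationSpec,
    SyntheticHiCParams,
    compute_compartment_track,
    delta_pc1_regions,
    detect_loops,
    gaussian_dot_kernel,
    ice_balance,
    mask_low_coverage,
    merge_matrices,
    quantify_loops,
    rank_sum_test,
    saddle_strength,
    scc,
    score_map,
    simulate_contact_pair,
    simulate_differential_tables,
    simulate_gene_truth,
    simulate_peaks,
    write_matrix,
)
from .hic import write_bedgraph
from .integration import (
    chi_square_2x2,
    classify_accessibility_dependence,
    classify_type_specific,
)
from .intervals import GenomicInterval
from .loops import LoopCall, classify_cluster_loops, loop_score_correlation, write_bedpe
from .reginter import build_peak_pairs, paired_enrichment_test, select_regulatory_peaks
from .simulate import peak_gene_map

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "compartments": {
        "bin_size": 40_000,           # ΔPC1 resolution
        "n_bins": 200,
        "depth": 5e5,
        "compartment_contrast": 0.4,
        "block_width": 20,
        "comp_gain": 1.5,
        "cluster_starts": [64, 104, 144],   # bins; inside A (+1) blocks
        "cluster_len": 10,                  # bins
        "control_offset": 1_000_000,
        "saddle_quantiles": 10,
        "corner_fraction": 0.2,
        "mask_quantile": 0.02,
    },
    "loops": {
        "bin_size": 10_000,
        "n_bins": 250,
        "depth": 5e5,
        "loop_strength": 5.0,
        "loop_width": 2.0,
        "intra_gain": 2.0,
        "inter_gain": 0.5,
        "threshold": 0.35,
        "min_separation": 5,
        "min_dist": 50_000,
        "max_dist": 10_000_000,
        "max_length": 500_000,
        "kernel_size": 17,
        "kernel_sigma": 1.5,
        "scc_h": 1,
        "scc_max_dist": 1_000_000,
    },
    "reginter": {
        "n_peaks_per_cluster": 6,
        "peak_loop_strength": 3.0,
        "peak_loop_width": 1.5,
    },
    "integration": {
        "n_genes": 600,
        "noise_sd": 0.5,
        "fc_thresh": 1.0,
        "padj_thresh": 0.05,
        "top_n": 200,
    },
}


def _merge_config(user: dict[str, Any] | None) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_compartments(cfg: dict, seed: int, outdir: Path) -> dict:
    c = cfg["compartments"]
    bs = c["bin_size"]
    genome = GenomeSpec(["chrC"], [c["n_bins"] * bs], bs)
    clusters = [GenomicInterval("chrC", s * bs, (s + c["cluster_len"]) * bs,
                                name=f"cluster{k}")
                for k, s in enumerate(c["cluster_starts"])]
    params = SyntheticHiCParams(1.0, c["depth"], c["compartment_contrast"],
                                block_width=c["block_width"], seed=seed)
    pert = PerturbationSpec(clusters=clusters, comp_gain=c["comp_gain"])
    unt, tre, truth = simulate_contact_pair(genome, params, pert)
    act = BinTrack("chrC", bs, truth.compartment_labels["chrC"].astype(float))
    results = {}
    pcs = {}
    for cond, mats in (("untreated", unt), ("treated", tre)):
        m = ice_balance(mask_low_coverage(mats["chrC"], c["mask_quantile"]))
        comp = compute_compartment_track(m, act)
        pcs[cond] = comp.pc1
        write_bedgraph(comp.pc1, outdir / f"pc1_{cond}.bedgraph")
        sad = saddle_strength(m, comp.pc1, c["saddle_quantiles"],
                              c["corner_fraction"])
        results[f"saddle_strength_{cond}"] = sad.strength
        results[f"phase_correlation_{cond}"] = comp.phase_correlation
    stats = delta_pc1_regions(pcs["treated"], pcs["untreated"], clusters,
                              c["control_offset"])
    rows = [(s.region.name, s.mean, s.control_up, s.control_down)
            for s in stats]
    pd.DataFrame(rows, columns=["region", "mean", "control_up",
                                "control_down"]) \
        .to_csv(outdir / "delta_pc1.tsv", sep="\t", index=False)
    cl_vals = [s.mean for s in stats if np.isfinite(s.mean)]
    ct_vals = [v for s in stats
               for v, ok in ((s.control_up, s.control_up_valid),
                             (s.control_down, s.control_down_valid))
               if ok and np.isfinite(v)]
    test = rank_sum_test(cl_vals, ct_vals)
    results["delta_pc1_ranksum_p"] = test.pvalue
    results["n_clusters_above_controls"] = int(sum(
        s.mean > s.control_up and s.mean > s.control_down for s in stats))
    results["n_clusters"] = len(stats)
    return results


def _stage_loops(cfg: dict, seed: int, outdir: Path) -> dict:
    c = cfg["loops"]
    bs = c["bin_size"]
    genome = GenomeSpec(["chrL"], [c["n_bins"] * bs], bs)
    clusters = [GenomicInterval("chrL", 40 * bs, 80 * bs, name="cl1"),
                GenomicInterval("chrL", 150 * bs, 190 * bs, name="cl2")]
    loops = []
    for c0 in (40, 150):
        loops += [LoopSpec("chrL", c0 + 5, c0 + 20, c["loop_strength"], c["loop_width"]),
                  LoopSpec("chrL", c0 + 12, c0 + 35, c["loop_strength"], c["loop_width"]),
                  LoopSpec("chrL", c0 + 22, c0 + 38, c["loop_strength"], c["loop_width"]),
                  LoopSpec("chrL", c0 + 10, c0 + 60, c["loop_strength"], c["loop_width"]),
                  LoopSpec("chrL", c0 - 25, c0 + 15, c["loop_strength"], c["loop_width"]),
                  LoopSpec("chrL", c0 + 30, c0 + 75, c["loop_strength"], c["loop_width"])]
    params = SyntheticHiCParams(1.0, c["depth"], 0.0, loops=loops, seed=seed)
    pert = PerturbationSpec(clusters=clusters, intra_gain=c["intra_gain"],
                            inter_gain=c["inter_gain"])
    unt, tre, truth = simulate_contact_pair(genome, params, pert)
    results = {"scc_between_conditions": scc(unt["chrL"], tre["chrL"],
                                             c["scc_h"], c["scc_max_dist"]).scc}
    fusion = merge_matrices([unt["chrL"], tre["chrL"]])
    write_matrix(fusion, outdir / "fusion_map.tsv")
    kern = gaussian_dot_kernel(c["kernel_size"], c["kernel_sigma"])
    mf = ice_balance(mask_low_coverage(fusion, 0.0))
    sf = score_map(mf, kern, c["min_dist"], c["max_dist"])
    calls = detect_loops(sf, "chrL", bs, c["threshold"], c["min_separation"])
    write_bedpe(calls, outdir / "loops.bedpe")
    results["n_loops_detected"] = len(calls)
    tbl = quantify_loops(calls, {"untreated": unt["chrL"], "treated": tre["chrL"]},
                         kern, seed=seed + 101, min_dist=c["min_dist"],
                         max_dist=c["max_dist"])
    tbl.to_csv(outdir / "loop_scores.tsv", sep="\t")
    ratios = {}
    for cond in tbl.columns:
        scored = [LoopCall(lc.chrom, lc.bin1, lc.bin2, tbl.loc[lc.id, cond],
                           lc.resolution)
                  for lc in calls if np.isfinite(tbl.loc[lc.id, cond])]
        stats = classify_cluster_loops(scored, clusters, c["max_length"])
        ratios[cond] = {s.cluster.name: s.ratio for s in stats}
    results["inter_intra_ratio"] = ratios
    if len(tbl) >= 3:
        results["loop_score_spearman"] = loop_score_correlation(
            tbl["untreated"], tbl["treated"])
    return results


def _stage_reginter(cfg: dict, seed: int, outdir: Path) -> dict:
    c = cfg["loops"]
    r = cfg["reginter"]
    bs = c["bin_size"]
    genome = GenomeSpec(["chrR"], [150 * bs], bs)
    cluster = [GenomicInterval("chrR", 40 * bs, 110 * bs, name="cl")]
    peaks = simulate_peaks(genome, cluster, [], r["n_peaks_per_cluster"],
                           seed=seed + 7)
    pk_bins = sorted(p.interval.midpoint // bs for p in peaks)
    loops = [LoopSpec("chrR", a, b, r["peak_loop_strength"],
                      r["peak_loop_width"])
             for i, a in enumerate(pk_bins) for b in pk_bins[i + 1:]
             if b - a >= 5]
    params = SyntheticHiCParams(1.0, c["depth"], 0.0, loops=loops, seed=seed)
    pert = PerturbationSpec(clusters=cluster, intra_gain=c["intra_gain"])
    _, tre, _ = simulate_contact_pair(genome, params, pert)
    m = ice_balance(mask_low_coverage(tre["chrR"], 0.0))
    sel = select_regulatory_peaks(peaks, cluster, [])
    pairs = build_peak_pairs(sel, m)
    res = paired_enrichment_test(pairs)
    rows = [(p.a.id, p.b.id, p.a.cluster_id, p.real_strength,
             p.control_strength,
             sum(cs.valid for cs in p.controls)) for p in pairs]
    pd.DataFrame(rows, columns=["peak_a", "peak_b", "cluster", "real",
                                "control", "n_valid_controls"]) \
        .to_csv(outdir / "peak_pairs.tsv", sep="\t", index=False)
    return {"n_pairs": res.n, "signed_rank_p": res.pvalue,
            "median_real": res.median_real,
            "median_control": res.median_control}


def _stage_integration(cfg: dict, seed: int, outdir: Path) -> dict:
    c = cfg["integration"]
    truth = simulate_gene_truth(c["n_genes"], seed=seed + 11)
    tables = simulate_differential_tables(truth, noise_sd=c["noise_sd"],
                                          seed=seed + 13)
    cls = classify_type_specific(tables["rna_a"], tables["rna_b"],
                                 c["fc_thresh"], c["padj_thresh"])
    cls.to_csv(outdir / "type_specific.tsv", sep="\t")
    labels, table = classify_accessibility_dependence(
        {"ifn_a": tables["rna_a"], "ifn_b": tables["rna_b"]},
        {"ifn_a": tables["atac_a"], "ifn_b": tables["atac_b"]},
        {"ifn_a": tables["atac_ko_a"], "ifn_b": tables["atac_ko_b"]},
        peak_gene_map(truth),
        rna_knockout=tables["rna_ko"], atac_knockout_homeo=tables["atac_ko"],
        fc_thresh=c["fc_thresh"], padj_thresh=c["padj_thresh"])
    labels.to_csv(outdir / "accessibility_dependence.tsv", sep="\t",
                  index=False)
    chi2, p = chi_square_2x2(table)
    (outdir / "contingency.json").write_text(json.dumps({
        "rows": table.row_labels, "cols": table.col_labels,
        "counts": table.counts.tolist(), "chi2": chi2, "p": p}, indent=1))
    return {"contingency": table.counts.tolist(), "chi2": chi2,
            "chi2_p": p,
            "class_counts": cls["class"].value_counts().to_dict()}


def run_pipeline(config: dict[str, Any] | None = None,
                 outdir: str | Path = "ifn3d_run") -> dict[str, Any]:
    """Run every analysis stage on freshly simulated data.

    Returns the per-stage result summary; writes outputs and
    ``manifest.json`` (config, per-stage results, output checksums) to
    ``outdir``. Any stage failure aborts with the stage name; outputs
    written so far are retained.
    """
    cfg = _merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    results: dict[str, Any] = {}
    stages = [("compartments", _stage_compartments),
              ("loops", _stage_loops),
              ("reginter", _stage_reginter),
              ("integration", _stage_integration)]
    for name, fn in stages:
        try:
            results[name] = fn(cfg, seed, outdir)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
    checksums = {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                 if p.is_file() and p.name != "manifest.json"}
    manifest = {"config": cfg, "results": results, "checksums": checksums}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     default=str))
    return results
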