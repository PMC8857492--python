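"""Chromatin loops: detect on a fusion map, quantify per condition.

Simulates paired 10-kb maps where stimulation doubles intra-cluster loop
enrichment and halves inter-cluster enrichment, then reproduces the
signature drop of the inter/intra median score ratio.
"""

import numpy as np

from ifn3d import (
    GenomeSpec, LoopSpec, PerturbationSpec, SyntheticHiCParams,
    classify_cluster_loops, detect_loops, gaussian_dot_kernel, ice_balance,
    loop_score_correlation, mask_low_coverage, merge_matrices,
    quantify_loops, score_map, simulate_contact_pair,
)
from ifn3d.loops import LoopCall
from ifn3d.intervals import GenomicInterval

BS = 10_000
genome = GenomeSpec(["chr1"], [250 * BS], BS)
clusters = [GenomicInterval("chr1", 40 * BS, 80 * BS, name="cl1"),
            GenomicInterval("chr1", 150 * BS, 190 * BS, name="cl2")]
loops = []
for c0 in (40, 150):  # three intra- and three inter-cluster loops each
    loops += [LoopSpec("chr1", c0 + 5, c0 + 20), LoopSpec("chr1", c0 + 12, c0 + 35),
              LoopSpec("chr1", c0 + 22, c0 + 38), LoopSpec("chr1", c0 + 10, c0 + 60),
              LoopSpec("chr1", c0 - 25, c0 + 15), LoopSpec("chr1", c0 + 30, c0 + 75)]
params = SyntheticHiCParams(1.0, 5e5, 0.0, loops=loops, seed=0)
pert = PerturbationSpec(clusters=clusters, intra_gain=2.0, inter_gain=0.5)
untreated, treated, truth = simulate_contact_pair(genome, params, pert)

kernel = gaussian_dot_kernel(17, 1.5)
fusion = ice_balance(mask_low_coverage(
    merge_matrices([untreated["chr1"], treated["chr1"]]), 0.0))
scores = score_map(fusion, kernel, min_dist=5 * BS, max_dist=10_000_000)
calls = detect_loops(scores, "chr1", BS, threshold=0.35, min_separation=5)
print(f"fusion map: {len(calls)} loops with score >= 0.35 "
      f"({len(loops)} injected)")

table = quantify_loops(calls, {"untreated": untreated["chr1"],
                               "treated": treated["chr1"]},
                       kernel, seed=1, min_dist=5 * BS)
print(f"score correlation between conditions (Spearman): "
      f"{loop_score_correlation(table['untreated'], table['treated']):.2f}")

for cond in ("untreated", "treated"):
    scored = [LoopCall(c.chrom, c.bin1, c.bin2, float(table.loc[c.id, cond]),
                       c.resolution)
              for c in calls if np.isfinite(table.loc[c.id, cond])]
    for s in classify_cluster_loops(scored, clusters, max_length=500_000):
        print(f"{cond:10s} {s.cluster.name}: "
              f"median intra={np.median(s.intra_scores):.3f} "
              f"inter={np.median(s.inter_scores):.3f} "
              f"ratio={s.ratio:.3f}")
print("a lower treated ratio means loops inside the cluster strengthened "
      "relative to those reaching out of it.")
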