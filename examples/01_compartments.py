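"""A/B compartments: call PC1, measure saddle strength, quantify ΔPC1.

Simulates a paired untreated/stimulated Hi-C map for one 8-Mb chromosome
(40-kb bins) in which three gene clusters gain compartmental coupling on
stimulation, then recovers that gain with the region-vs-control ΔPC1
statistic.
"""

import numpy as np

from ifn3d import (
    BinTrack, GenomeSpec, PerturbationSpec, SyntheticHiCParams,
    compute_compartment_track, delta_pc1_regions, ice_balance,
    mask_low_coverage, rank_sum_test, saddle_strength,
    simulate_contact_pair,
)
from ifn3d.intervals import GenomicInterval

BS = 40_000
genome = GenomeSpec(["chr1"], [200 * BS], BS)
clusters = [GenomicInterval("chr1", a * BS, b * BS, name=n)
            for (a, b, n) in [(64, 74, "clusterA"), (104, 114, "clusterB"),
                              (144, 154, "clusterC")]]
params = SyntheticHiCParams(decay_exponent=1.0, depth=5e5,
                            compartment_contrast=0.4, block_width=20, seed=0)
pert = PerturbationSpec(clusters=clusters, comp_gain=1.5)
untreated, treated, truth = simulate_contact_pair(genome, params, pert)

# activity track (stands in for binned RNA-seq coverage) phases the PC1 sign
activity = BinTrack("chr1", BS, truth.compartment_labels["chr1"].astype(float))

tracks = {}
for name, mats in [("untreated", untreated), ("treated", treated)]:
    m = ice_balance(mask_low_coverage(mats["chr1"], 0.02))
    comp = compute_compartment_track(m, activity)
    sad = saddle_strength(m, comp.pc1, n_quantiles=10, corner_fraction=0.2)
    tracks[name] = comp.pc1
    print(f"{name}: eigenvector rank {comp.eigen_rank}, "
          f"phase r={comp.phase_correlation:.3f}, "
          f"saddle strength={sad.strength:.2f}")

stats = delta_pc1_regions(tracks["treated"], tracks["untreated"], clusters,
                          control_offset=1_000_000)
print("\nregion            mean dPC1   control up  control down")
for s in stats:
    print(f"{s.region.name:14s} {s.mean:+11.4f} {s.control_up:+11.4f} "
          f"{s.control_down:+12.4f}")

cl = [s.mean for s in stats]
ct = [v for s in stats for v in (s.control_up, s.control_down)
      if np.isfinite(v)]
res = rank_sum_test(cl, ct)
print(f"\nrank-sum cluster vs control: p = {res.pvalue:.4f}")
print("positive cluster means exceeding both controls indicate the gain in "
      "A-compartment strength at stimulated clusters.")
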