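"""Regulatory-region interaction strength versus constructed controls.

Places accessible peaks inside a gene cluster, connects them by loops,
and tests whether peak-peak contacts exceed distance- and size-matched
control pairs with a paired Wilcoxon signed-rank test.
"""

from ifn3d import (
    GenomeSpec, LoopSpec, PerturbationSpec, SyntheticHiCParams,
    build_peak_pairs, ice_balance, mask_low_coverage,
    paired_enrichment_test, select_regulatory_peaks, simulate_contact_pair,
    simulate_peaks,
)
from ifn3d.intervals import GenomicInterval

BS = 10_000
genome = GenomeSpec(["chr1"], [150 * BS], BS)
cluster = [GenomicInterval("chr1", 40 * BS, 110 * BS, name="isg_cluster")]

peaks = simulate_peaks(genome, cluster, genes=[], n_per_cluster=6, seed=2)
bins = sorted(p.interval.midpoint // BS for p in peaks)
loops = [LoopSpec("chr1", a, b, 3.0, 1.5)
         for i, a in enumerate(bins) for b in bins[i + 1:] if b - a >= 5]
params = SyntheticHiCParams(1.0, 5e5, 0.0, loops=loops, seed=2)
_, treated, _ = simulate_contact_pair(
    genome, params, PerturbationSpec(clusters=cluster, intra_gain=2.0))

m = ice_balance(mask_low_coverage(treated["chr1"], 0.0))
selected = select_regulatory_peaks(peaks, cluster, gene_bodies=[])
pairs = build_peak_pairs(selected, m)
res = paired_enrichment_test(pairs)

print(f"{len(selected)} regulatory peaks -> {res.n} within-cluster pairs")
print(f"median interaction strength: real={res.median_real:.4f}  "
      f"control={res.median_control:.4f}")
print(f"paired signed-rank p = {res.pvalue:.3g}")
print("each control preserves the real pair's genomic distance and partner "
      "size, so the excess strength reflects looping between accessible "
      "regions, not distance decay.")
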