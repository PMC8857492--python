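"""Replicate similarity with the stratum-adjusted correlation coefficient.

Simulates two replicates per condition: all pairs are highly similar
(same decay and compartments), but the treated pair scores highest
because both replicates share the stimulation-specific loop gain.
"""

import itertools

from ifn3d import (
    GenomeSpec, LoopSpec, PerturbationSpec, SyntheticHiCParams,
    scc, simulate_contact_pair,
)
from ifn3d.intervals import GenomicInterval

BS = 10_000
genome = GenomeSpec(["chr1"], [150 * BS], BS)
cluster = [GenomicInterval("chr1", 40 * BS, 100 * BS)]
loops = [LoopSpec("chr1", 50, 70, 6.0, 2.0), LoopSpec("chr1", 55, 90, 6.0, 2.0)]
pert = PerturbationSpec(clusters=cluster, intra_gain=3.0)

samples = {}
for rep in (1, 2):
    params = SyntheticHiCParams(1.0, 3e5, 0.3, loops=loops, seed=rep)
    unt, tre, _ = simulate_contact_pair(genome, params, pert)
    samples[f"untreated_r{rep}"] = unt["chr1"]
    samples[f"treated_r{rep}"] = tre["chr1"]

print("pairwise SCC (10-kb bins, 1-Mb max distance):")
for a, b in itertools.combinations(samples, 2):
    v = scc(samples[a], samples[b], h=1, max_distance=1_000_000).scc
    kind = "within" if a.split("_")[0] == b.split("_")[0] else "between"
    print(f"  {a:13s} vs {b:13s}: {v:.3f}  ({kind} condition)")
print("all pairs share decay and compartments, so every SCC is high; the "
      "treated replicates additionally share the stimulation-specific loop "
      "gain and score highest.")
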