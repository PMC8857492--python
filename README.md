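# ifn3d

Quantitative analysis of interferon-induced 3D chromatin reorganization.

Type I and type II interferons (IFN) rapidly induce hundreds of
interferon-stimulated genes (ISG), many of which sit in genomic clusters
(*Gbp*, *Oas*, *Mx*, *Ifit*, ...). Stimulation does not switch these loci
between A and B compartments, but it strengthens their A-compartment
coupling, rewires chromatin loops toward short-range, intra-cluster
contacts, and opens chromatin at regulatory elements — largely through the
ISGF3 transcription-factor complex (STAT1/STAT2/IRF9). `ifn3d` packages the
statistics needed to quantify these effects from paired-condition Hi-C,
ATAC-seq and RNA-seq summaries, together with a synthetic-data generator
with known ground truth, so every statistic can be validated end to end.

## What it computes

For binned cis contact matrices `C` (per chromosome):

* **Balancing and normalization** — ICE weights `w` with
  `b_ij = C_ij w_i w_j`, distance-expected profile `E(d)` and
  observed-over-expected `OE_ij = b_ij / E(|i-j|)`.
* **Compartment score (PC1)** — eigenvectors of the Pearson correlation
  matrix of O/E rows; the one of the top three best correlated with an
  activity track (binned RNA-seq) is selected and oriented so r > 0
  (positive = A). Saddle strength `(AA + BB) / (2·AB)` over PC1-quantile
  corner blocks summarizes compartmentalization.
* **Region ΔPC1** — mean `PC1_treated − PC1_untreated` over bins
  overlapping a region of interest, against size-matched controls 1 Mb up-
  and downstream, compared by Wilcoxon rank-sum.
* **Loop scores** — Pearson correlation between a standardized Gaussian-dot
  template and local windows of `log(1 + OE)`; detection by greedy
  non-maximum suppression above score 0.35; per-condition quantification at
  fixed positions after subsampling all conditions to equal coverage;
  inter/intra-cluster classification and median score ratios.
* **Replicate similarity** — stratum-adjusted correlation coefficient
  `SCC = Σ w_k r_k / Σ w_k` with `w_k = N_k σ_1k σ_2k` over distance strata
  of smoothed maps.
* **Regulatory-pair enrichment** — mean balanced contact between accessible
  (ATAC) peak pairs within a cluster versus constructed control pairs that
  preserve each pair's midpoint distance and partner size, tested with a
  paired Wilcoxon signed-rank.
* **RNA/ATAC classification** — IFN-type-specific induction
  (log2FC ≥ 1, padj ≤ 0.05 in one type, log2FC < 1 in the other), induction
  strata (log2FC > 5 vs 1–5), top-200 induced genes, nearest-TSS peak
  annotation, ISGF3-dependence categories (expression up + accessibility up
  + accessibility lost in *Irf9*−/−), and the 2×2 chi-squared comparison of
  dependence rates between IFN types.

## Worked example

`examples/01_compartments.py` simulates an 8-Mb chromosome at 40-kb bins in
which three ISG-like clusters gain compartmental coupling (×1.5) on
stimulation, and quantifies the change:

```
untreated: eigenvector rank 1, phase r=0.992, saddle strength=2.12
treated: eigenvector rank 1, phase r=0.986, saddle strength=2.62

region            mean dPC1   control up  control down
clusterA           +0.0168     -0.0008      -0.0004
clusterB           +0.0182     +0.0003      -0.0015
clusterC           +0.0170     -0.0026      +0.0023

rank-sum cluster vs control: p = 0.0238
```

Each cluster's mean PC1 increase clearly exceeds both of its size-matched
1-Mb-offset controls: the treated clusters moved deeper into the A
compartment while their surroundings did not. The other examples cover loop
detection and inter/intra ratios (`02`), regulatory control-pair enrichment
(`03`, e.g. `median real=0.0416 vs control=0.0028, signed-rank p = 3.1e-4`),
RNA/ATAC classification with the chi-squared comparison (`04`), and SCC
replicate similarity (`05`).

A thin CLI mirrors the library (`ifn3d simulate|compartments|loops|
reginter|chisq|run`); `ifn3d run --seed 0 --outdir out/` executes the whole
synthetic pipeline and writes a manifest with output checksums.

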