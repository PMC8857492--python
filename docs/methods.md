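# Methods

## Scope and data model

`ifn3d` operates on cis (intra-chromosomal) binned contact matrices, one
chromosome per `ContactMatrix`, in 0-based half-open coordinates; bin `i`
covers `[i·bin_size, (i+1)·bin_size)`. Genome-level statements aggregate
per-chromosome results. Trans contacts, read-level processing, peak
calling and differential-model fitting are out of scope: differential
tables (feature id, log2FC, adjusted p) are consumed as produced by
upstream tools, never fitted here.

## Contact-matrix processing

**Masking.** Bins with zero marginal, or marginal below a configurable
quantile `q` of the nonzero marginals (default 0.02), are excluded from all
downstream computation. Masked bins have undefined weights, O/E values and
PC1 entries (NaN), and windows over them count as invalid.

**Balancing** is plain ICE: iterate `w_i ← w_i / s_i` (with `s` the
normalized row sums of the reweighted matrix) until the coefficient of
variation of unmasked row sums falls below `tol` (default 1e-6), then scale
so the mean unmasked balanced row sum is 1. Non-convergence within
`max_iter` raises, reporting the final CV. KR balancing is deliberately not
implemented; ICE is adequate for the rank- and correlation-based statistics
used downstream and its convergence test is explicit.

**Expected and O/E.** `E(d)` is the mean balanced value over unmasked cells
at bin distance `d`; `OE_ij = b_ij / E(|i−j|)`. By construction every
unmasked diagonal of O/E has mean 1 (asserted to 1e-9 in tests).

**Subsampling** to a target total uses a single multinomial draw over
upper-triangle cells with probabilities proportional to counts, giving an
exact target total, preserved symmetry and binomial per-cell marginals.
When a genome-wide target is split across chromosomes, it is split
proportionally to their totals.

**Log-ratio maps** are fixed-bin: `log2((C1·s + p)/(C2 + p))` with `s`
matching the totals and pseudocount `p` (default 1). This is a simplified
stand-in for flexible-binning ratio methods and is noisier in sparse
regions.

**SCC.** Both raw maps are smoothed with a `(2h+1)²` mean filter
(default h = 1) truncated at matrix borders and masked cells — no padding,
so no data is invented at edges. For each distance stratum up to
`max_distance` (default 1 Mb at 10-kb bins), `r_k` is the Pearson
correlation of paired valid cells and `w_k = N_k σ_1k σ_2k`; strata with
zero variance in either map get weight 0. Note that with truncated
smoothing, two independent draws from the same *decaying* law correlate
positively within strata near the borders; the zero-expectation null holds
for flat laws, and comparisons between real samples should always be read
relative to reference pairs (as in replicate-similarity heatmaps).

## Compartments

The Pearson correlation matrix of unmasked O/E rows is eigendecomposed;
the top three eigenvectors by |eigenvalue| are correlated with a per-bin
activity track (binned RNA-seq coverage in practice), and the best one is
selected and sign-flipped so the correlation is positive (positive PC1 =
active A compartment). Eigenvectors are unit-norm, not eigenvalue-scaled;
scaling cancels in every sign, correlation and difference use. Zero-variance
O/E rows or a constant activity track raise rather than phase arbitrarily.

**Saddle strength.** Unmasked bins are ranked by PC1 into `q` quantile
groups (default 10); saddle cell `(a,b)` is the mean O/E over bin pairs in
groups `a` and `b`; strength is `(AA + BB) / (2·AB)` over the extreme
`corner_fraction` (default 0.2) of groups. The corner fraction follows the
common convention and is config-exposed.

**ΔPC1 regions.** `Δ = PC1_treated − PC1_untreated` per bin; the region
statistic is the mean over bins whose interval intersects the region (any
intersection counts). Controls are intervals of the region's exact length
whose starts sit `control_offset` (default 1 Mb) up/downstream of the
region start; a control extending past a chromosome end is dropped and
flagged, never shortened, because size-matching is the point of the
control. Both per-region paired controls and the pooled control
distribution are available to downstream summaries; the rank-sum comparison
uses per-region means on both sides.

**Rank-sum test.** Mann-Whitney U, two-sided; exact null for combined
n ≤ 20 without ties, tie-corrected normal approximation otherwise; fully
degenerate input (all values identical) returns p = 1 with a flag instead
of raising.

## Loops

**Template.** A `k×k` (default 17 at 10-kb, odd) Gaussian dot (sd 1.5
bins) standardized to zero mean and unit variance. This is a deliberately
simple, documented dot template — the center is enriched over the
surrounding ring — rather than a reproduction of any specific published
kernel.

**Scoring** happens on `log(1 + O/E)` of the balanced matrix: O/E removes
distance decay, the log stabilizes dynamic range, and Pearson correlation
with the template makes scores invariant to positive rescaling of counts
(asserted to 1e-9). Cells within `[min_dist, max_dist]` (default up to
10 Mb) are scored when ≥ 80% of their window cells are valid; zero-variance
windows are undefined.

**Detection** collects cells above the score threshold (default 0.35, the
same threshold used for reporting) and keeps them greedily best-first with
no two calls within `min_separation` bins (Chebyshev), ties broken by
position — deterministic by construction.

**Quantification** at fixed positions (from a fusion map: the raw-count sum
of all replicates and conditions) subsamples every condition to the
smallest total, re-masks, re-balances and scores only the given positions,
so scores are comparable across conditions at equal coverage.

**Cluster classification.** A loop is considered if at least one anchor
midpoint lies in a cluster, its midpoint separation is ≤ 500 kb and it
passes an optional score filter (off by default for statistics; 0.35 for
display-style filtering). Intra: both anchors in the same cluster; inter:
exactly one anchor inside; loops bridging two different clusters are
excluded from both sets. The per-cluster statistic is
`median(inter) / median(intra)`, defined only when both sets are non-empty
and the intra median is nonzero.

## Regulatory-pair enrichment

Peaks overlapping a cluster but no gene body (gene-body peaks are broad and
uninformative for regulatory elements) are paired all-vs-all within their
cluster. Interaction strength is the mean *balanced* value over bin pairs
covering the two peaks — raw-scale normalized signal, not O/E (an O/E
variant is a config flag). For a pair A–B with midpoint distance `d`, two
controls are built: an interval of B's size `d` upstream of A's midpoint
(paired with A) and one of A's size `d` downstream of B's midpoint (paired
with B); midpoint placement rounds toward the start on odd sizes, so the
distance is preserved exactly in integer arithmetic. Off-chromosome
controls are flagged invalid, and pairs without any valid control are
dropped (counted). The test is a two-sided Wilcoxon signed-rank on
`real − mean(valid controls)` — exact for n ≤ 25 without zeros/ties,
normal approximation otherwise; an unpaired rank-sum variant is available
but the paired test is the default since the controls are constructed per
pair. Pairs spanning masked bins yield undefined strengths and are dropped.

## RNA/ATAC integration

Thresholds: significance is `padj ≤ 0.05`; induction is `log2FC ≥ 1`;
"extreme" is `log2FC > 5`, "moderate" `1–5`; downregulation is
`log2FC ≤ −1` (used symmetrically for knockout accessibility loss).
Type-specific genes are significantly up in one IFN type with the other
type's log2FC < 1. The top-200 selection ranks significant up-regulated
genes by log2FC with deterministic id tie-breaks. Peaks annotate to the
gene with the nearest TSS (gene start on `+`, end on `−`) to the peak
midpoint, ties to the smaller gene id. A gene counts as
accessibility-changed if *any* annotated peak passes ("any" is the default
quantifier; "all"/best-peak variants would be straightforward config
extensions). ISGF3-dependence per IFN type: "red" = RNA up and peak
accessibility up on stimulation; "blue" = red plus peak accessibility lost
in the *Irf9* knockout; the 2×2 table {IFN types} × {dependent,
independent} is tested by Pearson chi-squared with 1 df, Yates correction
off by default. Multiple-testing correction is consumed, never computed.

## Synthetic-data generator

Counts are independent Poisson draws per upper-triangle cell (mirrored;
diagonal drawn once) with mean

```
mu_ij = k · (1+|i−j|)^(−alpha) · (1 + c_ij · s_i · s_j) · prod_loops (1 + L · g_ij)
```

where `alpha` is the distance-decay exponent (default 1), `s` a continuous
compartment profile in [−1, 1] (default ±1 blocks of 20 bins),
`c_ij` the compartment contrast, `g_ij` a Gaussian dot of sd `w` bins at
the loop anchors (applied at both mirror positions to keep `mu` symmetric),
and `k` scales the expected upper-triangle total to `depth`. Negative
`mu` (possible when `c·gain > 1`) rejects the parameters.

The treated condition multiplies `c` by `comp_gain` for every pair with at
least one bin in a designated cluster — a region's A-strength gain is its
stronger checkerboard coupling with the whole chromosome; restricting the
gain to intra-cluster pairs would be invisible to compartment scoring —
and scales loop enrichments by `intra_gain`/`inter_gain` according to each
loop's truth class. With all gains 1 the treated generative law is
identical to the untreated one.

Seeding: the untreated draw uses `params.seed`; the treated draw uses an
independent stream derived from it, so that null simulations have honest
between-condition noise. Passing `treated_seed=params.seed` couples the
draws, making the two conditions bit-identical under unit gains (useful for
pipeline determinism checks). Identical seeds always give bit-identical
outputs.

Poisson (not negative-binomial) noise is a deliberate simplification:
the downstream statistics are ranks, correlations and sign comparisons,
for which overdispersion mostly rescales power; a dispersion parameter
would be the single place to change this. The generator also omits
replicate batch effects, restriction-fragment structure, trans contacts
and mappability artifacts — so passing tests demonstrate the statistics
recover the modelled effects at realistic noise, not robustness to every
artifact of real libraries.

Peaks are fixed-width (default 400 bp) intervals placed uniformly inside
clusters by rejection sampling, avoiding gene bodies and each other.
Differential tables draw `log2FC ~ Normal(class mean, sd)` with class
means 6 (extreme), 3 (moderate), ±2 for accessibility changes, −3 for
homeostatic knockout loss, and adjusted p-values uniform on (0, 0.01] for
true effects and on (0, 1] for nulls. ISGF3-dependence rates default to
0.7 for type I and 0.33 for type II induced genes, reproducing the
qualitative asymmetry between the IFN responses that the integration
module is designed to detect.

## Validation experiment sizes

The reference experiments (`ifn3d.validation`, shared by the test suite
and `scripts/acceptance.py`) use one 200-bin chromosome at 40 kb with
contrast 0.4 and depth 5×10⁵ for compartment recovery; three 10-bin
clusters inside A blocks (so both 1-Mb controls stay on-chromosome — a
geometric requirement, since clusters in B blocks legitimately move PC1
the other way) with gain 1.5 for ΔPC1 direction; 400 replicates of reduced
size (140 bins / depth 2×10⁵, or 150 bins / depth 5×10⁴) for the two null
calibrations; and 200–250-bin chromosomes at 10 kb with dot enrichment 5
and sd 2 bins for loop detection and ratio statistics. These sizes are
desk-scale stand-ins chosen so per-bin coverage is within the regime of a
deeply sequenced Hi-C study while hundreds of replicates remain cheap.

## Numerical choices and degenerate inputs

* Asymmetric or negative inputs, conflicting mirror records, and
  out-of-range bins are rejected at parse time with line numbers.
* Windows/means over all-masked cells are NaN and flagged, never silently
  zero; statistics requiring them drop-and-count.
* Degenerate statistical inputs (all values tied, all differences zero)
  return p = 1 with an explicit degeneracy flag.
* All tie-breaks (top-N ranking, loop suppression, TSS ties) are
  deterministic by id or position.
* Every random routine takes an explicit integer seed; identical seeds
  give bit-identical results.

## Known limitations

Cis-only; single-resolution (no matrix pyramids); no TAD/insulation
calling; no GC-based phasing fallback when no activity track exists; the
log-ratio map is fixed-bin; the loop template is a single dot pattern
(no borders/hairpins). The chi-squared comparison assumes independent loci;
clustered ISG violate this mildly, as they do in any locus-level count
comparison.
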