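"""Paired-condition synthetic data with known ground truth.

The generator emulates the statistical structure the analysis modules
assume, for a stimulus-vs-control (treated/untreated) design:

* cis contact maps with power-law distance decay ``(1 + d)^-alpha``,
  a checkerboard compartment term ``1 + c * s_i * s_j`` from a continuous
  per-bin profile ``s`` in [-1, 1], Gaussian loop dots, and independent
  Poisson counting noise per upper-triangle cell;
* a perturbation layer that multiplies the compartment contrast inside
  designated cluster regions (``comp_gain``) and rescales loop enrichments
  by truth class (``intra_gain`` / ``inter_gain``) in the treated map —
  mirroring the observed gain of short-range intra-cluster contacts and
  loss of long-range ones on interferon stimulation;
* cluster-confined accessible peaks avoiding gene bodies;
* differential expression/accessibility tables with truth-labelled
  induction classes, induction strata, and ISGF3-dependence flags.

All randomness flows from explicit integer seeds: identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hic import ContactMatrix
from .intervals import GenomicInterval
from .reginter import Peak


@dataclass
class GenomeSpec:
    """Chromosome names, lengths (bp) and a common bin size."""

    chroms: list[str]
    lengths: list[int]
    bin_size: int

    def __post_init__(self) -> None:
        if not self.chroms:
            raise ValueError("empty genome")
        if len(self.chroms) != len(self.lengths):
            raise ValueError("chroms and lengths differ in length")
        if any(l <= 0 for l in self.lengths) or self.bin_size <= 0:
            raise ValueError("lengths and bin_size must be positive")

    def length(self, chrom: str) -> int:
        return self.lengths[self.chroms.index(chrom)]

    def n_bins(self, chrom: str) -> int:
        return -(-self.length(chrom) // self.bin_size)  # ceil


@dataclass
class LoopSpec:
    """An injected loop dot at bins (bin1, bin2) with enrichment and width."""

    chrom: str
    bin1: int
    bin2: int
    strength: float = 5.0   # multiplicative enrichment L at the dot center
    width: float = 2.0      # Gaussian sd in bins

    def __post_init__(self) -> None:
        if self.strength < 0 or self.width <= 0:
            raise ValueError("loop strength must be >= 0 and width > 0")


@dataclass
class SyntheticHiCParams:
    """Generative parameters shared by both conditions."""

    decay_exponent: float = 1.0
    depth: float = 500_000.0          # expected total counts per chromosome
    compartment_contrast: float = 0.0
    compartment_profile: dict[str, np.ndarray] | None = None
    block_width: int = 20             # bins per ±1 block if profile is None
    loops: list[LoopSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if self.compartment_contrast < 0:
            raise ValueError("compartment_contrast must be >= 0")


@dataclass
class GeneTruth:
    """Ground-truth labels for one synthetic gene."""

    induced_a: bool = False
    induced_b: bool = False
    stratum: str | None = None        # "extreme" | "moderate" | None
    isgf3_dependent_a: bool = False
    isgf3_dependent_b: bool = False
    homeostatic_dependent: bool = False


@dataclass
class PerturbationSpec:
    """Treated-condition effects; all gains 1 means no perturbation."""

    clusters: list[GenomicInterval] = field(default_factory=list)
    comp_gain: float = 1.0
    intra_gain: float = 1.0
    inter_gain: float = 1.0
    gene_truth: dict[str, GeneTruth] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.comp_gain, self.intra_gain, self.inter_gain) < 0:
            raise ValueError("gains must be >= 0")


@dataclass
class SyntheticTruth:
    """Everything injected, for downstream recovery checks."""

    loop_classes: list[tuple[LoopSpec, str]]       # class: intra|inter|background
    compartment_labels: dict[str, np.ndarray]      # sign(s) per bin
    gene_truth: dict[str, GeneTruth]
    clusters: list[GenomicInterval]


def default_compartment_profile(n_bins: int, block_width: int) -> np.ndarray:
    """Two-state ±1 block profile (A = +1, B = -1), starting with B."""
    blocks = (np.arange(n_bins) // block_width) % 2
    return np.where(blocks == 1, 1.0, -1.0)


def _bin_in_intervals(chrom: str, b: int, bin_size: int,
                      intervals: list[GenomicInterval]) -> bool:
    mid = b * bin_size + bin_size // 2
    return any(iv.contains_point(chrom, mid) for iv in intervals)


def classify_loop(loop: LoopSpec, clusters: list[GenomicInterval],
                  bin_size: int) -> str:
    in1 = _bin_in_intervals(loop.chrom, loop.bin1, bin_size, clusters)
    in2 = _bin_in_intervals(loop.chrom, loop.bin2, bin_size, clusters)
    if in1 and in2:
        return "intra"
    if in1 or in2:
        return "inter"
    return "background"


def _mu_chrom(n: int, chrom: str, genome: GenomeSpec,
              params: SyntheticHiCParams, perturb: PerturbationSpec,
              treated: bool) -> np.ndarray:
    idx = np.arange(n)
    D = np.abs(np.subtract.outer(idx, idx))
    mu = (1.0 + D) ** (-params.decay_exponent)
    c = params.compartment_contrast
    if c > 0:
        if params.compartment_profile is not None:
            s = np.asarray(params.compartment_profile[chrom], dtype=float)
            if s.shape != (n,):
                raise ValueError(f"compartment profile length mismatch on {chrom}")
        else:
            s = default_compartment_profile(n, params.block_width)
        cij = np.full((n, n), c)
        if treated and perturb.comp_gain != 1.0 and perturb.clusters:
            in_cluster = np.array([
                _bin_in_intervals(chrom, b, genome.bin_size, perturb.clusters)
                for b in idx])
            # a region's compartment strength is its checkerboard coupling
            # with the whole chromosome, so the gain applies to every pair
            # with at least one bin in a cluster
            either = in_cluster[:, None] | in_cluster[None, :]
            cij[either] = c * perturb.comp_gain
        comp = 1.0 + cij * np.outer(s, s)
        if comp.min() < 0:
            raise ValueError("compartment term makes expected counts negative; "
                             "reduce compartment_contrast or comp_gain")
        mu = mu * comp
    for loop in params.loops:
        if loop.chrom != chrom:
            continue
        L = loop.strength
        if treated:
            cls = classify_loop(loop, perturb.clusters, genome.bin_size)
            if cls == "intra":
                L *= perturb.intra_gain
            elif cls == "inter":
                L *= perturb.inter_gain
        anchors = {(loop.bin1, loop.bin2), (loop.bin2, loop.bin1)}
        for a1, a2 in sorted(anchors):  # mirrored dot keeps mu symmetric
            g = np.exp(-((idx[:, None] - a1) ** 2 + (idx[None, :] - a2) ** 2)
                       / (2 * loop.width ** 2))
            mu = mu * (1.0 + L * g)
    # scale so the expected upper-triangle total matches the depth
    iu = np.triu_indices(n)
    mu = mu * (params.depth / mu[iu].sum())
    return mu


def _draw(mu: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Poisson draw on the upper triangle (incl. diagonal), mirrored."""
    raw = rng.poisson(mu).astype(float)
    upper = np.triu(raw)
    return upper + np.triu(raw, 1).T


def simulate_contact_pair(
    genome: GenomeSpec,
    params: SyntheticHiCParams,
    perturb: PerturbationSpec,
    treated_seed: int | None = None,
) -> tuple[dict[str, ContactMatrix], dict[str, ContactMatrix], SyntheticTruth]:
    """Draw an untreated/treated matrix pair per chromosome, plus truth.

    The untreated draw uses ``params.seed``; the treated draw uses
    ``treated_seed`` if given, else an independent stream derived from
    ``params.seed``. Passing ``treated_seed=params.seed`` couples the noise,
    so with all gains equal to 1 the two conditions are cell-for-cell
    identical.
    """
    for iv in perturb.clusters:
        if iv.chrom not in genome.chroms or iv.end > genome.length(iv.chrom):
            raise ValueError(f"perturbation region {iv} outside the genome")
    for lp in params.loops:
        n = genome.n_bins(lp.chrom)
        if not (0 <= lp.bin1 < n and 0 <= lp.bin2 < n):
            raise ValueError(f"loop anchors outside matrix on {lp.chrom}")
    rng_u = np.random.default_rng(params.seed)
    if treated_seed is None:
        treated_seed = int(np.random.default_rng([params.seed, 0x7EA7ED])
                           .integers(2**31))
    rng_t = np.random.default_rng(treated_seed)
    untreated, treated = {}, {}
    labels = {}
    for chrom in genome.chroms:
        n = genome.n_bins(chrom)
        mu_u = _mu_chrom(n, chrom, genome, params, perturb, treated=False)
        mu_t = _mu_chrom(n, chrom, genome, params, perturb, treated=True)
        untreated[chrom] = ContactMatrix(chrom, genome.bin_size, _draw(mu_u, rng_u))
        treated[chrom] = ContactMatrix(chrom, genome.bin_size, _draw(mu_t, rng_t))
        if params.compartment_profile is not None:
            s = np.asarray(params.compartment_profile[chrom], dtype=float)
        else:
            s = default_compartment_profile(n, params.block_width)
        labels[chrom] = np.sign(s)
    truth = SyntheticTruth(
        loop_classes=[(lp, classify_loop(lp, perturb.clusters, genome.bin_size))
                      for lp in params.loops],
        compartment_labels=labels,
        gene_truth=dict(perturb.gene_truth),
        clusters=list(perturb.clusters),
    )
    return untreated, treated, truth


# ---------------------------------------------------------------------------
# Peaks and genes

def simulate_peaks(genome: GenomeSpec, clusters: list[GenomicInterval],
                   genes: list[GenomicInterval], n_per_cluster: int,
                   seed: int, peak_width: int = 400,
                   max_tries: int = 2000) -> list[Peak]:
    """Place non-overlapping peaks inside clusters, avoiding gene bodies.

    Raises if a cluster is too crowded to host ``n_per_cluster``
    non-overlapping peaks (e.g. fully covered by a gene body).
    """
    rng = np.random.default_rng(seed)
    peaks: list[Peak] = []
    for ci, cluster in enumerate(clusters):
        if cluster.chrom not in genome.chroms or cluster.end > genome.length(cluster.chrom):
            raise ValueError(f"cluster {cluster} outside the genome")
        placed: list[GenomicInterval] = []
        tries = 0
        while len(placed) < n_per_cluster:
            if tries >= max_tries:
                raise ValueError(
                    f"cannot place {n_per_cluster} peaks in cluster "
                    f"{cluster.chrom}:{cluster.start}-{cluster.end} "
                    f"(placed {len(placed)} after {max_tries} tries)")
            tries += 1
            if cluster.length < peak_width:
                raise ValueError(
                    f"cluster {cluster.chrom}:{cluster.start}-{cluster.end} "
                    f"shorter than peak width")
            start = int(rng.integers(cluster.start,
                                     cluster.end - peak_width + 1))
            cand = GenomicInterval(cluster.chrom, start, start + peak_width)
            if any(cand.overlaps(g) for g in genes):
                continue
            if any(cand.overlaps(p) for p in placed):
                continue
            placed.append(cand)
        for pi, iv in enumerate(sorted(placed, key=lambda x: x.start)):
            name = cluster.name or f"cluster{ci}"
            peaks.append(Peak(iv, id=f"{name}_peak{pi}"))
    return peaks


# ---------------------------------------------------------------------------
# Gene truth and differential tables

def simulate_gene_truth(n_genes: int, seed: int,
                        p_a_only: float = 0.10, p_b_only: float = 0.10,
                        p_shared: float = 0.15,
                        p_extreme: float = 0.3,
                        p_isgf3_a: float = 0.7, p_isgf3_b: float = 0.33,
                        p_homeostatic: float = 0.1) -> dict[str, GeneTruth]:
    """Random induction classes for a synthetic gene set.

    The default ISGF3-dependence rates differ by IFN type (high for type I,
    low for type II), reproducing the asymmetry the integration module is
    designed to detect.
    """
    rng = np.random.default_rng(seed)
    truth = {}
    for g in range(n_genes):
        u = rng.random()
        induced_a = u < p_a_only + p_shared
        induced_b = p_a_only <= u < p_a_only + p_shared + p_b_only
        stratum = None
        if induced_a or induced_b:
            stratum = "extreme" if rng.random() < p_extreme else "moderate"
        truth[f"gene{g:04d}"] = GeneTruth(
            induced_a=induced_a,
            induced_b=induced_b,
            stratum=stratum,
            isgf3_dependent_a=induced_a and rng.random() < p_isgf3_a,
            isgf3_dependent_b=induced_b and rng.random() < p_isgf3_b,
            homeostatic_dependent=rng.random() < p_homeostatic,
        )
    return truth


DEFAULT_EFFECTS = {
    "extreme": 6.0,      # log2FC mean of strongly induced genes
    "moderate": 3.0,
    "null": 0.0,
    "atac_up": 2.0,      # accessibility gain accompanying induction
    "atac_down": -2.0,   # accessibility loss in the Irf9 knockout
    "homeo_down": -3.0,  # homeostatic expression loss in the knockout
}


def _diff_table(ids: list[str], means: np.ndarray, is_effect: np.ndarray,
                sd: float, rng: np.random.Generator) -> pd.DataFrame:
    log2fc = rng.normal(means, sd) if sd > 0 else means.astype(float).copy()
    padj = np.where(is_effect,
                    rng.uniform(1e-8, 0.01, size=len(ids)),
                    rng.uniform(0.0, 1.0, size=len(ids)))
    return pd.DataFrame({"log2fc": log2fc, "padj": padj},
                        index=pd.Index(ids, name="id"))


def simulate_differential_tables(truth: dict[str, GeneTruth],
                                 effect_sizes: dict[str, float] | None = None,
                                 noise_sd: float = 0.5,
                                 seed: int = 0) -> dict[str, pd.DataFrame]:
    """Differential tables per contrast from truth labels.

    Returns RNA contrasts (``rna_a``, ``rna_b``, ``rna_ko`` — homeostatic
    knockout vs wildtype) and per-gene promoter-peak ATAC contrasts
    (``atac_a``, ``atac_b``, ``atac_ko_a``, ``atac_ko_b``, ``atac_ko``),
    with log2FC ~ Normal(class mean, noise_sd) and small adjusted p-values
    (<= 0.01) on true effects, uniform on nulls. Peak ids are
    ``peak::<gene>``.
    """
    eff = dict(DEFAULT_EFFECTS)
    if effect_sizes:
        eff.update(effect_sizes)
    for key in DEFAULT_EFFECTS:
        if key not in eff:
            raise KeyError(f"missing effect-size class {key!r}")
    rng = np.random.default_rng(seed)
    genes = sorted(truth)
    peak_ids = [f"peak::{g}" for g in genes]

    def stratum_mean(t: GeneTruth) -> float:
        return eff[t.stratum] if t.stratum else eff["null"]

    tables = {}
    for key, induced in (("rna_a", lambda t: t.induced_a),
                         ("rna_b", lambda t: t.induced_b)):
        means = np.array([stratum_mean(truth[g]) if induced(truth[g])
                          else eff["null"] for g in genes])
        tables[key] = _diff_table(genes, means, means != 0, noise_sd, rng)
    means = np.array([eff["homeo_down"] if truth[g].homeostatic_dependent
                      else eff["null"] for g in genes])
    tables["rna_ko"] = _diff_table(genes, means, means != 0, noise_sd, rng)
    for key, up in (("atac_a", lambda t: t.induced_a),
                    ("atac_b", lambda t: t.induced_b)):
        means = np.array([eff["atac_up"] if up(truth[g]) else eff["null"]
                          for g in genes])
        tables[key] = _diff_table(peak_ids, means, means != 0, noise_sd, rng)
    for key, dep in (("atac_ko_a", lambda t: t.induced_a and t.isgf3_dependent_a),
                     ("atac_ko_b", lambda t: t.induced_b and t.isgf3_dependent_b)):
        means = np.array([eff["atac_down"] if dep(truth[g]) else eff["null"]
                          for g in genes])
        tables[key] = _diff_table(peak_ids, means, means != 0, noise_sd, rng)
    means = np.array([eff["atac_down"] if truth[g].homeostatic_dependent
                      else eff["null"] for g in genes])
    tables["atac_ko"] = _diff_table(peak_ids, means, means != 0, noise_sd, rng)
    return tables


def peak_gene_map(truth: dict[str, GeneTruth]) -> pd.DataFrame:
    """Annotation table for the synthetic one-peak-per-gene layout."""
    genes = sorted(truth)
    return pd.DataFrame(
        {"gene": genes, "tss_distance": 0.0, "assigned": True},
        index=pd.Index([f"peak::{g}" for g in genes], name="peak"))


# ---------------------------------------------------------------------------
# Truth serialization

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    obj = {
        "loops": [
            {"chrom": lp.chrom, "bin1": lp.bin1, "bin2": lp.bin2,
             "strength": lp.strength, "width": lp.width, "class": cls}
            for lp, cls in truth.loop_classes
        ],
        "compartment_labels": {c: v.tolist()
                               for c, v in truth.compartment_labels.items()},
        "clusters": [
            {"chrom": c.chrom, "start": c.start, "end": c.end, "name": c.name}
            for c in truth.clusters
        ],
        "genes": {g: vars(t) for g, t in truth.gene_truth.items()},
    }
    Path(path).write_text(json.dumps(obj, indent=1))
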