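"""Interaction strength between regulatory regions vs constructed controls.

For every pair of accessible (ATAC) peaks A-B inside the same cluster
(B downstream of A), two distance- and size-matched control pairs are
constructed: A with a position upstream of A at the same midpoint distance
and with B's size, and B with a position downstream of B at the same
distance and with A's size. The mean balanced Hi-C value over the bins
covering each pair measures its interaction strength; real-vs-control
enrichment is assessed with a paired Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hic import ContactMatrix
from .intervals import GenomicInterval, check_disjoint


@dataclass
class Peak:
    """An accessible region (ATAC-seq peak), optionally cluster-assigned."""

    interval: GenomicInterval
    id: str
    cluster_id: str | None = None


def select_regulatory_peaks(peaks: list[Peak],
                            clusters: list[GenomicInterval],
                            gene_bodies: list[GenomicInterval]) -> list[Peak]:
    """Keep peaks inside a cluster that touch no gene body.

    Gene-body peaks tend to be broad and uninformative for regulatory
    elements, so any overlap excludes the peak. Clusters must be disjoint;
    a peak straddling two clusters is an error.
    """
    check_disjoint(clusters)
    kept = []
    for p in peaks:
        hits = [c for c in clusters if p.interval.overlaps(c)]
        if len(hits) > 1:
            raise ValueError(f"peak {p.id} intersects two clusters")
        if not hits:
            continue
        if any(p.interval.overlaps(g) for g in gene_bodies):
            continue
        name = hits[0].name or f"{hits[0].chrom}:{hits[0].start}-{hits[0].end}"
        kept.append(Peak(p.interval, p.id, cluster_id=name))
    return kept


def interval_interaction_strength(a: GenomicInterval, b: GenomicInterval,
                                  m: ContactMatrix) -> float:
    """Mean balanced contact value over all bin pairs covering a and b.

    NaN when every such cell is masked.
    """
    if a.chrom != b.chrom or a.chrom != m.chrom:
        raise ValueError("intervals must be on the matrix chromosome")
    bal = m.balanced()
    bins_a = [i for i in a.bin_range(m.bin_size) if 0 <= i < m.n_bins]
    bins_b = [j for j in b.bin_range(m.bin_size) if 0 <= j < m.n_bins]
    if not bins_a or not bins_b:
        return float("nan")
    vals = bal[np.ix_(bins_a, bins_b)]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def pair_interaction_strength(a: Peak, b: Peak, m: ContactMatrix) -> float:
    return interval_interaction_strength(a.interval, b.interval, m)


@dataclass
class ControlSpec:
    """A constructed control interval paired with one real anchor."""

    interval: GenomicInterval
    anchor: GenomicInterval     # the real peak it pairs with
    valid: bool                 # False if it falls off the chromosome


def build_control_pairs(a: Peak, b: Peak,
                        chrom_length: int) -> tuple[ControlSpec, ControlSpec]:
    """Two distance/size-matched controls for the real pair A-B.

    With d the midpoint distance of the pair: the A-side control has B's
    size and sits d upstream of A's midpoint; the B-side control has A's
    size and sits d downstream of B's midpoint. A control reaching outside
    ``[0, chrom_length)`` is flagged invalid (never truncated).
    """
    if b.interval.start <= a.interval.start:
        raise ValueError("B must start after A")
    d = b.interval.midpoint - a.interval.midpoint
    specs = []
    for anchor, center, size in (
        (a.interval, a.interval.midpoint - d, b.interval.length),
        (b.interval, b.interval.midpoint + d, a.interval.length),
    ):
        start = center - size // 2
        end = start + size
        if start < 0 or end > chrom_length:
            # placeholder clamped interval; flagged invalid, never used
            iv = GenomicInterval(anchor.chrom, max(start, 0),
                                 max(start, 0) + size)
            specs.append(ControlSpec(iv, anchor, False))
        else:
            specs.append(ControlSpec(GenomicInterval(anchor.chrom, start, end),
                                     anchor, True))
    return specs[0], specs[1]


@dataclass
class PeakPair:
    """A real peak pair with its measured and control strengths."""

    a: Peak
    b: Peak
    real_strength: float
    controls: tuple[ControlSpec, ControlSpec]
    control_strengths: tuple[float, float]

    @property
    def control_strength(self) -> float:
        """Mean of the valid, defined control strengths (NaN if none)."""
        vals = [s for c, s in zip(self.controls, self.control_strengths)
                if c.valid and np.isfinite(s)]
        return float(np.mean(vals)) if vals else float("nan")


def build_peak_pairs(peaks: list[Peak], m: ContactMatrix) -> list[PeakPair]:
    """All within-cluster peak pairs with real and control strengths."""
    pairs = []
    by_cluster: dict[str, list[Peak]] = {}
    for p in peaks:
        if p.cluster_id is None:
            raise ValueError(f"peak {p.id} has no cluster assignment")
        by_cluster.setdefault(p.cluster_id, []).append(p)
    for cluster_peaks in by_cluster.values():
        cluster_peaks = sorted(cluster_peaks, key=lambda p: p.interval.start)
        for i in range(len(cluster_peaks)):
            for j in range(i + 1, len(cluster_peaks)):
                a, b = cluster_peaks[i], cluster_peaks[j]
                real = pair_interaction_strength(a, b, m)
                ctrl_a, ctrl_b = build_control_pairs(a, b, m.chrom_length)
                s_a = interval_interaction_strength(
                    ctrl_a.anchor, ctrl_a.interval, m) if ctrl_a.valid else float("nan")
                s_b = interval_interaction_strength(
                    ctrl_b.anchor, ctrl_b.interval, m) if ctrl_b.valid else float("nan")
                pairs.append(PeakPair(a, b, real, (ctrl_a, ctrl_b),
                                      (s_a, s_b)))
    return pairs


@dataclass
class EnrichmentTestResult:
    n: int
    statistic: float
    pvalue: float
    median_real: float
    median_control: float
    n_dropped: int = 0
    degenerate: bool = False


def paired_enrichment_test(pairs: list[PeakPair],
                           method: str = "signed_rank") -> EnrichmentTestResult:
    """Real-vs-control interaction strength test over peak pairs.

    Default is the two-sided Wilcoxon signed-rank test on per-pair
    differences (real − mean valid control), exact for n <= 25 without
    zeros/ties, normal approximation otherwise. ``method="rank_sum"``
    applies the unpaired Mann-Whitney U instead. Pairs lacking any valid,
    defined control (or a defined real strength) are dropped and counted.
    """
    real, ctrl = [], []
    dropped = 0
    for p in pairs:
        c = p.control_strength
        if np.isfinite(p.real_strength) and np.isfinite(c):
            real.append(p.real_strength)
            ctrl.append(c)
        else:
            dropped += 1
    if not real:
        raise ValueError("no pairs with a defined real and control strength")
    real_arr = np.array(real)
    ctrl_arr = np.array(ctrl)
    diffs = real_arr - ctrl_arr
    med_r = float(np.median(real_arr))
    med_c = float(np.median(ctrl_arr))
    n = diffs.size
    if method == "rank_sum":
        if np.all(real_arr == real_arr[0]) and np.all(ctrl_arr == real_arr[0]):
            return EnrichmentTestResult(n, 0.0, 1.0, med_r, med_c, dropped, True)
        res = stats.mannwhitneyu(real_arr, ctrl_arr, alternative="two-sided")
        return EnrichmentTestResult(n, float(res.statistic), float(res.pvalue),
                                    med_r, med_c, dropped)
    if method != "signed_rank":
        raise ValueError(f"unknown method {method!r}")
    if np.all(diffs == 0):
        return EnrichmentTestResult(n, 0.0, 1.0, med_r, med_c, dropped, True)
    nz = diffs[diffs != 0]
    exact_ok = nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size
    res = stats.wilcoxon(diffs, zero_method="wilcox",
                         alternative="two-sided",
                         method="exact" if exact_ok else "approx")
    return EnrichmentTestResult(n, float(res.statistic), float(res.pvalue),
                                med_r, med_c, dropped)
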