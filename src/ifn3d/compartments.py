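"""A/B compartment calling, saddle strength, and region-vs-control ΔPC1.

Compartments are inferred from the eigendecomposition of the Pearson
correlation matrix of the observed-over-expected map. Because the sign and
rank of eigenvectors are arbitrary, the first three eigenvectors are phased
against an activity track (e.g. binned RNA-seq coverage): the one with the
highest absolute correlation is selected and sign-flipped so that positive
values mark the active (A) compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hic import BinTrack, ContactMatrix, observed_over_expected
from .intervals import GenomicInterval


class DegenerateMatrixError(ValueError):
    """Matrix unusable for eigendecomposition (zero-variance rows)."""


@dataclass
class CompartmentResult:
    pc1: BinTrack          # phased compartment score; NaN on masked bins
    eigen_rank: int        # 1-based rank (by |eigenvalue|) of the chosen vector
    phase_correlation: float  # Pearson r with the activity track (> 0)


def compute_compartment_track(m: ContactMatrix,
                              activity: BinTrack) -> CompartmentResult:
    """Call the compartment score track for one chromosome.

    The top three eigenvectors (by eigenvalue magnitude) of the O/E Pearson
    correlation matrix are correlated with ``activity``; the best one is
    returned, oriented so the correlation is positive.
    """
    if activity.n_bins != m.n_bins:
        raise ValueError("activity track does not match matrix binning")
    oe = observed_over_expected(m)
    valid = ~m.mask
    sub = oe[np.ix_(valid, valid)]
    sub = np.nan_to_num(sub, nan=1.0)  # isolated NaN cells: neutral O/E
    row_sd = sub.std(axis=1)
    if np.any(row_sd == 0):
        raise DegenerateMatrixError("zero-variance O/E rows; cannot compute "
                                    "correlation matrix")
    corr = np.corrcoef(sub)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(np.abs(evals))[::-1][:3]
    act = activity.values[valid]
    ok = np.isfinite(act)
    if ok.sum() < 3 or np.nanstd(act) == 0:
        raise ValueError("activity track constant or undefined; cannot phase")
    best_rank, best_r, best_vec = 0, 0.0, None
    for rank, idx in enumerate(order, start=1):
        vec = evecs[:, idx]
        r = float(np.corrcoef(vec[ok], act[ok])[0, 1])
        if best_vec is None or abs(r) > abs(best_r):
            best_rank, best_r, best_vec = rank, r, vec
    if best_r < 0:
        best_vec = -best_vec
        best_r = -best_r
    values = np.full(m.n_bins, np.nan)
    values[valid] = best_vec
    return CompartmentResult(BinTrack(m.chrom, m.bin_size, values),
                             best_rank, best_r)


@dataclass
class SaddleResult:
    """PC1-quantile aggregated O/E matrix and corner-block strength."""

    saddle: np.ndarray   # (q, q), group 0 = most negative PC1 (B-most)
    strength: float      # (AA + BB) / (2 * AB) over corner blocks


def saddle_strength(m: ContactMatrix, pc1: BinTrack, n_quantiles: int = 10,
                    corner_fraction: float = 0.2) -> SaddleResult:
    """Compartmentalization strength from a saddle aggregation.

    Unmasked bins are ranked by PC1 into ``n_quantiles`` groups; the saddle
    cell (a, b) is the mean O/E over all bin pairs in groups a and b. The
    strength divides within-compartment corners (AA + BB) by twice the
    between-compartment corner, using the extreme ``corner_fraction`` of
    groups on each side.
    """
    if not 0 < corner_fraction <= 0.5:
        raise ValueError("corner_fraction must be in (0, 0.5]")
    oe = observed_over_expected(m)
    valid = ~m.mask & np.isfinite(pc1.values)
    idx = np.where(valid)[0]
    if n_quantiles > idx.size:
        raise ValueError("more quantiles than unmasked bins")
    order = idx[np.argsort(pc1.values[idx], kind="stable")]
    groups = np.array_split(order, n_quantiles)
    q = n_quantiles
    saddle = np.full((q, q), np.nan)
    for a in range(q):
        for b in range(a, q):
            block = oe[np.ix_(groups[a], groups[b])]
            v = float(np.nanmean(block)) if np.isfinite(block).any() else np.nan
            saddle[a, b] = saddle[b, a] = v
    nc = max(1, int(corner_fraction * q))
    bb = np.nanmean(saddle[:nc, :nc])          # B-B (low PC1) corner
    aa = np.nanmean(saddle[q - nc:, q - nc:])  # A-A (high PC1) corner
    ab = np.nanmean(saddle[:nc, q - nc:])      # off corner (symmetric twin equal)
    strength = float((aa + bb) / (2 * ab))
    return SaddleResult(saddle, strength)


@dataclass
class DeltaPC1Stat:
    """Mean PC1 change in one region versus size-matched flank controls."""

    region: GenomicInterval
    mean: float                 # mean ΔPC1 over bins overlapping the region
    control_up: float           # NaN if the upstream control is off-chromosome
    control_down: float
    control_up_valid: bool
    control_down_valid: bool

    @property
    def defined(self) -> bool:
        return np.isfinite(self.mean)


def _region_mean(delta: np.ndarray, bin_size: int,
                 region: GenomicInterval) -> float:
    bins = [b for b in region.bin_range(bin_size) if 0 <= b < delta.size]
    vals = delta[bins] if bins else np.array([])
    vals = vals[np.isfinite(vals)] if vals.size else vals
    return float(vals.mean()) if vals.size else float("nan")


def delta_pc1_regions(pc1_treated: BinTrack, pc1_untreated: BinTrack,
                      regions: list[GenomicInterval],
                      control_offset: int = 1_000_000) -> list[DeltaPC1Stat]:
    """Per-region mean ΔPC1 (treated − untreated) with flank controls.

    Controls are intervals of the region's exact length whose starts sit
    ``control_offset`` bp up- and downstream of the region start. A control
    extending beyond the chromosome is flagged invalid and its mean is NaN,
    never truncated (size-matching is required).
    """
    if not pc1_treated.same_binning(pc1_untreated):
        raise ValueError("PC1 tracks must share chromosome and binning")
    delta = pc1_treated.values - pc1_untreated.values
    bs = pc1_treated.bin_size
    chrom_len = pc1_treated.n_bins * bs
    out = []
    for region in regions:
        mean = _region_mean(delta, bs, region)
        stats_ = {}
        for label, shift in (("up", -control_offset), ("down", control_offset)):
            start = region.start + shift
            end = start + region.length
            if start < 0 or end > chrom_len:
                stats_[label] = (float("nan"), False)
            else:
                ctrl = GenomicInterval(region.chrom, start, end)
                stats_[label] = (_region_mean(delta, bs, ctrl), True)
        out.append(DeltaPC1Stat(region, mean,
                                stats_["up"][0], stats_["down"][0],
                                stats_["up"][1], stats_["down"][1]))
    return out


@dataclass
class RankSumResult:
    statistic: float
    pvalue: float
    degenerate: bool = False


def rank_sum_test(group_a, group_b) -> RankSumResult:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) test.

    Exact null distribution for combined n <= 20 without ties; otherwise the
    tie-corrected normal approximation. If every value in both groups is
    identical the test is degenerate and p = 1 is returned with a flag.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return RankSumResult(float(a.size * b.size / 2), 1.0, degenerate=True)
    n = a.size + b.size
    has_ties = np.unique(pooled).size < n
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankSumResult(float(res.statistic), float(res.pvalue))
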