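"""Template-correlation loop scoring, detection and cluster statistics.

A loop "dot" is scored by sliding a small zero-mean template over the
log(1 + O/E) contact map and computing, at each position within the scanned
distance band, the Pearson correlation between the template and the local
window. Scores therefore live in [-1, 1] and are invariant to affine
rescaling of the map — which makes them comparable across conditions once
coverage is equalized by subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hic import ContactMatrix, mask_low_coverage, ice_balance, \
    observed_over_expected, subsample_counts
from .intervals import GenomicInterval, check_disjoint


@dataclass
class LoopKernel:
    """Odd-sized square template with zero mean and unit variance."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        k = v.shape[0]
        if v.ndim != 2 or v.shape[0] != v.shape[1] or k % 2 == 0:
            raise ValueError("kernel must be square with odd size")
        if abs(v.mean()) > 1e-9 or abs(v.std() - 1) > 1e-9:
            raise ValueError("kernel must have zero mean and unit variance")
        self.values = v

    @property
    def size(self) -> int:
        return self.values.shape[0]

    @property
    def half(self) -> int:
        return self.values.shape[0] // 2


def gaussian_dot_kernel(size: int = 17, sigma: float = 1.5) -> LoopKernel:
    """Centered Gaussian dot, standardized to zero mean / unit variance.

    The center is enriched relative to the surrounding ring, mimicking the
    focal contact enrichment of a chromatin loop on the O/E map.
    """
    if size % 2 == 0 or size < 3:
        raise ValueError("size must be odd and >= 3")
    half = size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1]
    g = np.exp(-(x**2 + y**2) / (2 * sigma**2))
    g = g - g.mean()
    g = g / g.std()
    return LoopKernel(g)


def _log_oe(m: ContactMatrix) -> np.ndarray:
    return np.log1p(observed_over_expected(m))


def _score_cells(L: np.ndarray, kernel: LoopKernel,
                 cells: tuple[np.ndarray, np.ndarray],
                 min_valid_fraction: float = 0.8,
                 chunk: int = 20_000) -> np.ndarray:
    """Pearson score of the kernel vs the window around each (i, j) cell.

    ``L`` is the log(1+O/E) map with NaN on invalid cells; windows with
    fewer than ``min_valid_fraction`` valid cells, or zero variance, score
    NaN.
    """
    k = kernel.size
    hw = kernel.half
    n = L.shape[0]
    Lp = np.full((n + 2 * hw, n + 2 * hw), np.nan)
    Lp[hw:hw + n, hw:hw + n] = L
    kv = kernel.values.ravel()
    di, dj = np.mgrid[0:k, 0:k]
    di, dj = di.ravel(), dj.ravel()
    ci, cj = cells
    out = np.full(ci.size, np.nan)
    min_valid = min_valid_fraction * k * k
    for lo in range(0, ci.size, chunk):
        hi = min(lo + chunk, ci.size)
        wins = Lp[ci[lo:hi, None] + di[None, :], cj[lo:hi, None] + dj[None, :]]
        vm = np.isfinite(wins)
        nv = vm.sum(axis=1)
        ok = nv >= min_valid
        if not ok.any():
            continue
        w = np.where(vm, wins, 0.0)
        kvm = kv[None, :] * vm
        sx = w.sum(axis=1)
        sy = kvm.sum(axis=1)
        sxx = (w * w).sum(axis=1)
        syy = (kvm * kv[None, :]).sum(axis=1)
        sxy = (w * kv[None, :]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sxy - sx * sy / nv
            varx = sxx - sx**2 / nv
            vary = syy - sy**2 / nv
            r = cov / np.sqrt(varx * vary)
        r[~ok | (varx <= 1e-12) | (vary <= 1e-12)] = np.nan
        out[lo:hi] = r
    return out


def _band_cells(n: int, bin_size: int, min_dist: int,
                max_dist: int) -> tuple[np.ndarray, np.ndarray]:
    dmin = max(1, -(-min_dist // bin_size))  # ceil; diagonal never scanned
    dmax = min(n - 1, max_dist // bin_size)
    ii, jj = [], []
    for d in range(dmin, dmax + 1):
        i = np.arange(0, n - d)
        ii.append(i)
        jj.append(i + d)
    if not ii:
        return np.array([], dtype=int), np.array([], dtype=int)
    return np.concatenate(ii), np.concatenate(jj)


def score_map(m: ContactMatrix, kernel: LoopKernel,
              min_dist: int = 0, max_dist: int = 10_000_000,
              min_valid_fraction: float = 0.8) -> np.ndarray:
    """Dense score matrix (NaN outside the scanned band / invalid windows).

    Scores are computed on log(1 + O/E) of the balanced matrix for every
    upper-triangle cell whose genomic distance lies in
    ``[min_dist, max_dist]``; windows need >= ``min_valid_fraction`` valid
    cells.
    """
    n = m.n_bins
    if kernel.size > n:
        raise ValueError("kernel larger than the scannable band")
    L = _log_oe(m)
    ci, cj = _band_cells(n, m.bin_size, min_dist, max_dist)
    scores = np.full((n, n), np.nan)
    if ci.size:
        scores[ci, cj] = _score_cells(L, kernel, (ci, cj), min_valid_fraction)
    return scores


@dataclass
class LoopCall:
    """One called loop: two single-bin anchors and a Pearson score."""

    chrom: str
    bin1: int
    bin2: int
    score: float
    resolution: int

    def __post_init__(self) -> None:
        if self.bin1 >= self.bin2:
            raise ValueError("anchor1 must precede anchor2")

    @property
    def anchor1(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.bin1 * self.resolution,
                               (self.bin1 + 1) * self.resolution)

    @property
    def anchor2(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.bin2 * self.resolution,
                               (self.bin2 + 1) * self.resolution)

    @property
    def length(self) -> int:
        """Anchor separation, midpoint to midpoint."""
        return (self.bin2 - self.bin1) * self.resolution

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.bin1}-{self.bin2}"


def detect_loops(scores: np.ndarray, chrom: str, resolution: int,
                 threshold: float = 0.35,
                 min_separation: int = 3) -> list[LoopCall]:
    """Greedy non-maximum suppression over the score map.

    Cells above ``threshold`` are visited best-first; a cell is called only
    if no already-called loop lies within ``min_separation`` bins
    (Chebyshev distance). Deterministic: ties broken by (bin1, bin2).
    """
    if not -1 < threshold < 1:
        raise ValueError("threshold must be in (-1, 1)")
    cand = np.argwhere(np.nan_to_num(scores, nan=-2.0) >= threshold)
    cand = cand[cand[:, 0] < cand[:, 1]]
    if cand.size == 0:
        return []
    vals = scores[cand[:, 0], cand[:, 1]]
    order = np.lexsort((cand[:, 1], cand[:, 0], -vals))
    kept: list[tuple[int, int, float]] = []
    for idx in order:
        i, j, v = int(cand[idx, 0]), int(cand[idx, 1]), float(vals[idx])
        if all(max(abs(i - ki), abs(j - kj)) >= min_separation
               for ki, kj, _ in kept):
            kept.append((i, j, v))
    kept.sort()
    return [LoopCall(chrom, i, j, v, resolution) for i, j, v in kept]


def quantify_loops(positions: list[LoopCall],
                   matrices: dict[str, ContactMatrix],
                   kernel: LoopKernel,
                   seed: int,
                   min_dist: int = 0, max_dist: int = 10_000_000,
                   mask_quantile: float = 0.0,
                   balance_tol: float = 1e-6) -> pd.DataFrame:
    """Score fixed loop positions in each condition at equal coverage.

    Every condition's matrix is subsampled to the smallest total, masked,
    balanced, and scored only at the given positions. Positions outside the
    scanning band score NaN. Returns a loop-id x condition table.
    """
    if not matrices:
        raise ValueError("no condition matrices given")
    totals = {c: m.total for c, m in matrices.items()}
    target = int(min(totals.values()))
    seeds = {c: seed + k for k, c in enumerate(sorted(matrices))}
    cells_i = np.array([p.bin1 for p in positions], dtype=int)
    cells_j = np.array([p.bin2 for p in positions], dtype=int)
    table = {}
    for cond in sorted(matrices):
        sub = subsample_counts(matrices[cond], target, seeds[cond])
        sub = mask_low_coverage(sub, mask_quantile)
        sub = ice_balance(sub, tol=balance_tol)
        L = _log_oe(sub)
        s = _score_cells(L, kernel, (cells_i, cells_j))
        dist = (cells_j - cells_i) * sub.bin_size
        s[(dist < min_dist) | (dist > max_dist)] = np.nan
        table[cond] = s
    return pd.DataFrame(table, index=[p.id for p in positions])


@dataclass
class ClusterLoopStats:
    """Intra/inter loop scores for one cluster and their median ratio."""

    cluster: GenomicInterval
    intra_scores: list[float]
    inter_scores: list[float]

    @property
    def ratio(self) -> float:
        """median(inter) / median(intra); NaN when undefined."""
        if not self.intra_scores or not self.inter_scores:
            return float("nan")
        mi = float(np.median(self.intra_scores))
        if mi == 0:
            return float("nan")
        return float(np.median(self.inter_scores)) / mi


def classify_cluster_loops(loops: list[LoopCall],
                           clusters: list[GenomicInterval],
                           max_length: int = 500_000,
                           min_score: float | None = None
                           ) -> list[ClusterLoopStats]:
    """Split loops touching each cluster into intra- and inter-cluster sets.

    A loop is considered when at least one anchor midpoint lies inside a
    cluster, its length is <= ``max_length``, and (optionally) its score
    passes ``min_score``. Intra: both anchors in the same cluster; inter:
    exactly one anchor inside. Loops bridging two different clusters are
    excluded from both categories.
    """
    check_disjoint(clusters)
    stats_ = {id(c): ClusterLoopStats(c, [], []) for c in clusters}

    def find(chrom: str, pos: int) -> GenomicInterval | None:
        for c in clusters:
            if c.contains_point(chrom, pos):
                return c
        return None

    for lp in loops:
        if lp.length > max_length:
            continue
        if min_score is not None and lp.score < min_score:
            continue
        c1 = find(lp.chrom, lp.anchor1.midpoint)
        c2 = find(lp.chrom, lp.anchor2.midpoint)
        if c1 is None and c2 is None:
            continue
        if c1 is c2:
            stats_[id(c1)].intra_scores.append(lp.score)
        elif c1 is not None and c2 is not None:
            continue  # bridges two clusters: neither intra nor inter
        else:
            c = c1 if c1 is not None else c2
            stats_[id(c)].inter_scores.append(lp.score)
    return [stats_[id(c)] for c in clusters]


def loop_score_correlation(scores_a: pd.Series, scores_b: pd.Series) -> float:
    """Spearman correlation of per-loop scores between two samples.

    Requires >= 3 shared loops with defined scores in both tables.
    """
    shared = scores_a.index.intersection(scores_b.index)
    a = scores_a.loc[shared].astype(float)
    b = scores_b.loc[shared].astype(float)
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise ValueError("need at least 3 shared loops with defined scores")
    rho, _ = stats.spearmanr(a[ok], b[ok])
    return float(rho)


# ---------------------------------------------------------------------------
# BEDPE I/O

def write_bedpe(loops: list[LoopCall], path) -> None:
    rows = []
    for lp in loops:
        a1, a2 = lp.anchor1, lp.anchor2
        rows.append((lp.chrom, a1.start, a1.end, lp.chrom, a2.start, a2.end,
                     lp.id, f"{lp.score:.4f}"))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path) -> list[LoopCall]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for r in df.itertuples(index=False):
        res = int(r[2]) - int(r[1])
        out.append(LoopCall(str(r[0]), int(r[1]) // res, int(r[4]) // res,
                            float(r[7]), res))
    return out
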