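"""Contact-matrix data model, I/O, balancing, normalization and similarity.

A :class:`ContactMatrix` holds one chromosome's symmetric binned cis contact
map with raw counts, optional ICE balancing weights, and a per-bin exclusion
mask for low-coverage bins. All downstream analyses (compartments, loop
scoring, regulatory-pair strengths) consume this container.

The native on-disk format is a sparse TSV dialect::

    #chrom<TAB>bin_size<TAB>n_bins
    bin_i<TAB>bin_j<TAB>count        (i <= j, upper triangle)

``.cool`` files are supported through the optional ``cooler`` dependency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage


class BalanceError(RuntimeError):
    """ICE iteration failed to converge."""


@dataclass
class ContactMatrix:
    """Symmetric binned cis contact map for a single chromosome.

    Parameters
    ----------
    chrom : chromosome name.
    bin_size : bin width in base pairs.
    counts : (n, n) symmetric non-negative raw count matrix.
    weights : per-bin ICE balancing factors; NaN on masked bins.
    mask : per-bin boolean, True = excluded (low coverage).
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    weights: np.ndarray | None = None
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        n = self.counts.shape[0]
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError("mask length must match bin count")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (n,):
                raise ValueError("weights length must match bin count")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def chrom_length(self) -> int:
        return self.n_bins * self.bin_size

    @property
    def total(self) -> float:
        """Total contacts: sum over the upper triangle including the diagonal."""
        iu = np.triu_indices(self.n_bins)
        return float(self.counts[iu].sum())

    def balanced(self) -> np.ndarray:
        """Weight-corrected matrix ``counts[i,j] * w_i * w_j``; NaN on masked."""
        if self.weights is None:
            raise ValueError("matrix is not balanced; run ice_balance first")
        b = self.counts * np.outer(self.weights, self.weights)
        b[self.mask, :] = np.nan
        b[:, self.mask] = np.nan
        return b

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.chrom, self.bin_size, self.counts.copy(),
            None if self.weights is None else self.weights.copy(),
            self.mask.copy(),
        )


# ---------------------------------------------------------------------------
# I/O

def write_matrix(m: ContactMatrix, path: str | Path, format: str = "tsv-sparse") -> None:
    if format == "cooler":
        _write_cool(m, path)
        return
    if format != "tsv-sparse":
        raise ValueError(f"unknown format {format!r}")
    iu, ju = np.triu_indices(m.n_bins)
    vals = m.counts[iu, ju]
    keep = vals != 0
    with open(path, "w") as fh:
        fh.write(f"#{m.chrom}\t{m.bin_size}\t{m.n_bins}\n")
        for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
            v = int(v) if float(v).is_integer() else v
            fh.write(f"{i}\t{j}\t{v}\n")


def read_matrix(path: str | Path, format: str = "tsv-sparse") -> ContactMatrix:
    if format == "cooler":
        return _read_cool(path)
    if format != "tsv-sparse":
        raise ValueError(f"unknown format {format!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError("missing header line '#chrom<TAB>bin_size<TAB>n_bins'")
        try:
            chrom, bin_size, n_bins = header[1:].split("\t")
            bin_size, n_bins = int(bin_size), int(n_bins)
        except ValueError as e:
            raise ValueError(f"malformed header {header!r}") from e
        counts = np.zeros((n_bins, n_bins))
        seen: dict[tuple[int, int], float] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 3 fields, got {len(parts)}")
            i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            if v < 0:
                raise ValueError(f"line {lineno}: negative count {v}")
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise ValueError(f"line {lineno}: bin index out of range ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen and seen[key] != v:
                raise ValueError(
                    f"line {lineno}: asymmetric input, conflicting values for "
                    f"cell {key}: {seen[key]} vs {v}"
                )
            seen[key] = v
            counts[key[0], key[1]] = v
            counts[key[1], key[0]] = v
    return ContactMatrix(chrom, bin_size, counts)


def _write_cool(m: ContactMatrix, path: str | Path) -> None:
    try:
        import cooler
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError(
            "cooler is required for .cool output; install ifn3d[cool]"
        ) from e
    import pandas as pd  # local: only needed here

    bins = pd.DataFrame({
        "chrom": m.chrom,
        "start": np.arange(m.n_bins) * m.bin_size,
        "end": np.minimum(np.arange(1, m.n_bins + 1) * m.bin_size, m.chrom_length),
    })
    iu, ju = np.triu_indices(m.n_bins)
    vals = m.counts[iu, ju]
    keep = vals != 0
    pixels = pd.DataFrame({"bin1_id": iu[keep], "bin2_id": ju[keep],
                           "count": vals[keep]})
    cooler.create_cooler(str(path), bins, pixels)


def _read_cool(path: str | Path) -> ContactMatrix:
    try:
        import cooler
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError(
            "cooler is required for .cool input; install ifn3d[cool]"
        ) from e
    clr = cooler.Cooler(str(path))
    if len(clr.chromnames) != 1:
        raise ValueError("expected a single-chromosome cooler file")
    chrom = clr.chromnames[0]
    counts = clr.matrix(balance=False).fetch(chrom).astype(float)
    return ContactMatrix(chrom, clr.binsize, counts)


@dataclass
class BinTrack:
    """Per-bin scalar values aligned to a contact matrix binning.

    NaN marks undefined values (e.g. masked bins).
    """

    chrom: str
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def same_binning(self, other: "BinTrack") -> bool:
        return (self.chrom == other.chrom and self.bin_size == other.bin_size
                and self.n_bins == other.n_bins)


def read_bedgraph(path: str | Path, chrom: str, bin_size: int,
                  n_bins: int) -> BinTrack:
    """Average a bedGraph track into bins by overlap-weighted mean."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    df = df[df["chrom"].astype(str) == chrom]
    num = np.zeros(n_bins)
    den = np.zeros(n_bins)
    for start, end, value in zip(df["start"], df["end"], df["value"]):
        b0 = int(start) // bin_size
        b1 = min((int(end) - 1) // bin_size, n_bins - 1)
        for b in range(b0, b1 + 1):
            ov = min(int(end), (b + 1) * bin_size) - max(int(start), b * bin_size)
            if ov > 0:
                num[b] += ov * value
                den[b] += ov
    vals = np.full(n_bins, np.nan)
    nz = den > 0
    vals[nz] = num[nz] / den[nz]
    return BinTrack(chrom, bin_size, vals)


def write_bedgraph(track: BinTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            if np.isfinite(v):
                fh.write(f"{track.chrom}\t{i * track.bin_size}\t"
                         f"{(i + 1) * track.bin_size}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# Masking and balancing

def mask_low_coverage(m: ContactMatrix, quantile: float = 0.02) -> ContactMatrix:
    """Mask bins with zero marginal or marginal below the given quantile
    of the nonzero marginals. Returns a new matrix; weights are reset."""
    if not 0 <= quantile < 1:
        raise ValueError("quantile must be in [0, 1)")
    marg = m.counts.sum(axis=0)
    nonzero = marg[marg > 0]
    if nonzero.size == 0:
        raise ValueError("all bins have zero coverage")
    thr = np.quantile(nonzero, quantile)
    mask = (marg == 0) | (marg < thr)
    if mask.all():
        raise ValueError("low-coverage filter masked every bin")
    return ContactMatrix(m.chrom, m.bin_size, m.counts.copy(), None, mask)


def ice_balance(m: ContactMatrix, tol: float = 1e-6,
                max_iter: int = 1000) -> ContactMatrix:
    """Iterative correction: find per-bin weights equalizing row sums.

    Weights are scaled so the mean unmasked balanced row sum is 1.
    Convergence: coefficient of variation of unmasked row sums < ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    valid = ~m.mask
    sub = m.counts[np.ix_(valid, valid)]
    if sub.size == 0:
        raise ValueError("no unmasked bins to balance")
    w = np.ones(sub.shape[0])
    cv = np.inf
    for _ in range(max_iter):
        s = (w[:, None] * w[None, :] * sub).sum(axis=1)
        mean_s = s.mean()
        if mean_s == 0:
            raise BalanceError("balancing degenerate: zero row sums")
        cv = s.std() / mean_s
        if cv < tol:
            break
        w = w / (s / mean_s)
    else:
        raise BalanceError(
            f"ICE did not converge in {max_iter} iterations (final CV {cv:.3g})"
        )
    # scale so mean unmasked row sum of the balanced matrix equals 1
    s = (w[:, None] * w[None, :] * sub).sum(axis=1)
    w = w / np.sqrt(s.mean())
    weights = np.full(m.n_bins, np.nan)
    weights[valid] = w
    return ContactMatrix(m.chrom, m.bin_size, m.counts.copy(), weights,
                         m.mask.copy())


# ---------------------------------------------------------------------------
# Expected / observed-over-expected

def expected_profile(m: ContactMatrix, use_balanced: bool = True) -> np.ndarray:
    """Mean contact value at each bin distance, over unmasked cells.

    Returns an array of length ``n_bins``; NaN where a distance has no
    unmasked cells.
    """
    x = m.balanced() if use_balanced else np.where(
        m.mask[:, None] | m.mask[None, :], np.nan, m.counts)
    n = m.n_bins
    E = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(x, d)
        if np.isfinite(diag).any():
            E[d] = np.nanmean(diag)
    return E


def observed_over_expected(m: ContactMatrix, E: np.ndarray | None = None,
                           use_balanced: bool = True) -> np.ndarray:
    """O/E matrix: each cell divided by the expected value at its distance."""
    x = m.balanced() if use_balanced else np.where(
        m.mask[:, None] | m.mask[None, :], np.nan, m.counts)
    if E is None:
        E = expected_profile(m, use_balanced=use_balanced)
    n = m.n_bins
    dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    Em = E[dist]
    if np.any((Em == 0) & (np.nan_to_num(x) > 0)):
        raise ValueError("expected value 0 at a distance with observed counts")
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = x / Em
    return oe


# ---------------------------------------------------------------------------
# Merging, subsampling, log-ratio

def merge_matrices(ms: list[ContactMatrix]) -> ContactMatrix:
    """Cell-wise sum of raw counts across replicates; mask recomputed
    (zero-marginal bins only — re-apply mask_low_coverage for stricter
    filtering)."""
    if not ms:
        raise ValueError("nothing to merge")
    first = ms[0]
    for m in ms[1:]:
        if m.chrom != first.chrom or m.bin_size != first.bin_size:
            raise ValueError("cannot merge matrices with different binning")
        if m.counts.shape != first.counts.shape:
            raise ValueError("cannot merge matrices of different shape")
    counts = np.sum([m.counts for m in ms], axis=0)
    marg = counts.sum(axis=0)
    return ContactMatrix(first.chrom, first.bin_size, counts, None, marg == 0)


def subsample_counts(m: ContactMatrix, target_total: int,
                     seed: int | np.random.Generator) -> ContactMatrix:
    """Multinomial thinning of the upper triangle to an exact total.

    Each retained contact lands in a cell with probability proportional to
    its original count, so per-cell marginals are Binomial(total, p_cell).
    ``target_total == total`` returns an identical copy.
    """
    total = m.total
    if target_total > total:
        raise ValueError(f"target_total {target_total} exceeds total {total}")
    if target_total == total:
        return m.copy()
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    iu, ju = np.triu_indices(m.n_bins)
    vals = m.counts[iu, ju]
    p = vals / vals.sum()
    new_vals = rng.multinomial(int(target_total), p).astype(float)
    counts = np.zeros_like(m.counts)
    counts[iu, ju] = new_vals
    counts = counts + np.triu(counts, 1).T
    return ContactMatrix(m.chrom, m.bin_size, counts, None, m.mask.copy())


def log_ratio_map(m1: ContactMatrix, m2: ContactMatrix,
                  pseudocount: float = 1.0) -> np.ndarray:
    """log2 ratio of the two raw maps after scaling m1's total to m2's.

    A fixed-bin stand-in for flexible-binning ratio plots: red (positive)
    marks interactions gained in m1 relative to m2.
    """
    if m1.counts.shape != m2.counts.shape:
        raise ValueError("shape mismatch")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    s = m2.total / m1.total
    return np.log2((m1.counts * s + pseudocount) / (m2.counts + pseudocount))


# ---------------------------------------------------------------------------
# Stratum-adjusted correlation (replicate similarity)

@dataclass
class SCCResult:
    """Stratum-adjusted correlation between two contact maps.

    ``scc = sum(w_k * r_k) / sum(w_k)`` over distance strata ``k``, with
    ``r_k`` the Pearson correlation within stratum ``k`` of the smoothed
    maps and ``w_k = N_k * sigma_1k * sigma_2k``.
    """

    scc: float
    stratum_corr: np.ndarray
    stratum_weight: np.ndarray


def _truncated_mean_smooth(x: np.ndarray, valid: np.ndarray, h: int) -> np.ndarray:
    """(2h+1)^2 mean filter over valid cells, truncated at borders."""
    if h == 0:
        out = np.where(valid, x, np.nan)
        return out
    size = 2 * h + 1
    num = ndimage.uniform_filter(np.where(valid, x, 0.0), size=size,
                                 mode="constant", cval=0.0)
    den = ndimage.uniform_filter(valid.astype(float), size=size,
                                 mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den
    sm[~valid] = np.nan
    return sm


def scc(m1: ContactMatrix, m2: ContactMatrix, h: int = 1,
        max_distance: int = 1_000_000) -> SCCResult:
    """Stratum-adjusted correlation coefficient between two maps.

    Both raw maps are smoothed with a (2h+1)x(2h+1) truncated mean filter,
    then correlated within each genomic-distance stratum up to
    ``max_distance``; stratum correlations are combined with weights
    ``N_k * sigma_1k * sigma_2k``. Zero-variance strata get weight 0.
    """
    if m1.counts.shape != m2.counts.shape or m1.bin_size != m2.bin_size:
        raise ValueError("matrices must share shape and bin size")
    if h < 0:
        raise ValueError("h must be >= 0")
    bin_valid = ~(m1.mask | m2.mask)
    cell_valid = bin_valid[:, None] & bin_valid[None, :]
    s1 = _truncated_mean_smooth(m1.counts, cell_valid, h)
    s2 = _truncated_mean_smooth(m2.counts, cell_valid, h)
    kmax = min(m1.n_bins - 1, max_distance // m1.bin_size)
    rs, ws = [], []
    for d in range(kmax + 1):
        x = np.diagonal(s1, d)
        y = np.diagonal(s2, d)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 2:
            rs.append(np.nan)
            ws.append(0.0)
            continue
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            rs.append(np.nan)
            ws.append(0.0)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rs.append(r)
        ws.append(x.size * sx * sy)
    rs_arr = np.array(rs)
    ws_arr = np.array(ws)
    wsum = ws_arr.sum()
    if wsum == 0:
        raise ValueError("no stratum with variance in both matrices")
    val = float(np.nansum(ws_arr * np.nan_to_num(rs_arr)) / wsum)
    return SCCResult(val, rs_arr, ws_arr)
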