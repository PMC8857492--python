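"""Genomic intervals and plain-text interval formats.

All coordinates are 0-based, half-open: an interval covers
``[start, end)`` and bin ``i`` of a binned track covers
``[i * bin_size, (i + 1) * bin_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # integer midpoint, rounded toward the start on odd lengths
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def bin_range(self, bin_size: int) -> range:
        """Indices of all bins whose interval intersects this one."""
        return range(self.start // bin_size, (self.end - 1) // bin_size + 1)


def check_disjoint(intervals: Sequence[GenomicInterval]) -> None:
    """Raise ValueError if any two intervals on the same chromosome overlap."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda x: x.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping intervals on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


def centered_interval(chrom: str, center: int, size: int,
                      name: str | None = None) -> GenomicInterval:
    """Interval of ``size`` bp centered at ``center``.

    On odd sizes the extra base goes downstream, i.e. the start is rounded
    toward the chromosome start, so ``midpoint`` recovers ``center`` exactly.
    """
    start = center - size // 2
    return GenomicInterval(chrom, start, start + size, name=name)


# ---------------------------------------------------------------------------
# BED-family readers/writers (plain TSV; tabular work delegated to pandas)

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ into intervals; column 4 (if present) becomes the name."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = df[3] if df.shape[1] > 3 else [None] * len(df)
    return [
        GenomicInterval(str(c), int(s), int(e), name=None if n is None else str(n))
        for c, s, e, n in zip(df[0], df[1], df[2], names)
    ]


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    rows = [
        (iv.chrom, iv.start, iv.end, iv.name if iv.name is not None else ".",
         0, ".")
        for iv in intervals
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class Gene:
    """Gene body with strand; TSS is ``start`` on '+' and ``end`` on '-'."""

    interval: GenomicInterval
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def id(self) -> str | None:
        return self.interval.name


def read_genes(path: str | Path) -> list[Gene]:
    """Read genes from BED6-style TSV (chrom start end name score strand)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError("gene file needs 6 columns: chrom start end name score strand")
    return [
        Gene(GenomicInterval(str(r[0]), int(r[1]), int(r[2]), name=str(r[3])),
             strand=str(r[5]))
        for r in df.itertuples(index=False)
    ]


def write_genes(genes: Iterable[Gene], path: str | Path) -> None:
    rows = [
        (g.interval.chrom, g.interval.start, g.interval.end,
         g.interval.name or ".", 0, g.strand)
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
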