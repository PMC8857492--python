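"""RNA-seq / ATAC-seq integration: induction classes and ISGF3 dependence.

Differential tables are consumed, not fitted: each is a DataFrame with
columns ``id``, ``log2fc``, ``padj`` (or an ``id`` index). The rules here
reproduce the classification logic applied to interferon-stimulated genes:

* type-specific induction — significantly up in one IFN type but not the
  other (log2FC >= 1, padj <= 0.05; other type's log2FC < 1);
* induction strata — extreme (log2FC > 5) vs moderate (1 <= log2FC <= 5);
* the top-200 induced genes by log2FC among significant ones;
* ISGF3 dependence of accessibility — genes whose induced accessibility
  gain is lost in Irf9-deficient cells — and the resulting 2x2
  contingency comparison between IFN types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Gene
from .reginter import Peak

DEFAULT_FC = 1.0
DEFAULT_PADJ = 0.05
EXTREME_FC = 5.0


def _table(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize a differential table to be indexed by feature id."""
    if "id" in df.columns:
        df = df.set_index("id")
    missing = {"log2fc", "padj"} - set(df.columns)
    if missing:
        raise ValueError(f"differential table lacks columns {sorted(missing)}")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ValueError("padj values must lie in [0, 1]")
    return df


def _sig_up(df: pd.DataFrame, fc: float = DEFAULT_FC,
            padj: float = DEFAULT_PADJ) -> pd.Series:
    return (df["log2fc"] >= fc) & (df["padj"] <= padj)


def _sig_down(df: pd.DataFrame, fc: float = DEFAULT_FC,
              padj: float = DEFAULT_PADJ) -> pd.Series:
    return (df["log2fc"] <= -fc) & (df["padj"] <= padj)


def classify_type_specific(tbl_a: pd.DataFrame, tbl_b: pd.DataFrame,
                           fc_thresh: float = DEFAULT_FC,
                           padj_thresh: float = DEFAULT_PADJ) -> pd.DataFrame:
    """Per-gene induction class across two IFN-type contrasts.

    Classes: ``a_specific`` (up in A, log2FC_b < fc_thresh), ``b_specific``
    (symmetric), ``shared`` (up in both), ``none``. Genes present in only
    one table are excluded; their count is in ``df.attrs["n_excluded"]``.
    """
    a = _table(tbl_a)
    b = _table(tbl_b)
    shared_ids = a.index.intersection(b.index)
    n_excluded = len(a.index.union(b.index)) - len(shared_ids)
    a = a.loc[shared_ids]
    b = b.loc[shared_ids]
    up_a = _sig_up(a, fc_thresh, padj_thresh)
    up_b = _sig_up(b, fc_thresh, padj_thresh)
    cls = pd.Series("none", index=shared_ids, name="class")
    cls[up_a & (b["log2fc"] < fc_thresh)] = "a_specific"
    cls[up_b & (a["log2fc"] < fc_thresh)] = "b_specific"
    cls[up_a & up_b] = "shared"
    out = pd.DataFrame({"class": cls,
                        "log2fc_a": a["log2fc"], "padj_a": a["padj"],
                        "log2fc_b": b["log2fc"], "padj_b": b["padj"]})
    out.attrs["n_excluded"] = n_excluded
    return out


def select_induced_groups(tbl: pd.DataFrame, mode: str,
                          n_top: int = 200,
                          fc_thresh: float = DEFAULT_FC,
                          extreme_fc: float = EXTREME_FC,
                          padj_thresh: float = DEFAULT_PADJ) -> dict[str, list[str]]:
    """Gene groups for accessibility heatmaps.

    ``mode="top200"``: among significant up-regulated genes
    (padj <= 0.05, log2FC >= 1), the ``n_top`` largest by log2FC (ties
    broken by gene id; fewer than ``n_top`` returns all with a warning).
    ``mode="strata"``: ``extreme`` (log2FC > 5) and ``moderate``
    (1 <= log2FC <= 5), both among significant genes.
    """
    df = _table(tbl)
    if df.empty:
        raise ValueError("empty differential table")
    sig = df[_sig_up(df, fc_thresh, padj_thresh)]
    if mode == "top200":
        # descending log2FC, ties broken by gene id (deterministic)
        ranked = sig.iloc[np.lexsort((sig.index, -sig["log2fc"].values))]
        if len(ranked) < n_top:
            warnings.warn(f"only {len(ranked)} significant genes for "
                          f"top-{n_top} selection")
        return {"top": list(ranked.index[:n_top])}
    if mode == "strata":
        return {
            "extreme": list(sig.index[sig["log2fc"] > extreme_fc]),
            "moderate": list(sig.index[(sig["log2fc"] >= fc_thresh)
                                       & (sig["log2fc"] <= extreme_fc)]),
        }
    raise ValueError(f"unknown mode {mode!r}")


def annotate_peaks_to_genes(peaks: list[Peak],
                            genes: list[Gene]) -> pd.DataFrame:
    """Assign each peak to the gene with the nearest TSS to its midpoint.

    Ties break deterministically toward the smaller gene id. Peaks on a
    chromosome without genes are flagged unassigned (gene NaN).
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    rows = []
    for p in peaks:
        cands = by_chrom.get(p.interval.chrom, [])
        if not cands:
            rows.append((p.id, None, np.nan, False))
            continue
        mid = p.interval.midpoint
        best = min(cands, key=lambda g: (abs(g.tss - mid), g.id or ""))
        rows.append((p.id, best.id, abs(best.tss - mid), True))
    return pd.DataFrame(rows, columns=["peak", "gene", "tss_distance",
                                       "assigned"]).set_index("peak")


@dataclass
class ContingencyTable2x2:
    """Labelled 2x2 count table."""

    counts: np.ndarray
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2):
            raise ValueError("table must be 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("grand total must be positive")


def chi_square_2x2(table: ContingencyTable2x2,
                   yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test with 1 df on a 2x2 table.

    Yates continuity correction is off by default. A zero row or column
    margin makes the test undefined and raises.
    """
    t = table.counts
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin: chi-squared undefined")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=yates)
    return float(chi2), float(p)


def _gene_peak_hit(atac: pd.DataFrame, peak2gene: pd.DataFrame,
                   predicate: pd.Series) -> set[str]:
    """Genes with ANY annotated peak satisfying the predicate."""
    hits = atac.index[predicate]
    assigned = peak2gene[peak2gene["assigned"]]
    return set(assigned.loc[assigned.index.intersection(hits), "gene"])


def classify_accessibility_dependence(
    rna_stim: dict[str, pd.DataFrame],
    atac_stim: dict[str, pd.DataFrame],
    atac_knockout: dict[str, pd.DataFrame],
    peak2gene: pd.DataFrame,
    rna_knockout: pd.DataFrame | None = None,
    atac_knockout_homeo: pd.DataFrame | None = None,
    fc_thresh: float = DEFAULT_FC,
    padj_thresh: float = DEFAULT_PADJ,
) -> tuple[pd.DataFrame, ContingencyTable2x2]:
    """ISGF3-dependence categories per IFN type and the 2x2 comparison.

    Per IFN type (keys of the dicts, e.g. ``"ifn_a"``, ``"ifn_b"``):

    * red — RNA up on stimulation AND any annotated peak ATAC-up;
    * blue — red AND any annotated peak ATAC-down in the Irf9-knockout
      contrast (accessibility gain requires ISGF3);
    * homeostatic — (when homeostatic contrasts are given) RNA down in
      resting knockout cells AND a peak ATAC-down there.

    Returns a per-gene label table and the ``{types} x {ISGF3-dependent
    (blue), ISGF3-independent (red minus blue)}`` contingency table.
    """
    types = sorted(rna_stim)
    if sorted(atac_stim) != types or sorted(atac_knockout) != types:
        raise ValueError("rna_stim, atac_stim and atac_knockout must share "
                         "the same contrast keys")
    rows = []
    counts = np.zeros((2, 2), dtype=int)
    if len(types) != 2:
        raise ValueError("expected exactly two IFN-type contrasts")
    homeo_genes: set[str] = set()
    if rna_knockout is not None and atac_knockout_homeo is not None:
        rk = _table(rna_knockout)
        rna_down = set(rk.index[_sig_down(rk, fc_thresh, padj_thresh)])
        atac_down = _gene_peak_hit(
            _table(atac_knockout_homeo), peak2gene,
            _sig_down(_table(atac_knockout_homeo), fc_thresh, padj_thresh))
        homeo_genes = rna_down & atac_down
    for ti, t in enumerate(types):
        rna = _table(rna_stim[t])
        atac = _table(atac_stim[t])
        atac_ko = _table(atac_knockout[t])
        rna_up = set(rna.index[_sig_up(rna, fc_thresh, padj_thresh)])
        atac_up_genes = _gene_peak_hit(atac, peak2gene,
                                       _sig_up(atac, fc_thresh, padj_thresh))
        atac_ko_down_genes = _gene_peak_hit(
            atac_ko, peak2gene, _sig_down(atac_ko, fc_thresh, padj_thresh))
        red = rna_up & atac_up_genes
        blue = red & atac_ko_down_genes
        counts[ti, 0] = len(blue)
        counts[ti, 1] = len(red - blue)
        for g in sorted(rna.index):
            if g in blue:
                cat = "induced_isgf3_dependent"
            elif g in red:
                cat = "induced_isgf3_independent"
            elif g in homeo_genes:
                cat = "homeostatic_isgf3_dependent"
            else:
                cat = "none"
            rows.append((g, t, g in rna_up, g in atac_up_genes,
                         g in atac_ko_down_genes, cat))
    labels = pd.DataFrame(rows, columns=["gene", "ifn_type", "rna_up",
                                         "atac_up", "atac_down_in_ko",
                                         "category"])
    table = ContingencyTable2x2(counts, (types[0], types[1]),
                                ("isgf3_dependent", "isgf3_independent"))
    return labels, table
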