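"""Read deduplication, peak consolidation, fragment counting and QC gates.

Coordinates are 0-based half-open throughout; two intervals overlap when
they share at least one base pair.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import QCThresholds

PEAK_WIDTH = 200
HALF_WIDTH = PEAK_WIDTH // 2


def tn5_shift(starts, ends, plus_shift: int = 4, minus_shift: int = -5):
    """Apply the Tn5 insertion-site correction to raw fragment coordinates.

    Tn5 binds as a homodimer over a 9-bp site; the conventional correction
    moves the fragment start by +4 and the end by -5. The offsets are
    configurable because pipelines differ in whether they shift +4/-5 or
    +4/-4.
    """
    return np.asarray(starts) + plus_shift, np.asarray(ends) + minus_shift


# -------------------------------------------------------------------- dedup

def deduplicate_reads(reads: pd.DataFrame, min_mapq: int = 60,
                      blacklist: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cell-aware removal of likely PCR duplicates.

    Within each cell (barcode) and chromosome, reads sharing the duplicate
    key are collapsed to a single record; identical coordinates seen in
    *different* cells are all retained, since independent cells legitimately
    produce fragments at the same positions. The key is
    ``(start, mate_start, cigar)`` when mate information is present and
    ``(start,)`` otherwise (single-end style data lacks a mate CIGAR).

    Records with ``mapq`` below ``min_mapq``, with a missing barcode, or
    overlapping ``blacklist`` intervals are dropped first. A summary of drop
    counts is attached as ``result.attrs["dropped"]``.

    Parameters
    ----------
    reads
        Columns ``chrom, start, barcode`` and optionally ``mate_start,
        cigar, mapq``.
    """
    df = reads.copy()
    dropped = {"low_mapq": 0, "no_barcode": 0, "blacklist": 0,
               "missing_key": 0, "duplicate": 0}

    if "mapq" in df.columns:
        keep = df["mapq"].to_numpy() >= min_mapq
        dropped["low_mapq"] = int((~keep).sum())
        df = df[keep]
    has_bc = df["barcode"].notna() & (df["barcode"].astype(str) != "")
    dropped["no_barcode"] = int((~has_bc).sum())
    df = df[has_bc]

    if blacklist is not None and len(blacklist) and len(df):
        end = df["end"] if "end" in df.columns else df["start"] + 1
        bad = _interval_overlap_mask(df["chrom"].to_numpy(),
                                     df["start"].to_numpy(),
                                     end.to_numpy(), blacklist)
        dropped["blacklist"] = int(bad.sum())
        df = df[~bad]

    paired = "mate_start" in df.columns or "cigar" in df.columns
    key_cols = ["barcode", "chrom", "start"]
    if paired:
        for col in ("mate_start", "cigar"):
            if col in df.columns:
                missing = df[col].isna()
                if missing.any():
                    dropped["missing_key"] += int(missing.sum())
                    df = df[~missing]
                key_cols.append(col)

    n_before = len(df)
    df = df.drop_duplicates(subset=key_cols, keep="first")
    dropped["duplicate"] = n_before - len(df)
    df = df.reset_index(drop=True)
    df.attrs["dropped"] = dropped
    return df


def _interval_overlap_mask(chroms, starts, ends, intervals: pd.DataFrame):
    """Boolean mask of records overlapping any interval (per chromosome)."""
    mask = np.zeros(len(chroms), dtype=bool)
    for chrom, sub in intervals.groupby("chrom", sort=False):
        sel = chroms == chrom
        if not sel.any():
            continue
        # merge intervals, then binary-search: overlap iff the latest
        # interval starting before the record end also ends after its start
        iv = sub.sort_values("start")
        istarts = iv["start"].to_numpy()
        iends = np.maximum.accumulate(iv["end"].to_numpy())
        idx = np.searchsorted(istarts, ends[sel], side="left") - 1
        ok = idx >= 0
        hit = np.zeros(int(sel.sum()), dtype=bool)
        hit[ok] = iends[idx[ok]] > starts[sel][ok]
        mask[sel] = hit
    return mask


# -------------------------------------------------------- peak consolidation

def trim_and_deduplicate_peaks(sub_peaks: pd.DataFrame) -> pd.DataFrame:
    """Consolidate called sub-peaks into fixed-width non-overlapping peaks.

    Each sub-peak is trimmed to 200 bp centered on its summit
    (``[summit-100, summit+100)``); candidates are then visited in order of
    ascending q-value (ties broken by chrom, start for determinism) and kept
    greedily, discarding any candidate that overlaps an already-kept peak.
    Summits within 100 bp of the contig start are clipped to ``[0, 200)``
    with a warning rather than dropped.

    Returns a coordinate-sorted table with columns
    ``chrom, start, end, summit, q``; all widths are exactly 200 and kept
    peaks are pairwise non-overlapping per chromosome.
    """
    if not len(sub_peaks):
        return pd.DataFrame(columns=["chrom", "start", "end", "summit", "q"])
    q = sub_peaks["q"].to_numpy(dtype=float)
    if np.any((q <= 0) | (q > 1)):
        raise ValueError("q-values must lie in (0, 1]")
    summit = sub_peaks["summit"].to_numpy(dtype=np.int64)
    start = summit - HALF_WIDTH
    clipped = start < 0
    if clipped.any():
        warnings.warn(f"{int(clipped.sum())} summit(s) within {HALF_WIDTH} bp "
                      "of the contig start; clipped to [0, 200)")
        start = np.maximum(start, 0)
    end = start + PEAK_WIDTH
    cand = pd.DataFrame({"chrom": sub_peaks["chrom"].to_numpy(),
                         "start": start, "end": end,
                         "summit": np.clip(summit, start, end - 1), "q": q})
    cand = cand.sort_values(["q", "chrom", "start"], kind="mergesort")

    kept_rows = []
    kept_by_chrom: dict[str, list[int]] = {}
    for row in cand.itertuples(index=False):
        starts = kept_by_chrom.setdefault(row.chrom, [])
        i = bisect_right(starts, row.start)
        # neighbors at i-1 (starts before) and i (starts at/after); widths
        # are fixed at 200 so only adjacent kept peaks can overlap
        if i > 0 and starts[i - 1] + PEAK_WIDTH > row.start:
            continue
        if i < len(starts) and starts[i] < row.end:
            continue
        starts.insert(i, row.start)
        kept_rows.append(row)
    out = pd.DataFrame(kept_rows)
    return (out.sort_values(["chrom", "start"], kind="mergesort")
            .reset_index(drop=True))


# ----------------------------------------------------------------- counting

def count_fragments_in_peaks(fragments: pd.DataFrame, peaks: pd.DataFrame,
                             barcodes=None) -> tuple[sp.csr_matrix, list]:
    """Count fragments overlapping peaks into a sparse cells x peaks matrix.

    A fragment contributes to every peak it shares at least one bp with
    (half-open convention). Peaks must be non-overlapping and sortable per
    chromosome, as produced by :func:`trim_and_deduplicate_peaks`. Fragments
    on chromosomes absent from the peak set count as zero.

    Returns ``(matrix, barcodes)`` with rows following ``barcodes`` (the
    sorted unique fragment barcodes unless an explicit list is given).
    """
    if barcodes is None:
        barcodes = sorted(fragments["barcode"].unique())
    bc_index = {b: i for i, b in enumerate(barcodes)}
    peaks = peaks.reset_index(drop=True)
    peak_pos = {}
    for chrom, sub in peaks.groupby("chrom", sort=False):
        order = sub.sort_values("start")
        peak_pos[chrom] = (order["start"].to_numpy(), order["end"].to_numpy(),
                           order.index.to_numpy())

    rows, cols = [], []
    missing_chroms = set()
    for chrom, sub in fragments.groupby("chrom", sort=False):
        if chrom not in peak_pos:
            missing_chroms.add(chrom)
            continue
        pstart, pend, pidx = peak_pos[chrom]
        fstart = sub["start"].to_numpy()
        fend = sub["end"].to_numpy()
        fbc = sub["barcode"].map(bc_index).to_numpy()
        lo = np.searchsorted(pend, fstart, side="right")
        hi = np.searchsorted(pstart, fend, side="left")
        n_over = hi - lo
        single = n_over == 1
        rows.append(fbc[single])
        cols.append(pidx[lo[single]])
        for k in np.flatnonzero(n_over > 1):
            js = pidx[lo[k]:hi[k]]
            rows.append(np.full(len(js), fbc[k]))
            cols.append(js)
    if missing_chroms:
        warnings.warn("fragments on chromosome(s) absent from the peak set "
                      f"counted as zero: {sorted(missing_chroms)}")
    rows = np.concatenate(rows) if rows else np.array([], dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.array([], dtype=np.int64)
    mat = sp.coo_matrix((np.ones(len(rows), dtype=np.int64), (rows, cols)),
                        shape=(len(barcodes), len(peaks))).tocsr()
    return mat, list(barcodes)


# ----------------------------------------------------------------------- QC

def peak_neighborhoods(peaks: pd.DataFrame, scale: int = 5) -> pd.DataFrame:
    """Dilate peaks to ``scale`` times their full width around the center."""
    center = (peaks["start"] + peaks["end"]) // 2
    half = (peaks["end"] - peaks["start"]) * scale // 2
    return pd.DataFrame({"chrom": peaks["chrom"],
                         "start": np.maximum(center - half, 0),
                         "end": center + half})


def atac_cell_stats(fragments: pd.DataFrame, peaks: pd.DataFrame,
                    promoter_peaks: pd.DataFrame,
                    blacklist: pd.DataFrame | None = None,
                    mito_chrom: str = "chrM",
                    neighborhood_scale: int = 5) -> pd.DataFrame:
    """Per-cell read statistics feeding :func:`atac_cell_qc`."""
    chroms = fragments["chrom"].to_numpy()
    starts = fragments["start"].to_numpy()
    ends = fragments["end"].to_numpy()
    bc = fragments["barcode"]
    nb = peak_neighborhoods(peaks, neighborhood_scale)
    in_nb = _interval_overlap_mask(chroms, starts, ends, nb)
    in_prom = _interval_overlap_mask(chroms, starts, ends, promoter_peaks)
    is_mito = chroms == mito_chrom
    in_bl = (np.zeros(len(fragments), dtype=bool) if blacklist is None
             else _interval_overlap_mask(chroms, starts, ends, blacklist))
    stats = pd.DataFrame({
        "n_reads": bc.groupby(bc).size(),
        "n_neighborhood": pd.Series(in_nb, index=bc.index).groupby(bc).sum(),
        "n_promoter": pd.Series(in_prom, index=bc.index).groupby(bc).sum(),
        "n_mito": pd.Series(is_mito, index=bc.index).groupby(bc).sum(),
        "n_blacklist": pd.Series(in_bl, index=bc.index).groupby(bc).sum(),
    }).fillna(0).astype(np.int64)
    stats.index.name = "barcode"
    return stats


def atac_cell_qc(cell_stats: pd.DataFrame,
                 thresholds: QCThresholds | None = None) -> pd.Series:
    """Boolean per-cell mask implementing the ATAC QC gates.

    Pass iff reads strictly exceed ``min_reads``, the neighborhood and
    promoter fractions are at least their minima, and the mitochondrial and
    blacklist fractions are not more than their maxima (boundary semantics
    read literally: "more than" strict, "at least"/"not more than"
    inclusive).
    """
    t = thresholds or QCThresholds()
    req = ["n_reads", "n_neighborhood", "n_promoter", "n_mito", "n_blacklist"]
    s = cell_stats[req]
    if (s.to_numpy() < 0).any():
        raise ValueError("negative counts in cell stats")
    n = s["n_reads"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = lambda col: np.where(n > 0, s[col].to_numpy() / n, 0.0)  # noqa: E731
        ok = ((n > t.min_reads)
              & (frac("n_neighborhood") >= t.min_frac_in_peak_neighborhood)
              & (frac("n_promoter") >= t.min_frac_promoter)
              & (frac("n_mito") <= t.max_frac_mito)
              & (frac("n_blacklist") <= t.max_frac_blacklist))
    return pd.Series(ok, index=cell_stats.index, name="pass_qc")


def rna_cell_qc(gene_counts: sp.spmatrix, mito_gene_mask,
                thresholds: QCThresholds | None = None) -> np.ndarray:
    """Boolean per-cell mask for the RNA modality.

    Pass iff at least ``rna_min_genes`` genes are detected and the
    mitochondrial read fraction is strictly below ``rna_max_frac_mito``.
    """
    t = thresholds or QCThresholds()
    gene_counts = sp.csr_matrix(gene_counts)
    n_genes = gene_counts.getnnz(axis=1)
    total = np.asarray(gene_counts.sum(axis=1)).ravel()
    mito = np.asarray(
        gene_counts[:, np.asarray(mito_gene_mask, dtype=bool)].sum(axis=1)
    ).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_mito = np.where(total > 0, mito / total, 0.0)
    return (n_genes >= t.rna_min_genes) & (frac_mito < t.rna_max_frac_mito)


# ------------------------------------------------------------ PMA selection

def select_pma_peaks(counts: sp.spmatrix, frac: float = 0.005,
                     min_cells: int | None = None) -> np.ndarray:
    """Peaks-with-minimal-accessibility mask within one cell type.

    Keep a peak iff it has a fragment in at least ``ceil(frac * n_cells)``
    cells, or at least ``min_cells`` cells when ``min_cells`` is given (the
    absolute threshold overrides the fraction, as used for low-count cell
    types).
    """
    counts = sp.csr_matrix(counts)
    n_cells = counts.shape[0]
    if n_cells == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    cells_with_signal = counts.astype(bool).sum(axis=0).A.ravel()
    threshold = (min_cells if min_cells is not None
                 else int(np.ceil(frac * n_cells)))
    return cells_with_signal >= threshold
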