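"""Signed per-cell scores, class-specific peaks, motif enrichment and
fine-mapped SNP prioritization.

A signed score is the mean normalized signal over a positive feature set
minus the mean over a negative set — used for CD4/CD8 lineage scores,
hyper-/hypomethylated region scores and lining/sublining fibroblast
identity scores alike. Motif enrichment in class-specific peaks is a
hypergeometric upper tail with BH correction and display filters; SNP
prioritization overlaps high-PIP variants with peaks and ranks chromatin
classes by z-scored mean accessibility.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .differential import wilcoxon_markers
from .synthetic import SignedSet


# ------------------------------------------------------------- signed score

def signed_score(normalized, feature_names, signed_set: SignedSet
                 ) -> np.ndarray:
    """Per-cell signed score over positive/negative feature sets.

    ``score_i = mean over positive features - mean over negative features``
    of the normalized values; positive scores indicate association with the
    positive set. Linear in the input matrix.
    """
    if not signed_set.positive and not signed_set.negative:
        raise ValueError("both feature sets are empty")
    idx = {f: i for i, f in enumerate(feature_names)}
    missing = [f for f in (*signed_set.positive, *signed_set.negative)
               if f not in idx]
    if missing:
        raise KeyError(f"features absent from matrix: {missing[:5]}")
    x = sp.csc_matrix(normalized)
    score = np.zeros(x.shape[0])
    if signed_set.positive:
        cols = [idx[f] for f in signed_set.positive]
        score += np.asarray(x[:, cols].sum(axis=1)).ravel() / len(cols)
    if signed_set.negative:
        cols = [idx[f] for f in signed_set.negative]
        score -= np.asarray(x[:, cols].sum(axis=1)).ravel() / len(cols)
    return score


def score_group_test(scores, group_mask, alternative: str = "greater"
                     ) -> float:
    """Rank-sum p-value comparing scores of a cell group against the rest.

    ``alternative`` follows the scipy convention for the group relative to
    the complement. The exact null distribution is used for small untied
    samples (both groups at most 25), where the normal approximation is
    poor; constant scores yield p = 1 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    mask = np.asarray(group_mask, dtype=bool)
    a, b = scores[mask], scores[~mask]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(scores) == 0:
        warnings.warn("constant scores; p = 1")
        return 1.0
    small = max(len(a), len(b)) <= 25
    no_ties = len(np.unique(scores)) == len(scores)
    method = "exact" if small and no_ties else "asymptotic"
    return float(scipy.stats.mannwhitneyu(a, b, alternative=alternative,
                                          method=method).pvalue)


def build_signed_sets_from_markers(marker_table: pd.DataFrame,
                                   fdr_max: float, logfc_min: float,
                                   auc_min: float,
                                   name: str = "markers") -> SignedSet:
    """Signed feature sets from a two-group rank-sum marker table.

    The positive set holds features passing ``fdr < fdr_max``,
    ``logFC > logfc_min`` and ``auc > auc_min`` for the first group, the
    negative set those passing for the second group. Standard cutoffs are
    FDR < 0.1, logFC > 0.25, AUC > 0.6 for genes and FDR < 0.1, logFC > 0.1,
    AUC > 0.58 for peaks.
    """
    if not len(marker_table):
        raise ValueError("empty marker table")
    groups = sorted(marker_table["group"].unique())
    if len(groups) != 2:
        raise ValueError("marker table must contain exactly two groups")
    sets = {}
    for g in groups:
        sub = marker_table[marker_table["group"] == g]
        ok = ((sub["fdr"] < fdr_max) & (sub["logFC"] > logfc_min)
              & (sub["auc"] > auc_min))
        sets[g] = sub.loc[ok, "feature"].tolist()
    return SignedSet(name, positive=sets[groups[0]],
                     negative=sets[groups[1]])


# ------------------------------------------------------ class-specific peaks

def class_specific_peaks(normalized, peak_names, class_labels,
                         fdr_max: float = 0.1,
                         log2fc_min: float = 0.5) -> dict:
    """One-vs-rest marker peaks per class (rank-sum, FDR and logFC cutoffs).

    Classes with fewer than 3 cells are skipped with a warning. Returns
    ``{class: [peak, ...]}``.
    """
    labels = np.asarray(class_labels)
    counts = pd.Series(labels).value_counts()
    classes = sorted(counts.index)
    usable = [c for c in classes if counts[c] >= 3]
    for c in set(classes) - set(usable):
        warnings.warn(f"class {c!r} has fewer than 3 cells; skipped")
    if len(usable) < 2:
        raise ValueError("need at least 2 classes")
    mk = wilcoxon_markers(normalized, peak_names, labels, groups=usable)
    out = {}
    for c in usable:
        sub = mk[mk["group"] == c]
        ok = (sub["fdr"] <= fdr_max) & (sub["logFC"] >= log2fc_min)
        out[c] = sub.loc[ok, "feature"].tolist()
    return out


# ----------------------------------------------------------- motif enrichment

def motif_enrichment(class_peak_sets: dict, motif_annot: pd.DataFrame,
                     background_peaks, tf_expression: pd.DataFrame
                     | None = None, motif_tf_gene: pd.Series | None = None,
                     enrich_min: float = 5.0, expr_min: float = 0.05,
                     within_max_frac: float = 0.95) -> pd.DataFrame:
    """Hypergeometric motif enrichment in class-specific peak sets.

    Per (class, motif): the upper-tail hypergeometric p of the motif count
    in the class set against the background universe, BH-adjusted across the
    whole table; the enrichment value is -log10(p_adj). A motif is
    ``selected`` for display when its enrichment is at least ``enrich_min``,
    is maximal or within ``within_max_frac`` of the class's maximal
    enrichment, and (when expression data are supplied) the corresponding
    TF has mean normalized expression of at least ``expr_min`` in the class.
    ``pct_of_max`` scales each motif's enrichment to the percentage of its
    cross-class maximum for heat-map display.

    ``tf_expression`` is a class x gene table of mean normalized expression
    and ``motif_tf_gene`` maps motif names to TF gene names.
    """
    background = [p for p in background_peaks if p in motif_annot.index]
    annot = motif_annot.loc[background]
    M = len(background)
    motif_counts = annot.sum(axis=0)
    rows = []
    for cls in sorted(class_peak_sets):
        peaks = [p for p in class_peak_sets[cls] if p in annot.index]
        n = len(peaks)
        in_set = annot.loc[peaks]
        for motif in annot.columns:
            K = int(motif_counts[motif])
            if K == 0:
                continue  # motif absent from the background universe
            k = int(in_set[motif].sum())
            p = float(scipy.stats.hypergeom.sf(k - 1, M, K, n))
            rows.append((cls, motif, k, n, K, M, p))
    res = pd.DataFrame(rows, columns=["class", "motif", "k_in_set",
                                      "n_set", "K_background",
                                      "M_background", "p"])
    if not len(res):
        res["p_adj"] = []
        res["enrichment"] = []
        res["selected"] = []
        res["pct_of_max"] = []
        return res
    res["p_adj"] = multipletests(res["p"], method="fdr_bh")[1]
    with np.errstate(divide="ignore"):
        res["enrichment"] = -np.log10(res["p_adj"])

    class_max = res.groupby("class")["enrichment"].transform("max")
    selected = ((res["enrichment"] >= enrich_min)
                & (res["enrichment"] >= within_max_frac * class_max))
    if tf_expression is not None and motif_tf_gene is not None:
        expr_ok = []
        for cls, motif in zip(res["class"], res["motif"]):
            gene = motif_tf_gene.get(motif)
            val = (tf_expression.at[cls, gene]
                   if gene is not None and gene in tf_expression.columns
                   and cls in tf_expression.index else 0.0)
            expr_ok.append(val >= expr_min)
        selected &= np.asarray(expr_ok)
    res["selected"] = selected
    motif_max = res.groupby("motif")["enrichment"].transform("max")
    with np.errstate(divide="ignore", invalid="ignore"):
        res["pct_of_max"] = np.where(motif_max > 0,
                                     100.0 * res["enrichment"] / motif_max,
                                     0.0)
    return res


# ---------------------------------------------------------------- SNP overlap

def snp_peak_overlap(snps: pd.DataFrame, peaks: pd.DataFrame,
                     pip_min: float = 0.1) -> pd.DataFrame:
    """Join fine-mapped SNPs with PIP > ``pip_min`` to containing peaks.

    Containment is half-open: a SNP at position ``pos`` matches a peak with
    ``start <= pos < end`` on the same chromosome.
    """
    keep = snps[snps["pip"] > pip_min]
    rows = []
    for chrom, sub in keep.groupby("chrom", sort=False):
        pk = peaks[peaks["chrom"] == chrom].sort_values("start")
        if not len(pk):
            continue
        starts = pk["start"].to_numpy()
        ends = pk["end"].to_numpy()
        pos = sub["pos"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0)
        ok[ok] &= pos[ok] < ends[j[ok]]
        for (_, snp), jj, hit in zip(sub.iterrows(), j, ok):
            if hit:
                peak = pk.iloc[jj]
                rows.append((snp["id"], snp["chrom"], int(snp["pos"]),
                             float(snp["pip"]),
                             peak.get("peak", f"{chrom}:{peak['start']}"),
                             int(peak["start"]), int(peak["end"])))
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "pip",
                                       "peak", "peak_start", "peak_end"])


# ------------------------------------------------ class accessibility profile

def class_accessibility_profile(normalized, peak_names, class_labels,
                                peaks_of_interest,
                                class_cell_type: dict | None = None
                                ) -> dict:
    """Mean class accessibility of selected peaks, z-scored across classes.

    Per peak the mean normalized accessibility per class is standardized
    across the class axis (mean 0, SD 1 per peak); classes with z > 1 are
    called accessible. When ``class_cell_type`` maps classes to broad cell
    types, a one-sided exact rank-sum test per (peak, cell type) compares
    that type's class z-values against the other classes' (small class
    counts make the exact null appropriate).

    Returns ``{"means", "z", "accessible", "cell_type_p"}``; zero-variance
    peaks get NaN z rows and are flagged in ``"degenerate_peaks"``.
    """
    labels = np.asarray(class_labels)
    x = sp.csc_matrix(normalized)
    idx = {p: i for i, p in enumerate(peak_names)}
    cols = [idx[p] for p in peaks_of_interest]
    classes = sorted(pd.unique(labels))
    means = np.vstack([
        np.asarray(x[labels == c][:, cols].mean(axis=0)).ravel()
        for c in classes])  # classes x peaks
    means = pd.DataFrame(means, index=classes, columns=peaks_of_interest)
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=1)
    degenerate = list(means.columns[sd == 0])
    if degenerate:
        warnings.warn(f"zero-variance peak(s), z undefined: {degenerate}")
    z = (means - mu) / sd.replace(0, np.nan)
    accessible = z > 1

    ct_rows = []
    if class_cell_type is not None:
        types = sorted(set(class_cell_type.values()))
        for peak in peaks_of_interest:
            zvals = z[peak]
            for t in types:
                in_t = np.array([class_cell_type[c] == t for c in classes])
                a, b = zvals[in_t], zvals[~in_t]
                if a.isna().any() or b.isna().any() or not len(a) \
                        or not len(b):
                    p = np.nan
                else:
                    p = float(scipy.stats.mannwhitneyu(
                        a, b, alternative="greater", method="exact").pvalue)
                ct_rows.append((peak, t, p))
    cell_type_p = pd.DataFrame(ct_rows, columns=["peak", "cell_type", "p"])
    return {"means": means, "z": z, "accessible": accessible,
            "cell_type_p": cell_type_p, "degenerate_peaks": degenerate}


# --------------------------------------------------------------- bedgraph

def export_class_bedgraph(fragments: pd.DataFrame, cell_groups: dict,
                          region: tuple, group_total_reads: dict
                          | None = None) -> dict:
    """Scaled per-bp coverage tracks within a region, one per cell group.

    ``region`` is ``(chrom, start, end)``; ``cell_groups`` maps group name
    to a collection of barcodes. Coverage is divided by (group total read
    count / 1e7) so that tracks are comparable between groups of different
    sizes; ``group_total_reads`` defaults to each group's fragment count in
    the whole table. Returns ``{group: DataFrame(chrom, start, end, value)}``
    of coverage runs (zero runs omitted).
    """
    chrom, rstart, rend = region
    out = {}
    frag_bc = fragments["barcode"]
    for group, barcodes in cell_groups.items():
        barcodes = set(barcodes)
        sel = frag_bc.isin(barcodes).to_numpy()
        total = (group_total_reads[group] if group_total_reads is not None
                 else int(sel.sum()))
        if total == 0:
            raise ValueError(f"group {group!r} has zero total reads")
        sub = fragments[sel]
        sub = sub[(sub["chrom"] == chrom) & (sub["start"] < rend)
                  & (sub["end"] > rstart)]
        cov = np.zeros(rend - rstart + 1)
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            cov[max(s, rstart) - rstart] += 1
            cov[min(e, rend) - rstart] -= 1
        cov = np.cumsum(cov)[:rend - rstart]
        cov = cov / (total / 1e7)
        # compress to runs
        change = np.flatnonzero(np.diff(cov)) + 1
        bounds = np.concatenate([[0], change, [rend - rstart]])
        rows = [(chrom, rstart + int(b0), rstart + int(b1), float(cov[b0]))
                for b0, b1 in zip(bounds[:-1], bounds[1:])
                if cov[b0] != 0]
        out[group] = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                                 "value"])
    return out
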