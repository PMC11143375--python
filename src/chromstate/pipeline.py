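"""End-to-end orchestration of the superstate analysis on synthetic data.

``run_pipeline`` chains every stage — simulate, dedup, peak consolidation,
counting, QC, chromatin classing, cross-modal transfer, superstate
statistics, differential tests, scores/enrichment/variants and track
export — into one artifact directory. Each stage writes its tables with a
metadata header (config hash, seed, thresholds) plus a machine-readable
JSON summary, and the whole run is a deterministic function of the config.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import QCThresholds, RunConfig, SynthConfig
from .differential import (derive_lineage, lineage_association,
                           nb_lrt_differential, promoter_gene_concordance,
                           pseudobulk_counts, wilcoxon_markers)
from .embedding import (adjust_batch, compute_embedding, log_normalize,
                        select_variable_features, snn_louvain,
                        tfidf_normalize)
from .fragments import (atac_cell_qc, atac_cell_stats,
                        count_fragments_in_peaks, deduplicate_reads,
                        rna_cell_qc, select_pma_peaks,
                        trim_and_deduplicate_peaks)
from .scores import (class_specific_peaks, export_class_bedgraph,
                     motif_enrichment, score_group_test, signed_score,
                     snp_peak_overlap)
from .synthetic import generate_multiome
from .transfer import (class_state_or_matrix, knn_classify,
                       pairwise_lda_auc, within_across_summary)


def demo_config(seed: int = 0) -> RunConfig:
    """A small, fast demonstration configuration.

    Cell depth and QC gates are scaled down together so the demo runs in
    well under a minute; the full-scale QC thresholds remain the package
    defaults in :class:`~chromstate.config.QCThresholds`.
    """
    synth = SynthConfig(n_samples=3, cells_per_sample=300, n_peaks=600,
                        n_genes=300, markers_per_state=10,
                        depth_mu=math.log(800.0), n_snps=50, n_motifs=12,
                        seed=seed)
    qc = QCThresholds(min_reads=200, min_frac_promoter=0.05,
                      rna_min_genes=20)
    return RunConfig(synth=synth, qc=qc, seed=seed)


def _meta(config: RunConfig, **extra) -> dict:
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    meta.update(extra)
    return meta


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full analysis chain and write artifacts to ``outdir``.

    Returns a dictionary of the key in-memory results. Running twice with
    the same config produces byte-identical result files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    # ------------------------------------------------------------ simulate
    ds = generate_multiome(config.synth, include_reads=True)
    io.write_json({"config": config.to_json()}, out / "config.json")
    io.write_fragments_tsv(ds.fragments, out / "fragments.tsv")
    io.write_narrowpeak(ds.sub_peaks, out / "sub_peaks.narrowPeak")
    io.write_result_table(ds.cells, out / "cells_truth.tsv", _meta(config))
    snp_bed = pd.DataFrame({"chrom": ds.snps["chrom"],
                            "start": ds.snps["pos"],
                            "end": ds.snps["pos"] + 1,
                            "id": ds.snps["id"], "pip": ds.snps["pip"]})
    io.write_bed(snp_bed, out / "snps.bed", extra_columns=["id", "pip"])
    io.write_result_table(ds.motif_annot.astype(int), out / "motifs.tsv",
                          _meta(config), index=True)
    io.write_json({name: {"positive": s.positive, "negative": s.negative}
                   for name, s in ds.signed_sets.items()},
                  out / "signed_sets.json")
    summary["simulate"] = {"n_cells": len(ds.cells),
                           "n_peaks": len(ds.peaks),
                           "n_genes": len(ds.genes),
                           "n_reads": len(ds.reads)}

    # --------------------------------------------------------------- dedup
    dedup = deduplicate_reads(ds.reads)
    summary["dedup"] = {"n_in": len(ds.reads), "n_out": len(dedup),
                        "n_unique_truth": ds.reads.attrs["n_unique_truth"],
                        **dedup.attrs["dropped"]}

    # --------------------------------------------------------------- peaks
    peaks = trim_and_deduplicate_peaks(ds.sub_peaks)
    io.write_bed(peaks, out / "peaks.bed", extra_columns=["summit", "q"])
    summary["peaks"] = {"n_sub_peaks": len(ds.sub_peaks),
                        "n_consolidated": len(peaks)}

    # --------------------------------------------------------------- count
    barcodes = ds.cells["barcode"].tolist()
    counts, _ = count_fragments_in_peaks(ds.fragments, peaks, barcodes)
    peak_names = [f"{c}:{s}-{e}" for c, s, e in
                  zip(peaks["chrom"], peaks["start"], peaks["end"])]
    io.write_mtx(counts, barcodes, peak_names, out / "peak_counts")
    summary["count"] = {"total_fragments_in_peaks": int(counts.sum())}

    # ------------------------------------------------------------------ QC
    promoter_truth = ds.peaks[ds.peaks["is_promoter"]]
    stats = atac_cell_stats(ds.fragments, peaks, promoter_truth,
                            neighborhood_scale=config.qc.neighborhood_scale)
    stats = stats.reindex(barcodes).fillna(0).astype(np.int64)
    atac_pass = atac_cell_qc(stats, config.qc)
    mito_mask = np.zeros(len(ds.genes), dtype=bool)  # no mito genes simulated
    rna_pass = rna_cell_qc(ds.gene_counts, mito_mask, config.qc)
    keep = atac_pass.to_numpy() & rna_pass
    qc_table = stats.copy()
    qc_table["atac_pass"] = atac_pass.to_numpy()
    qc_table["rna_pass"] = rna_pass
    io.write_result_table(qc_table.reset_index(), out / "qc.tsv",
                          _meta(config, min_reads=config.qc.min_reads))
    summary["qc"] = {"n_pass": int(keep.sum()), "n_total": len(keep)}

    cells = ds.cells[keep].reset_index(drop=True)
    peak_counts = ds.peak_counts[keep]
    gene_counts = ds.gene_counts[keep]
    n_fragments = np.asarray(peak_counts.sum(axis=1)).ravel()

    # ------------------------------------------------------------- cluster
    binary = (peak_counts > 0).astype(float)
    pma = select_pma_peaks(peak_counts)
    norm = tfidf_normalize(binary[:, np.flatnonzero(pma)],
                           scale=config.tfidf_scale)
    sel = select_variable_features(
        norm, min(config.n_variable_features, norm.shape[1]))
    emb = compute_embedding(norm[:, sel], config.n_components_fine,
                            seed=config.seed)
    emb = adjust_batch(emb, cells["sample"], method=config.batch_method)
    classes = snn_louvain(emb, config.snn_k, config.resolution,
                          seed=config.seed, prune=config.snn_prune)
    cls_table = pd.DataFrame({"barcode": cells["barcode"],
                              "chromatin_class": classes.to_numpy()})
    io.write_result_table(cls_table, out / "chromatin_classes.tsv",
                          _meta(config, resolution=config.resolution,
                                k=config.snn_k))
    summary["cluster"] = {"n_classes": int(classes.nunique())}

    # ------------------------------------------------------------ transfer
    gene_norm = log_normalize(gene_counts)
    rna_emb = compute_embedding(gene_norm, config.n_components_fine,
                                seed=config.seed)
    rna_emb = adjust_batch(rna_emb, cells["sample"],
                           method=config.batch_method)
    ref = np.arange(len(cells)) % 2 == 0  # even cells act as the reference
    transfer = knn_classify(rna_emb.coordinates[ref],
                            cells.loc[ref, "state_true"].to_numpy(),
                            rna_emb.coordinates[~ref], k=config.knn_k)
    states = cells["state_true"].to_numpy().copy()
    states[~ref] = transfer["label"].to_numpy()
    tr_table = pd.DataFrame({"barcode": cells["barcode"], "state": states,
                             "is_reference": ref})
    io.write_result_table(tr_table, out / "state_transfer.tsv",
                          _meta(config, k=config.knn_k,
                                confidence_votes=config.knn_k // 2 + 1))
    summary["transfer"] = {
        "frac_high_confidence": float(transfer["high_confidence"].mean()),
        "query_accuracy": float(
            (transfer["label"].to_numpy()
             == cells.loc[~ref, "state_true"].to_numpy()).mean())}

    # ----------------------------------------------------------- superstate
    orm = class_state_or_matrix(classes, states,
                                min_state_cells=config.min_state_cells,
                                fdr_alpha=config.or_fdr,
                                estimate=config.or_estimate)
    io.write_result_table(orm, out / "or_matrix.tsv",
                          _meta(config, fdr=config.or_fdr,
                                min_state_cells=config.min_state_cells))
    state_class = (pd.DataFrame({"state": states,
                                 "cls": cells["class_true"]})
                   .groupby("state")["cls"].agg(lambda v: v.mode()[0]))
    auc = pairwise_lda_auc(emb.coordinates, states, cells["sample"],
                           n_fragments, train_frac=config.lda_train_frac,
                           min_cells=config.lda_min_cells, seed=config.seed,
                           state_class_map=state_class.to_dict())
    io.write_result_table(auc, out / "lda_auc.tsv",
                          _meta(config, train_frac=config.lda_train_frac,
                                min_cells=config.lda_min_cells))
    summary["superstate"] = {
        "n_significant_or": int((orm["significant"]
                                 & (orm["odds_ratio"] > 1)).sum()),
        **within_across_summary(auc)}

    # ---------------------------------------------------------- differential
    prom_idx = np.flatnonzero(ds.peaks["is_promoter"].to_numpy())
    prom_names = ds.peaks["peak"].iloc[prom_idx].tolist()
    cd4 = ds.peaks.loc[ds.peaks["role"] == "lineage_promoter:CD4",
                       "peak"].iloc[0]
    cd8a = ds.peaks.loc[ds.peaks["role"] == "lineage_promoter:CD8A",
                        "peak"].iloc[0]
    lineage = derive_lineage(binary, ds.peaks["peak"].tolist(), cd4, cd8a)
    lin_res = lineage_association(binary[:, prom_idx], prom_names, lineage,
                                  classes, cells["sample"], n_fragments,
                                  fdr_alpha=config.lineage_fdr,
                                  sample_effect=config.sample_effect)
    io.write_result_table(lin_res, out / "lineage_association.tsv",
                          _meta(config, fdr=config.lineage_fdr))
    pb = pseudobulk_counts(peak_counts[:, prom_idx], prom_names,
                           cells["sample"], states,
                           min_sample_cells=30, min_state_cells=30,
                           min_combo_cells=10)
    nb = nb_lrt_differential(pb, fdr_alpha=config.pseudobulk_fdr)
    io.write_result_table(nb, out / "pseudobulk_differential.tsv",
                          _meta(config, fdr=config.pseudobulk_fdr))
    markers = wilcoxon_markers(gene_norm, ds.genes["gene"].tolist(), states)
    io.write_result_table(markers, out / "gene_markers.tsv", _meta(config))

    pair_states = sorted(pd.unique(states))[:2]
    pair = np.isin(states, pair_states)
    pg_map = ds.peaks[["peak", "gene"]].dropna()
    conc = promoter_gene_concordance(
        gene_counts[pair], gene_norm[pair], ds.genes["gene"].tolist(),
        binary[pair], tfidf_normalize(binary)[pair],
        ds.peaks["peak"].tolist(), pg_map, states[pair], n_fragments[pair],
        sample_labels=cells.loc[pair, "sample"].to_numpy(), min_cells=20)
    io.write_result_table(conc, out / "concordance.tsv", _meta(config))
    summary["differential"] = {
        "n_lineage_significant": int(lin_res["significant"].sum()),
        "n_pseudobulk_differential": int(nb["differential"].sum())
        if len(nb) else 0,
        "concordance_gene_sig": float(conc["gene_significant"].mean())
        if len(conc) else float("nan"),
        "concordance_peak_sig": float(conc["peak_significant"].mean())
        if len(conc) else float("nan")}

    # ------------------------------------------- scores / motifs / variants
    all_norm = tfidf_normalize(binary)
    peak_names_true = ds.peaks["peak"].tolist()
    score_rows = {}
    for name, sset in ds.signed_sets.items():
        sc = signed_score(all_norm, peak_names_true, sset)
        target = (cells["class_true"] == 0).to_numpy()
        score_rows[name] = {
            "mean_target": float(sc[target].mean()),
            "mean_rest": float(sc[~target].mean()),
            "p_greater": score_group_test(sc, target, "greater")}
    io.write_json(score_rows, out / "signed_scores.json")

    cls_sets = class_specific_peaks(all_norm, peak_names_true, classes)
    tf_expr = pd.DataFrame(
        {g: np.asarray(gene_norm[:, j].todense()).ravel()
         for j, g in enumerate(ds.genes["gene"])})
    tf_expr["__cls"] = classes.to_numpy()
    tf_expr = tf_expr.groupby("__cls").mean()
    enr = motif_enrichment(cls_sets, ds.motif_annot, peak_names_true,
                           tf_expression=tf_expr,
                           motif_tf_gene=ds.motif_tf_gene,
                           enrich_min=config.enrich_min,
                           expr_min=config.expr_min)
    io.write_result_table(enr, out / "motif_enrichment.tsv",
                          _meta(config, enrich_min=config.enrich_min))
    overlap = snp_peak_overlap(ds.snps, ds.peaks, pip_min=config.pip_min)
    io.write_result_table(overlap, out / "snp_peak_overlap.tsv",
                          _meta(config, pip_min=config.pip_min))
    summary["scores_enrichment_variants"] = {
        "n_selected_motifs": int(enr["selected"].sum()) if len(enr) else 0,
        "n_snp_overlaps": len(overlap)}

    # -------------------------------------------------------------- tracks
    region = (ds.peaks["chrom"].iloc[0], int(ds.peaks["start"].iloc[0]),
              int(ds.peaks["end"].iloc[5]))
    groups = {f"class_{c}": cells.loc[classes.to_numpy() == c,
                                      "barcode"].tolist()
              for c in sorted(classes.unique())}
    frag_kept = ds.fragments[ds.fragments["barcode"].isin(
        set(cells["barcode"]))]
    tracks = export_class_bedgraph(frag_kept, groups, region)
    for name, track in tracks.items():
        io.write_bedgraph(track, out / f"track_{name}.bedgraph")
    summary["tracks"] = {"n_groups": len(tracks), "region": list(region)}

    io.write_json(summary, out / "summary.json")
    return {"dataset": ds, "cells": cells, "classes": classes,
            "states": states, "embedding": emb, "or_matrix": orm,
            "auc": auc, "lineage": lin_res, "pseudobulk": nb,
            "concordance": conc, "motifs": enr, "snp_overlap": overlap,
            "summary": summary}
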