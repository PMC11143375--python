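"""Signed scores, motif enrichment in class-specific peaks, and SNP
prioritization across chromatin classes."""

import numpy as np
import pandas as pd

import chromstate as cs
from chromstate.embedding import log_normalize

ds = cs.generate_multiome(cs.SynthConfig(seed=1))
binary = (ds.peak_counts > 0).astype(float)
norm = cs.tfidf_normalize(binary)
peak_names = ds.peaks["peak"].tolist()
classes = ds.cells["class_true"]  # use truth; see example 02 for clustering

# signed score: class-0-specific peaks (positive) vs class-1 (negative)
sset = ds.signed_sets["class0_vs_class1_peaks"]
score = cs.signed_score(norm, peak_names, sset)
mask = (classes == 0).to_numpy()
p = cs.score_group_test(score, mask, alternative="greater")
print(f"signed score, class 0 vs rest: one-sided rank-sum p = {p:.2e}")

# motif enrichment with the expression display filter
sets = cs.class_specific_peaks(norm, peak_names, classes)
gene_norm = log_normalize(ds.gene_counts)
tf_expr = pd.DataFrame(gene_norm.toarray(), columns=ds.genes["gene"])
tf_expr["cls"] = classes.to_numpy()
tf_expr = tf_expr.groupby("cls").mean()
enr = cs.motif_enrichment(sets, ds.motif_annot, peak_names,
                          tf_expression=tf_expr,
                          motif_tf_gene=ds.motif_tf_gene)
top = enr[enr["selected"]].sort_values("enrichment", ascending=False)
print(top[["class", "motif", "enrichment", "pct_of_max"]].round(1)
      .to_string(index=False))

# fine-mapped SNPs: overlap with peaks, rank classes by z-scored access.
overlap = cs.snp_peak_overlap(ds.snps, ds.peaks, pip_min=0.1)
prof = cs.class_accessibility_profile(norm, peak_names, classes,
                                      overlap["peak"].unique().tolist())
hits = prof["accessible"].sum(axis=0)
print(f"{len(overlap)} SNP-peak overlaps (PIP > 0.1); accessible classes "
      f"(z > 1) per peak: min {hits.min()}, max {hits.max()}")
# The planted motifs (MOTIF_0..2, one per class) are the selected ones, and
# planted high-PIP SNPs land in peaks whose accessible class is their class.
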