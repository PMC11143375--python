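"""The class x state odds-ratio matrix: the superstate test.

Each (chromatin class, transcriptional state) pair gets a 2x2 Fisher exact
test with a conditional-MLE odds ratio. A class that is significantly
enriched for several states is a 'superstate': one accessibility profile
shared by multiple expression-defined states.
"""

import numpy as np

import chromstate as cs

ds = cs.generate_multiome(cs.SynthConfig(seed=1))
binary = (ds.peak_counts > 0).astype(float)
norm = cs.tfidf_normalize(binary)
sel = cs.select_variable_features(norm, 1000)
emb = cs.adjust_batch(cs.compute_embedding(norm[:, sel], 10, seed=0),
                      ds.cells["sample"])
classes = cs.snn_louvain(emb, 20, 0.1, seed=0)

orm = cs.class_state_or_matrix(classes, ds.cells["state_true"],
                               min_state_cells=10, fdr_alpha=0.05)
print(orm[["class", "state", "odds_ratio", "fdr",
           "log_or_display"]].round(3).to_string(index=False))
enriched = orm[orm["significant"] & (orm["odds_ratio"] > 1)]
per_class = enriched.groupby("class")["state"].apply(list)
print("\nstates nested per chromatin class:", per_class.to_dict())
# Classes hosting two states each are the planted superstates; infinite
# odds ratios are shown capped at 1 + ceil(max finite |log OR|).
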