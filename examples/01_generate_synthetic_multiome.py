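"""Generate a ground-truthed multi-sample multiome dataset.

The generator plants transcriptional states *nested inside* chromatin
classes: states of one class share its peak-openness profile exactly and
differ only in their marker genes' expression. Per-cell depth is
log-normal, per-(sample, peak) batch shifts act on the logit scale, and
peak counts are Poisson draws over the cell's openness composition.
"""

import math

import numpy as np

import chromstate as cs

cfg = cs.SynthConfig(n_samples=3, cells_per_sample=300, n_peaks=600,
                     n_genes=300, markers_per_state=10,
                     depth_mu=math.log(800.0), seed=1)
ds = cs.generate_multiome(cfg, include_reads=True)

print(f"cells: {len(ds.cells)}  peaks: {len(ds.peaks)}  "
      f"genes: {len(ds.genes)}")
print("states per class:",
      ds.cells.groupby('class_true')['state_true'].nunique().to_dict())
print("peak roles:", ds.peaks['role'].value_counts().to_dict())
depth = np.asarray(ds.peak_counts.sum(axis=1)).ravel()
print(f"median fragments/cell: {np.median(depth):.0f}  "
      f"reads incl. planted PCR duplicates: {len(ds.reads)}")
# The role column is the ground truth downstream analyses are scored
# against: class-specific peaks drive the chromatin classes, lineage peaks
# the CD4/CD8 analysis, and promoter-gene pairings the concordance test.
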