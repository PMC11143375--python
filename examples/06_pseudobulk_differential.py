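"""Pseudobulk negative-binomial differential accessibility.

Counts are summed by (sample, state); each promoter peak is tested by a
negative-binomial likelihood-ratio test of the state term with sample and
depth covariates. Between two chromatin-distinct groups the planted peaks
light up; between sibling states of one superstate class almost nothing
does.
"""

import numpy as np

import chromstate as cs


def promoter_pma_pseudobulk(ds):
    pma = cs.select_pma_peaks(ds.peak_counts)
    keep = np.flatnonzero(ds.peaks["is_promoter"].to_numpy() & pma)
    return cs.pseudobulk_counts(
        ds.peak_counts[:, keep], ds.peaks["peak"].iloc[keep].tolist(),
        ds.cells["sample"], ds.cells["state_true"]), keep


# two chromatin-distinct groups (~4-fold class-specific accessibility)
cfg = cs.SynthConfig(n_samples=6, cells_per_sample=400, n_classes=2,
                     states_per_class=[1, 1], n_peaks=330,
                     frac_class_specific=0.3, p_open_high=0.2,
                     p_open_low=0.05, frac_promoter=0.9, n_genes=100,
                     markers_per_state=5, seed=1)
ds = cs.generate_multiome(cfg)
pb, keep = promoter_pma_pseudobulk(ds)
res = cs.nb_lrt_differential(pb, fdr_alpha=0.10).set_index("feature")
role = ds.peaks.set_index("peak")["role"].loc[res.index]
planted = role.str.startswith("class_specific").to_numpy()
print(f"across classes: {int(res['differential'].sum())} differential "
      f"promoter peaks of {len(res)} tested "
      f"(recall of planted 4-fold effects: "
      f"{res.loc[planted, 'differential'].mean():.2f})")

# two sibling states inside one superstate class: shared accessibility
cfg = cs.SynthConfig(n_samples=6, cells_per_sample=400, n_classes=1,
                     states_per_class=[2], n_peaks=330,
                     frac_class_specific=0.3, frac_promoter=0.9,
                     n_genes=100, markers_per_state=5, seed=1)
ds = cs.generate_multiome(cfg)
pb, _ = promoter_pma_pseudobulk(ds)
res = cs.nb_lrt_differential(pb, fdr_alpha=0.10)
print(f"within a class:  {int(res['differential'].sum())} differential "
      f"promoter peaks of {len(res)} tested")
# Many differential peaks across classes, essentially none within a class:
# the pseudobulk view of the superstate model.
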