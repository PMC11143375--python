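"""Shared fixtures: small synthetic datasets generated at test time."""

import warnings

import numpy as np
import pytest

import chromstate as cs


@pytest.fixture(scope="session")
def small_dataset():
    """A compact multiome dataset with reads, shared across unit tests."""
    cfg = cs.SynthConfig(n_samples=2, cells_per_sample=150, n_peaks=400,
                         n_genes=200, markers_per_state=8, n_snps=40,
                         n_motifs=10, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cs.generate_multiome(cfg, include_reads=True)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-scale superstate dataset (3 samples x 1000 cells)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cs.generate_multiome(cs.SynthConfig(seed=11))


def cluster_chromatin(ds, resolution=0.1, n_components=10, seed=0,
                      n_features=1000):
    """The fine-grain chromatin classing chain used across tests."""
    binary = (ds.peak_counts > 0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = cs.tfidf_normalize(binary)
        sel = cs.select_variable_features(norm,
                                          min(n_features, norm.shape[1]))
        emb = cs.compute_embedding(norm[:, sel], n_components, seed=seed)
        emb = cs.adjust_batch(emb, ds.cells["sample"])
        labels = cs.snn_louvain(emb, 20, resolution, seed=seed)
    return emb, labels


@pytest.fixture(scope="session")
def clustered_default(default_dataset):
    emb, labels = cluster_chromatin(default_dataset)
    nfrag = np.asarray(default_dataset.peak_counts.sum(axis=1)).ravel()
    return default_dataset, emb, labels, nfrag
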