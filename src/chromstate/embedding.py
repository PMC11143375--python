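"""Chromatin normalization, dimensionality reduction and graph clustering.

The chromatin pipeline is: binarize the cell x peak matrix, log(TF-IDF)
normalize, select the most variable features, center/scale, truncated PCA,
batch adjustment, then Louvain clustering of a shared-nearest-neighbor
graph. 20 components are used for broad cell-type clustering and 10 for
fine-grain chromatin classes.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors


@dataclass
class Embedding:
    """Cells x components coordinates with batch-adjustment provenance."""

    coordinates: np.ndarray
    n_components: int
    batch_adjusted: bool = False

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedding contains non-finite entries")
        if self.coordinates.shape[1] != self.n_components:
            raise ValueError("n_components does not match coordinates")


def tfidf_normalize(binary: sp.spmatrix, scale: float = 1e4) -> sp.csr_matrix:
    """log(1 + scale * TF * IDF) normalization of a binarized peak matrix.

    ``TF_ij = x_ij / (row i total)`` and ``IDF_j = n_cells / (column j
    total)``. The scale factor (default 1e4) is a dialect choice recorded in
    run metadata; all-zero cells yield all-zero rows with a warning, and an
    all-zero peak column is an error (such peaks should have been removed by
    feature selection).
    """
    x = sp.csr_matrix(binary, dtype=float)
    x.data[:] = 1.0  # defensively binarize
    n_cells = x.shape[0]
    row_tot = np.asarray(x.sum(axis=1)).ravel()
    col_tot = np.asarray(x.sum(axis=0)).ravel()
    if np.any(col_tot == 0):
        raise ValueError("column with zero total; pre-filter empty peaks")
    if np.any(row_tot == 0):
        warnings.warn("all-zero cell rows produce all-zero output")
    inv_row = np.where(row_tot > 0, 1.0 / row_tot, 0.0)
    out = x.multiply(inv_row[:, None]).multiply(
        (n_cells / col_tot)[None, :]).tocsr()
    out.data = np.log1p(scale * out.data)
    return out


def log_normalize(counts: sp.spmatrix, scale: float = 1e4) -> sp.csr_matrix:
    """log(1 + scale * x / library size) normalization for expression counts.

    The default scale of 1e4 normalizes every cell to 10,000 reads before
    the log, the standard convention for single-cell RNA matrices.
    """
    x = sp.csr_matrix(counts, dtype=float)
    lib = np.asarray(x.sum(axis=1)).ravel()
    inv = np.where(lib > 0, 1.0 / lib, 0.0)
    out = x.multiply(inv[:, None]).tocsr()
    out.data = np.log1p(scale * out.data)
    return out


def select_variable_features(matrix, n_features: int,
                             clip: bool = True) -> np.ndarray:
    """Indices of the most variable features (VST-style standardized variance).

    A mean-variance trend is fit on log10 scale by local regression over the
    non-constant features; each feature's values are standardized by the
    trend-expected standard deviation, clipped at ``sqrt(n_cells)``, and the
    features with the largest variance of the clipped standardized values
    are returned (largest first). The trend is fit on features whose mean
    lies within the bulk of the mean distribution (2nd-98th percentile) and
    extrapolated flat beyond it, so isolated extreme features cannot set
    their own expectation. Constant features are never selected.
    """
    if n_features <= 0:
        raise ValueError("n_features must be positive")
    x = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix,
                                                                dtype=float)
    n_cells, n_feat = x.shape
    n_features = min(n_features, n_feat)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    usable = (var > 0) & (mean > 0)
    std_var = np.zeros(n_feat)
    if usable.sum() >= 3:
        from statsmodels.nonparametric.smoothers_lowess import lowess
        lm, lv = np.log10(mean[usable]), np.log10(var[usable])
        lo_q, hi_q = np.quantile(lm, [0.02, 0.98])
        bulk = (lm >= lo_q) & (lm <= hi_q)
        if bulk.sum() < 3:
            bulk[:] = True
        fit = lowess(lv[bulk], lm[bulk], frac=0.5, return_sorted=True)
        expected_var = 10.0 ** np.interp(np.log10(mean[usable]),
                                         fit[:, 0], fit[:, 1])
        expected_sd = np.sqrt(np.maximum(expected_var, 1e-12))
        z = (x[:, usable] - mean[usable]) / expected_sd
        if clip:
            bound = np.sqrt(n_cells)
            z = np.clip(z, -bound, bound)
        std_var[usable] = z.var(axis=0, ddof=1)
    else:
        std_var[usable] = var[usable]
    order = np.argsort(-std_var, kind="stable")
    return order[:n_features][std_var[order[:n_features]] > 0]


def scale_features(matrix) -> np.ndarray:
    """Center each feature to mean 0 and variance 1 across cells."""
    x = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix,
                                                                dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (x - mean) / sd


def compute_embedding(matrix, n_components: int, seed: int = 0,
                      scale: bool = True) -> Embedding:
    """Truncated PCA of the (scaled) feature matrix.

    Component signs are fixed by convention: the loading with the largest
    absolute value is made positive, so the embedding is deterministic given
    the seed.
    """
    x = scale_features(matrix) if scale else (
        matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix,
                                                                dtype=float))
    if n_components > min(x.shape):
        raise ValueError(f"n_components={n_components} exceeds data rank "
                         f"bound {min(x.shape)}")
    pca = PCA(n_components=n_components, svd_solver="full",
              random_state=seed)
    coords = pca.fit_transform(x)
    flip = np.ones(n_components)
    for k in range(n_components):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            flip[k] = -1.0
    emb = Embedding(coords * flip, n_components)
    emb.explained_variance_ = pca.explained_variance_
    emb.components_ = pca.components_ * flip[:, None]
    return emb


def adjust_batch(embedding: Embedding, sample_labels,
                 method: str = "center") -> Embedding:
    """Batch-adjustment contract: per-sample means equal the global mean.

    The default ``center`` method subtracts each sample's mean and restores
    the global mean per component — an explicit stand-in for heavier
    mixing-based correctors; ``none`` passes through, and real-data users
    can inject an externally adjusted embedding instead. Samples with a
    single cell are passed through unadjusted with a warning.
    """
    labels = np.asarray(sample_labels)
    if len(labels) != len(embedding.coordinates):
        raise ValueError("every cell needs a sample label")
    if method == "none":
        return Embedding(embedding.coordinates, embedding.n_components,
                         batch_adjusted=False)
    if method != "center":
        raise ValueError(f"unknown batch method {method!r}")
    x = embedding.coordinates.copy()
    global_mean = x.mean(axis=0)
    for s in pd.unique(labels):
        rows = labels == s
        if rows.sum() < 2:
            warnings.warn(f"sample {s!r} has a single cell; left unadjusted")
            continue
        x[rows] += global_mean - x[rows].mean(axis=0)
    return Embedding(x, embedding.n_components, batch_adjusted=True)


def _snn_graph(coords: np.ndarray, k: int, prune: float):
    """kNN -> shared-nearest-neighbor graph with Jaccard edge weights.

    Neighbor sets include the cell itself; edges with Jaccard weight below
    ``prune`` are removed.
    """
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k, n)).fit(coords)
    _, idx = nn.kneighbors(coords)
    # neighbor incidence including self
    rows = np.repeat(np.arange(n), idx.shape[1])
    adj = sp.csr_matrix((np.ones(rows.size), (rows, idx.ravel())),
                        shape=(n, n))
    adj = ((adj + sp.eye(n, format="csr")) > 0).astype(float)
    shared = adj @ adj.T
    shared = sp.coo_matrix(sp.triu(shared, k=1))
    set_size = np.asarray(adj.sum(axis=1)).ravel()
    union = set_size[shared.row] + set_size[shared.col] - shared.data
    jacc = shared.data / union
    keep = jacc >= prune
    return shared.row[keep], shared.col[keep], jacc[keep], n


def snn_louvain(embedding: Embedding, k_neighbors: int = 20,
                resolution: float = 0.8, seed: int = 0,
                prune: float = 1.0 / 15.0) -> pd.Series:
    """Louvain clustering of the SNN graph at the given resolution.

    Labels are contiguous integers renumbered by descending cluster size
    (largest cluster is 0). Cells disconnected from the pruned graph are
    assigned to the nearest cluster by centroid distance with a warning.
    Deterministic given the seed.
    """
    coords = embedding.coordinates
    if k_neighbors >= coords.shape[0]:
        raise ValueError("k_neighbors must be smaller than the cell count")
    src, dst, w, n = _snn_graph(coords, k_neighbors, prune)
    g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())))
    state = _pyrandom.getstate()
    try:
        _pyrandom.seed(seed)
        part = g.community_multilevel(weights=list(w),
                                      resolution=resolution)
    finally:
        _pyrandom.setstate(state)
    labels = np.asarray(part.membership)

    degree = np.asarray(g.degree())
    orphans = np.flatnonzero(degree == 0)
    if orphans.size and orphans.size < n:
        warnings.warn(f"{orphans.size} disconnected cell(s) assigned to the "
                      "nearest cluster by centroid distance")
        connected = degree > 0
        cents = {c: coords[connected & (labels == c)].mean(axis=0)
                 for c in np.unique(labels[connected])}
        cids = sorted(cents)
        cmat = np.vstack([cents[c] for c in cids])
        for i in orphans:
            d = np.linalg.norm(cmat - coords[i], axis=1)
            labels[i] = cids[int(np.argmin(d))]

    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    out = pd.Series([remap[v] for v in labels], name="cluster")
    out.attrs.update(resolution=resolution, seed=seed, k=k_neighbors,
                     prune=prune)
    return out
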