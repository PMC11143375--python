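"""Cross-modal kNN label transfer and the superstate statistics.

The class x state correspondence is quantified by a Fisher-exact odds-ratio
matrix; the discriminability of state pairs from chromatin alone by
pairwise LDA AUCs. Both statistics operate on per-cell labels and a shared
embedding: reference and query are assumed to live in one coordinate space
(for synthetic data this holds by construction; for real data the
harmonized embedding is an input).
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from scipy.stats.contingency import odds_ratio as _odds_ratio
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests


# ------------------------------------------------------------ label transfer

def knn_classify(reference_embedding, reference_labels, query_embedding,
                 k: int = 5) -> pd.DataFrame:
    """Classify query cells by the majority label of their k nearest
    reference neighbors (Euclidean).

    Vote ties are broken by the nearest neighbor whose label is among the
    tied winners. A mapping is high-confidence when the winning label holds
    at least ``floor(k/2) + 1`` of the votes (3 of 5 at the default k). The
    direction is reversible: states can be transferred onto multiome cells
    or classes onto reference cells by swapping the arguments.

    Returns a DataFrame with ``label``, ``vote_count``, ``high_confidence``
    and the mean coordinates of the k neighbors.
    """
    ref = np.asarray(reference_embedding, dtype=float)
    query = np.asarray(query_embedding, dtype=float)
    labels = np.asarray(reference_labels)
    if k < 1 or k > ref.shape[0]:
        raise ValueError(f"k={k} out of range for {ref.shape[0]} reference "
                         "cells")
    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    _, idx = nn.kneighbors(query)
    majority = k // 2 + 1
    out_label, out_votes = [], []
    for row in idx:
        neigh = labels[row]
        vals, counts = np.unique(neigh, return_counts=True)
        top = counts.max()
        winners = set(vals[counts == top])
        if len(winners) == 1:
            win = next(iter(winners))
        else:  # nearest neighbor among the tied labels wins
            win = next(lab for lab in neigh if lab in winners)
        out_label.append(win)
        out_votes.append(int(top))
    mean_coords = ref[idx].mean(axis=1)
    res = pd.DataFrame({"label": out_label, "vote_count": out_votes})
    res["high_confidence"] = res["vote_count"] >= majority
    for d in range(mean_coords.shape[1]):
        res[f"neighbor_mean_{d}"] = mean_coords[:, d]
    return res


# --------------------------------------------------------------- OR matrix

def fisher_or(table, estimate: str = "conditional"):
    """Two-sided Fisher exact p and odds-ratio estimate for a 2x2 table.

    ``conditional`` returns the conditional maximum-likelihood estimate
    under the noncentral hypergeometric model (the convention of the
    classical Fisher-test routines); ``sample`` returns the plain
    cross-product ratio.
    """
    table = np.asarray(table, dtype=np.int64)
    _, p = scipy.stats.fisher_exact(table, alternative="two-sided")
    if estimate == "sample":
        a, b = table[0]
        c, d = table[1]
        orr = np.inf if b * c == 0 and a * d > 0 else (
            (a * d) / (b * c) if b * c else np.nan)
    elif estimate == "conditional":
        orr = _odds_ratio(table, kind="conditional").statistic
    else:
        raise ValueError(f"unknown estimate {estimate!r}")
    return float(orr), float(p)


def _cap_log_or(log_or: np.ndarray) -> np.ndarray:
    """Display rule for infinite log odds ratios.

    Infinite values are replaced by +/-(1 + ceil(max finite |log OR|)); if
    every value is infinite the cap is +/-1.
    """
    out = log_or.astype(float).copy()
    finite = np.isfinite(out)
    cap = 1.0 + (math.ceil(np.abs(out[finite]).max()) if finite.any()
                 else 0.0)
    out[np.isposinf(log_or)] = cap
    out[np.isneginf(log_or)] = -cap
    return out


def class_state_or_matrix(class_labels, state_labels,
                          min_state_cells: int = 10,
                          fdr_alpha: float = 0.05,
                          estimate: str = "conditional") -> pd.DataFrame:
    """Odds-ratio matrix between chromatin classes and cell states.

    For every (class, state) pair a 2x2 table of cells in/out of the class
    by in/out of the state is tested with Fisher's exact test; the OR is the
    conditional MLE by default. States with ``min_state_cells`` or fewer
    cells are excluded. BH FDR is computed across all tested pairs, and
    ``log_or_display`` applies the cap rule for infinite estimates.
    """
    cls = pd.Series(np.asarray(class_labels))
    st = pd.Series(np.asarray(state_labels))
    if len(cls) != len(st):
        raise ValueError("class and state labels must align per cell")
    state_counts = st.value_counts()
    kept_states = sorted(state_counts.index[state_counts > min_state_cells])
    skipped = sorted(set(state_counts.index) - set(kept_states))
    if skipped:
        warnings.warn(f"states excluded with <= {min_state_cells} cells: "
                      f"{skipped}")
    rows = []
    n = len(cls)
    for c in sorted(cls.unique()):
        in_c = (cls == c).to_numpy()
        for s in kept_states:
            in_s = (st == s).to_numpy()
            a = int(np.sum(in_c & in_s))
            b = int(np.sum(in_c & ~in_s))
            cc = int(np.sum(~in_c & in_s))
            d = n - a - b - cc
            orr, p = fisher_or([[a, b], [cc, d]], estimate=estimate)
            rows.append((c, s, orr, p, a, b, cc, d))
    res = pd.DataFrame(rows, columns=["class", "state", "odds_ratio", "p",
                                      "n11", "n10", "n01", "n00"])
    res["fdr"] = multipletests(res["p"], method="fdr_bh")[1]
    res["significant"] = res["fdr"] < fdr_alpha
    with np.errstate(divide="ignore"):
        log_or = np.log(res["odds_ratio"].to_numpy())
    res["log_or"] = log_or
    res["log_or_display"] = _cap_log_or(log_or)
    return res


# ------------------------------------------------------------- pairwise LDA

def _pair_design(h_pcs, sample_labels, n_fragments):
    """Predictors for one state pair: hPCs + one-hot sample + scaled
    log10 fragment counts."""
    parts = [np.asarray(h_pcs, dtype=float)]
    samples = pd.Categorical(sample_labels)
    if len(samples.categories) > 1:
        onehot = np.eye(len(samples.categories))[samples.codes][:, 1:]
        parts.append(onehot)
    lf = np.log10(np.asarray(n_fragments, dtype=float))
    sd = lf.std(ddof=1)
    parts.append(((lf - lf.mean()) / sd if sd > 0 else lf * 0.0)[:, None])
    return np.column_stack(parts), len(samples.categories)


def pairwise_lda_auc(embedding, state_labels, sample_labels, n_fragments,
                     train_frac: float = 0.75, min_cells: int = 50,
                     seed: int = 0, state_class_map=None) -> pd.DataFrame:
    """Held-out LDA AUC for every unordered pair of states.

    Per pair: subset the cells, append one-hot sample and scaled
    log10(fragments) covariates to the chromatin PCs, make a stratified
    75/25 split (re-drawn if a split lacks one of the states), fit a
    two-class LDA and score the held-out posterior with AUC. Pairs in which
    either state has fewer than ``min_cells`` cells, or with a degenerate
    predictor (a single sample or constant fragment counts), are marked
    ``skipped``. The result is symmetric in the two states by construction.
    """
    emb = np.asarray(embedding, dtype=float)
    st = pd.Series(np.asarray(state_labels))
    samp = np.asarray(sample_labels)
    nf = np.asarray(n_fragments, dtype=float)
    counts = st.value_counts()
    states = sorted(counts.index)
    rng = np.random.default_rng(seed)
    rows = []
    for s1, s2 in combinations(states, 2):
        within = (None if state_class_map is None
                  else state_class_map[s1] == state_class_map[s2])
        if counts[s1] < min_cells or counts[s2] < min_cells:
            rows.append((s1, s2, np.nan, True, within))
            continue
        sel = st.isin([s1, s2]).to_numpy()
        X, n_samp = _pair_design(emb[sel], samp[sel], nf[sel])
        y = (st[sel] == s2).to_numpy().astype(int)
        if n_samp < 2 and np.ptp(nf[sel]) == 0:
            rows.append((s1, s2, np.nan, True, within))
            continue
        auc = np.nan
        for attempt in range(10):
            # stratified split from a label-name-independent permutation so
            # the result is exactly symmetric in the two states' roles
            perm = np.random.default_rng(
                int(rng.integers(2**31))).permutation(len(y))
            train_mask = np.zeros(len(y), dtype=bool)
            for grp in (0, 1):
                stratum = perm[y[perm] == grp]
                n_train = int(np.ceil(train_frac * len(stratum)))
                train_mask[stratum[:n_train]] = True
            Xtr, Xte = X[train_mask], X[~train_mask]
            ytr, yte = y[train_mask], y[~train_mask]
            if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
                continue
            try:
                lda = LinearDiscriminantAnalysis(solver="svd")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lda.fit(Xtr, ytr)
                auc = roc_auc_score(yte, lda.predict_proba(Xte)[:, 1])
            except np.linalg.LinAlgError:
                lda = LinearDiscriminantAnalysis(solver="lsqr",
                                                 shrinkage=1e-6)
                lda.fit(Xtr, ytr)
                auc = roc_auc_score(yte, lda.decision_function(Xte))
            break
        rows.append((s1, s2, float(auc), not np.isfinite(auc), within))
    res = pd.DataFrame(rows, columns=["state_a", "state_b", "auc",
                                      "skipped", "within_class"])
    return res


def within_across_summary(auc_table: pd.DataFrame,
                          state_class_map=None) -> dict:
    """Mean AUC over non-skipped pairs, split within vs across classes.

    ``mean_within`` is reported as missing (NaN) when no within-class pairs
    were computed.
    """
    df = auc_table[~auc_table["skipped"]].copy()
    if state_class_map is not None:
        df["within_class"] = [state_class_map[a] == state_class_map[b]
                              for a, b in zip(df["state_a"], df["state_b"])]
    if df["within_class"].isna().any():
        raise ValueError("every state must be mapped to a class")
    within = df.loc[df["within_class"].astype(bool), "auc"]
    across = df.loc[~df["within_class"].astype(bool), "auc"]
    return {"mean_within": float(within.mean()) if len(within) else np.nan,
            "mean_across": float(across.mean()) if len(across) else np.nan,
            "n_within": int(len(within)), "n_across": int(len(across))}


# --------------------------------------------------- proportion correlation

def class_proportion_correlation(props_a: pd.DataFrame, props_b: pd.DataFrame,
                                 cells_a: pd.Series, cells_b: pd.Series,
                                 min_cells: int = 200) -> pd.DataFrame:
    """Per-class Pearson correlation of class proportions across two sources.

    ``props_a``/``props_b`` are donor x class proportion tables (rows sum to
    1) from two technologies; ``cells_a``/``cells_b`` give each donor's cell
    count per source. Donors with fewer than ``min_cells`` cells in either
    source are dropped (the threshold is lowered for sparse cell types such
    as endothelium by the caller). With fewer than 3 donors remaining, r is
    still reported but the p-value is flagged unreliable.
    """
    donors = sorted(set(props_a.index) & set(props_b.index))
    keep = [d for d in donors
            if cells_a.get(d, 0) >= min_cells and cells_b.get(d, 0) >= min_cells]
    classes = sorted(set(props_a.columns) & set(props_b.columns))
    rows = []
    for cls in classes:
        x = props_a.loc[keep, cls].to_numpy(dtype=float)
        y = props_b.loc[keep, cls].to_numpy(dtype=float)
        if len(keep) >= 3 and np.std(x) > 0 and np.std(y) > 0:
            r, p = scipy.stats.pearsonr(x, y)
            unreliable = False
        elif len(keep) == 2 and np.std(x) > 0 and np.std(y) > 0:
            r = float(np.corrcoef(x, y)[0, 1])
            p, unreliable = np.nan, True
        else:
            r, p, unreliable = np.nan, np.nan, True
        rows.append((cls, r, p, len(keep), unreliable))
    return pd.DataFrame(rows, columns=["class", "r", "p", "n_donors",
                                       "p_unreliable"])
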