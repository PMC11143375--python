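"""Differential accessibility and expression statistics.

Single-cell models regress binarized promoter-peak accessibility on the
variable of interest (ternary CD4/CD8 lineage code or a one-vs-rest class
indicator) with sample and depth covariates, testing by likelihood-ratio.
Pseudobulk models aggregate counts over (sample, state) combinations and
test the state term of a negative-binomial regression. Expression markers
use two-sided rank-sum tests on normalized values.

The per-peak logistic fits use a hand-written IRLS so that thousands of
peaks are testable in seconds; it is cross-checked against statsmodels in
the test suite. The "(1|sample)" term of the original mixed models is a
pluggable strategy: fixed-effect one-hot sample dummies by default
(deterministic and asymptotically equivalent for the tested term, since the
sample terms appear in both the full and null models), with an optional
Laplace-approximated random intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import expit
from statsmodels.stats.multitest import multipletests


# ----------------------------------------------------------- lineage coding

def derive_lineage(binary_matrix, peak_names, cd4_peak: str,
                   cd8a_peak: str) -> np.ndarray:
    """Ternary lineage code from CD4/CD8A promoter-peak accessibility.

    +1 when the CD4 promoter peak is open and CD8A closed, -1 when CD8A is
    open and CD4 closed, 0 otherwise (both open or both closed).
    """
    names = list(peak_names)
    try:
        i4, i8 = names.index(cd4_peak), names.index(cd8a_peak)
    except ValueError as exc:
        raise KeyError(f"lineage peak missing from matrix: {exc}") from exc
    x = sp.csc_matrix(binary_matrix)
    cd4 = np.asarray(x[:, i4].todense()).ravel() > 0
    cd8 = np.asarray(x[:, i8].todense()).ravel() > 0
    return np.where(cd4 & ~cd8, 1, np.where(cd8 & ~cd4, -1, 0))


# ---------------------------------------------------------- logistic engine

def _irls_logistic(y, X, max_iter: int = 50, tol: float = 1e-8):
    """Maximum-likelihood logistic fit by IRLS with step halving.

    Returns ``(beta, llf, converged)``. Non-convergence (including
    quasi-separation, where coefficients diverge) is reported, not raised.
    """
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    mu = expit(eta)
    llf = np.sum(y * eta - np.logaddexp(0.0, eta))
    for _ in range(max_iter):
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        try:
            wx = X * w[:, None]
            beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError:
            return beta, llf, False
        step = beta_new - beta
        for _ in range(20):  # halve until the likelihood does not decrease
            eta_new = X @ (beta + step)
            llf_new = np.sum(y * eta_new - np.logaddexp(0.0, eta_new))
            if llf_new >= llf - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        eta = X @ beta
        mu = expit(eta)
        improved = llf_new - llf
        llf = llf_new
        if abs(improved) < tol:
            if np.abs(beta).max() > 1e2:  # separation: MLE at infinity
                return beta, llf, False
            return beta, llf, True
    return beta, llf, False


def _laplace_random_intercept(y, X, group_codes, n_groups,
                              max_iter: int = 200):
    """Laplace-approximate ML for a logistic model with a random intercept.

    Profiles the per-group intercepts at their conditional modes and
    maximizes the Laplace-approximated marginal likelihood over the random
    intercept SD; the fixed effects are re-estimated at each SD by
    penalized IRLS. Adequate for the moderate group counts (samples) seen
    here; returns ``(beta, approx_llf, converged)``.
    """
    n, p = X.shape

    def neg_marginal(log_sigma):
        sigma2 = np.exp(2.0 * log_sigma)
        beta = np.zeros(p)
        u = np.zeros(n_groups)
        for _ in range(50):
            eta = X @ beta + u[group_codes]
            mu = expit(eta)
            w = np.maximum(mu * (1 - mu), 1e-10)
            # block update: u given beta (per-group Newton), beta given u
            g_resid = np.bincount(group_codes, weights=y - mu,
                                  minlength=n_groups)
            g_w = np.bincount(group_codes, weights=w, minlength=n_groups)
            u_new = u + (g_resid - u / sigma2) / (g_w + 1.0 / sigma2)
            wx = X * w[:, None]
            z = (X @ beta) + (y - mu) / w
            try:
                beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
            except np.linalg.LinAlgError:
                return np.inf
            if (np.max(np.abs(u_new - u)) < 1e-8
                    and np.max(np.abs(beta_new - beta)) < 1e-8):
                beta, u = beta_new, u_new
                break
            beta, u = beta_new, u_new
        eta = X @ beta + u[group_codes]
        mu = expit(eta)
        llf = np.sum(y * eta - np.logaddexp(0.0, eta))
        llf -= 0.5 * np.sum(u**2) / sigma2
        g_w = np.bincount(group_codes,
                          weights=np.maximum(mu * (1 - mu), 1e-10),
                          minlength=n_groups)
        llf -= 0.5 * np.sum(np.log1p(sigma2 * g_w))
        neg_marginal.last = (beta, llf)
        return -llf

    res = minimize_scalar(neg_marginal, bounds=(-5.0, 2.0),
                          method="bounded",
                          options={"xatol": 1e-4, "maxiter": max_iter})
    beta, llf = neg_marginal.last
    return beta, llf, bool(res.success)


def _one_hot(labels, drop_first: bool = True) -> np.ndarray:
    cat = pd.Categorical(labels)
    m = np.eye(len(cat.categories))[cat.codes]
    return m[:, 1:] if drop_first else m


def scaled_log10(values) -> np.ndarray:
    """scale(log10(x)): log10 then center/scale to unit variance."""
    lf = np.log10(np.asarray(values, dtype=float))
    sd = lf.std(ddof=1)
    return (lf - lf.mean()) / sd if sd > 0 else lf - lf.mean()


@dataclass
class _LRTOutcome:
    beta: float
    lrt: float
    p: float
    converged: bool


def _logistic_lrt_one(y, X_full, X_null, df: int,
                      sample_effect: str = "fixed",
                      group_codes=None, n_groups: int = 0) -> _LRTOutcome:
    if sample_effect == "fixed":
        b_full, ll_full, ok_f = _irls_logistic(y, X_full)
        _, ll_null, ok_n = _irls_logistic(y, X_null)
    elif sample_effect == "random":
        b_full, ll_full, ok_f = _laplace_random_intercept(
            y, X_full, group_codes, n_groups)
        _, ll_null, ok_n = _laplace_random_intercept(
            y, X_null, group_codes, n_groups)
    else:
        raise ValueError(f"unknown sample_effect {sample_effect!r}")
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    p = float(scipy.stats.chi2.sf(lrt, df))
    return _LRTOutcome(float(b_full[1]), lrt, p, ok_f and ok_n)


def _run_peak_lrts(binary, peak_names, tested_column, covariates,
                   sample_labels, fdr_method_scope="table",
                   sample_effect: str = "fixed") -> pd.DataFrame:
    """Shared driver: per-peak logistic LRT of one tested column (df = 1).

    ``covariates`` excludes the intercept and tested column. Peaks constant
    after binarization are excluded before fitting; non-converged fits are
    flagged and excluded from the FDR correction.
    """
    x = sp.csc_matrix(binary)
    n = x.shape[0]
    if sample_effect == "fixed":
        Z = np.column_stack([np.ones(n), tested_column, covariates,
                             _one_hot(sample_labels)])
        group_codes, n_groups = None, 0
    else:
        Z = np.column_stack([np.ones(n), tested_column, covariates])
        cat = pd.Categorical(sample_labels)
        group_codes, n_groups = cat.codes, len(cat.categories)
    null_cols = [0] + list(range(2, Z.shape[1]))
    rows = []
    for j, name in enumerate(peak_names):
        y = np.asarray(x[:, j].todense()).ravel().astype(float)
        y = (y > 0).astype(float)
        if y.min() == y.max():  # uniformly open or closed: excluded
            continue
        out = _logistic_lrt_one(y, Z, Z[:, null_cols], df=1,
                                sample_effect=sample_effect,
                                group_codes=group_codes, n_groups=n_groups)
        rows.append((name, out.beta, out.lrt, out.p, out.converged))
    res = pd.DataFrame(rows, columns=["feature", "beta", "lrt_stat", "p",
                                      "converged"])
    res["fdr"] = np.nan
    ok = res["converged"].to_numpy()
    if ok.any():
        res.loc[ok, "fdr"] = multipletests(res.loc[ok, "p"],
                                           method="fdr_bh")[1]
    n_failed = int((~ok).sum())
    if n_failed:
        warnings.warn(f"{n_failed} peak fit(s) did not converge; excluded "
                      "from the FDR correction")
    res.attrs["n_nonconverged"] = n_failed
    return res


# ------------------------------------------------------- single-cell models

def lineage_association(binary_promoter_peaks, peak_names, lineage,
                        class_labels, sample_labels, n_fragments,
                        fdr_alpha: float = 0.20,
                        sample_effect: str = "fixed") -> pd.DataFrame:
    """Per-peak logistic LRT for CD4/CD8 lineage association.

    Full model: peak ~ lineage + class + sample + scale(log10(nFragments));
    the null drops the numeric lineage term (LRT df = 1). A positive beta
    means CD4-associated, negative CD8A-associated. Peaks uniform after
    binarization are excluded. ``significant`` applies BH FDR < ``fdr_alpha``
    (0.20 by default).
    """
    lineage = np.asarray(lineage, dtype=float)
    cov = np.column_stack([_one_hot(class_labels),
                           scaled_log10(n_fragments)])
    res = _run_peak_lrts(binary_promoter_peaks, peak_names, lineage, cov,
                         sample_labels, sample_effect=sample_effect)
    res["direction"] = np.where(res["beta"] > 0, "CD4", "CD8A")
    res["significant"] = res["fdr"] < fdr_alpha
    return res


def class_logistic_lrt(binary_promoter_peaks, peak_names, class_indicator,
                       sample_labels, n_fragments,
                       sample_effect: str = "fixed") -> pd.DataFrame:
    """Per-peak logistic LRT for a one-vs-rest class indicator.

    Full model: peak ~ class + sample + scale(log10(nFragments)) versus the
    class-free null (df = 1). The effect column reports the class beta
    (log-odds); following the source convention this is the value labeled
    "log2FC" in displays even though it is a natural-log-odds coefficient.
    """
    ind = np.asarray(class_indicator, dtype=float)
    cov = scaled_log10(n_fragments)[:, None]
    res = _run_peak_lrts(binary_promoter_peaks, peak_names, ind, cov,
                         sample_labels, sample_effect=sample_effect)
    res["direction"] = np.where(res["beta"] > 0, "up", "down")
    return res


# -------------------------------------------------------------- pseudobulk

@dataclass
class PseudobulkMatrix:
    """(sample, state) x peak summed counts with inclusion mask.

    ``included`` marks combinations from samples with more than 150 cells,
    states with more than 130 cells, and combinations with more than 10
    cells (strict thresholds). ``n_fragments`` is the total count of the
    combination's cells.
    """

    counts: pd.DataFrame
    n_cells: pd.Series
    n_fragments: pd.Series
    included: pd.Series
    min_sample_cells: int = 150
    min_state_cells: int = 130
    min_combo_cells: int = 10


def pseudobulk_counts(cell_matrix, peak_names, sample_labels, state_labels,
                      min_sample_cells: int = 150,
                      min_state_cells: int = 130,
                      min_combo_cells: int = 10) -> PseudobulkMatrix:
    """Sum the non-binary cell x peak matrix by (sample, state)."""
    x = sp.csr_matrix(cell_matrix)
    df = pd.DataFrame({"sample": np.asarray(sample_labels),
                       "state": np.asarray(state_labels)})
    groups = df.groupby(["sample", "state"], sort=True).indices
    index = pd.MultiIndex.from_tuples(sorted(groups), names=["sample",
                                                             "state"])
    mat = np.vstack([np.asarray(x[groups[key]].sum(axis=0)).ravel()
                     for key in sorted(groups)])
    counts = pd.DataFrame(mat, index=index, columns=list(peak_names))
    n_cells = pd.Series({key: len(groups[key]) for key in sorted(groups)})
    n_cells.index = index
    sample_cells = df.groupby("sample").size()
    state_cells = df.groupby("state").size()
    included = pd.Series(
        [(sample_cells[s] > min_sample_cells)
         and (state_cells[t] > min_state_cells)
         and (n_cells[(s, t)] > min_combo_cells)
         for s, t in index], index=index)
    n_frag = pd.Series(mat.sum(axis=1), index=index)
    return PseudobulkMatrix(counts, n_cells, n_frag, included,
                            min_sample_cells, min_state_cells,
                            min_combo_cells)


def _nb_llf(y, X, start_params=None):
    """Fit a negative-binomial regression (joint MLE of the dispersion)."""
    model = sm.NegativeBinomial(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(disp=0, maxiter=200, method="bfgs",
                        start_params=start_params)
    if not np.isfinite(fit.llf):
        raise RuntimeError("NB fit diverged")
    return fit


def nb_lrt_differential(pseudobulk: PseudobulkMatrix, states=None,
                        min_reads: int = 5,
                        fdr_alpha: float = 0.10) -> pd.DataFrame:
    """Per-peak negative-binomial LRT between transcriptional states.

    For each peak with at least ``min_reads`` reads across the included
    pseudobulks, the full model (state + sample + scale(log10(nFragments)))
    is tested against the state-free null with LRT df = (#states - 1). A
    Poisson fallback is used (and flagged) when the NB dispersion fit fails.
    Peaks are differential when BH FDR < ``fdr_alpha``.
    """
    pb = pseudobulk.counts[pseudobulk.included.to_numpy()]
    idx = pb.index
    if states is not None:
        keep = idx.get_level_values("state").isin(list(states))
        pb = pb[keep]
        idx = pb.index
    state_vals = idx.get_level_values("state")
    if len(pd.unique(state_vals)) < 2:
        raise ValueError("need at least 2 states after masking")
    X_state = _one_hot(state_vals)
    X_sample = _one_hot(idx.get_level_values("sample"))
    nfrag = pseudobulk.n_fragments.loc[idx]
    x_depth = scaled_log10(nfrag.to_numpy())
    ones = np.ones(len(pb))
    X_full = np.column_stack([ones, X_state, X_sample, x_depth])
    X_null = np.column_stack([ones, X_sample, x_depth])
    df_lrt = X_state.shape[1]

    rows = []
    n_fallback = 0
    totals = pb.sum(axis=0)
    for peak in pb.columns:
        if totals[peak] < min_reads:
            continue
        y = pb[peak].to_numpy(dtype=float)
        try:
            full = _nb_llf(y, X_full)
            null = _nb_llf(y, X_null)
            ll_full, ll_null = full.llf, null.llf
            effect = float(full.params[1])
            fallback = False
        except Exception:
            n_fallback += 1
            fallback = True
            full = sm.GLM(y, X_full, family=sm.families.Poisson()).fit()
            null = sm.GLM(y, X_null, family=sm.families.Poisson()).fit()
            ll_full, ll_null = full.llf, null.llf
            effect = float(full.params[1])
        lrt = max(0.0, 2.0 * (ll_full - ll_null))
        p = float(scipy.stats.chi2.sf(lrt, df_lrt))
        rows.append((peak, effect, lrt, p, fallback))
    res = pd.DataFrame(rows, columns=["feature", "beta", "lrt_stat", "p",
                                      "poisson_fallback"])
    if len(res):
        res["fdr"] = multipletests(res["p"], method="fdr_bh")[1]
        res["differential"] = res["fdr"] < fdr_alpha
    else:
        res["fdr"] = []
        res["differential"] = []
    res.attrs["n_poisson_fallback"] = n_fallback
    return res


# ---------------------------------------------------------- rank-sum markers

def wilcoxon_markers(normalized, feature_names, group_labels,
                     groups=None) -> pd.DataFrame:
    """One-vs-rest two-sided rank-sum marker statistics per feature.

    For each feature and group: tie-corrected Mann-Whitney p, AUC =
    U / (n1 * n2), and logFC = difference of group means of the normalized
    values. BH FDR is computed over the whole (feature, group) table.
    """
    x = normalized.toarray() if sp.issparse(normalized) \
        else np.asarray(normalized, dtype=float)
    labels = np.asarray(group_labels)
    if groups is None:
        groups = sorted(pd.unique(labels))
    rows = []
    for g in groups:
        in_g = labels == g
        n1, n2 = int(in_g.sum()), int((~in_g).sum())
        if n1 == 0 or n2 == 0:
            continue
        a, b = x[in_g], x[~in_g]
        with np.errstate(invalid="ignore"):
            res = scipy.stats.mannwhitneyu(a, b, axis=0,
                                           alternative="two-sided")
        auc = res.statistic / (n1 * n2)
        logfc = a.mean(axis=0) - b.mean(axis=0)
        p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
        for j, name in enumerate(feature_names):
            rows.append((g, name, float(logfc[j]), float(auc[j]),
                         float(p[j])))
    out = pd.DataFrame(rows, columns=["group", "feature", "logFC", "auc",
                                      "p"])
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) \
        else []
    return out


# -------------------------------------------------------------- concordance

def promoter_gene_concordance(gene_counts, gene_norm, gene_names,
                              peak_binary, peak_norm, peak_names,
                              peak_gene_map: pd.DataFrame,
                              state_labels, n_fragments,
                              sample_labels=None, min_cells: int = 50,
                              fdr_alpha: float = 0.10) -> pd.DataFrame:
    """Pair gene-expression and promoter-peak differential results between
    two states of one chromatin class.

    Genes and their chosen promoter peaks must show signal (>= 1 UMI /
    fragment) in strictly more than ``min_cells`` cells of the pair. A gene
    with several promoter peaks uses the one with the maximal normalized
    accessibility summed across the pair's cells. Gene significance is a
    two-sided rank-sum test on normalized expression; peak significance a
    logistic LRT on binarized accessibility with depth (and optionally
    sample) covariates. FDR is corrected separately within the two
    modalities, and ``direction_agrees`` compares the signs of the gene
    logFC and the peak beta.
    """
    states = sorted(pd.unique(np.asarray(state_labels)))
    if len(states) != 2:
        raise ValueError("concordance is defined for exactly two states")
    labels = np.asarray(state_labels)
    gc = sp.csc_matrix(gene_counts)
    pk_bin = sp.csc_matrix(peak_binary)
    pk_norm = sp.csc_matrix(peak_norm)
    gene_idx = {g: i for i, g in enumerate(gene_names)}
    peak_idx = {p: i for i, p in enumerate(peak_names)}

    detected_cells = np.asarray((gc > 0).sum(axis=0)).ravel()
    peak_cells = np.asarray((pk_bin > 0).sum(axis=0)).ravel()
    peak_signal = np.asarray(pk_norm.sum(axis=0)).ravel()

    pairs = []
    n_dropped_no_peak = 0
    mapped = peak_gene_map.dropna(subset=["gene"])
    by_gene = mapped.groupby("gene")["peak"].apply(list)
    for gene in pd.unique(mapped["gene"]):
        gi = gene_idx.get(gene)
        if gi is None or detected_cells[gi] <= min_cells:
            continue
        cand = [peak_idx[p] for p in by_gene[gene] if p in peak_idx]
        cand = [j for j in cand if peak_cells[j] > min_cells]
        if not cand:
            n_dropped_no_peak += 1
            continue
        j = cand[int(np.argmax(peak_signal[cand]))]
        pairs.append((gene, gi, j))
    if not pairs:
        out = pd.DataFrame(columns=["gene", "peak", "gene_logFC", "gene_p",
                                    "gene_fdr", "peak_beta", "peak_p",
                                    "peak_fdr", "direction_agrees"])
        out.attrs["n_dropped_no_peak"] = n_dropped_no_peak
        return out

    gsub = np.asarray(gene_norm.todense()) if sp.issparse(gene_norm) \
        else np.asarray(gene_norm, dtype=float)
    in_a = labels == states[0]
    gene_cols = [gi for _, gi, _ in pairs]
    mk = wilcoxon_markers(gsub[:, gene_cols],
                          [g for g, _, _ in pairs], labels,
                          groups=[states[0]])
    mk = mk.set_index("feature")

    tested = (labels == states[0]).astype(float)
    cov = scaled_log10(n_fragments)[:, None]
    peak_cols = sorted({j for _, _, j in pairs})
    if sample_labels is not None and len(pd.unique(sample_labels)) > 1:
        pk_res = _run_peak_lrts(pk_bin[:, peak_cols],
                                [peak_names[j] for j in peak_cols],
                                tested, cov, sample_labels)
    else:
        # single pooled sample: plain logistic, no sample term
        x = pk_bin[:, peak_cols]
        rows = []
        Z = np.column_stack([np.ones(len(tested)), tested, cov])
        for jj, j in enumerate(peak_cols):
            y = (np.asarray(x[:, jj].todense()).ravel() > 0).astype(float)
            if y.min() == y.max():
                rows.append((peak_names[j], np.nan, np.nan, np.nan, False))
                continue
            out = _logistic_lrt_one(y, Z, Z[:, [0, 2]], df=1)
            rows.append((peak_names[j], out.beta, out.lrt, out.p,
                         out.converged))
        pk_res = pd.DataFrame(rows, columns=["feature", "beta", "lrt_stat",
                                             "p", "converged"])
        ok = pk_res["converged"] & pk_res["p"].notna()
        pk_res["fdr"] = np.nan
        if ok.any():
            pk_res.loc[ok, "fdr"] = multipletests(pk_res.loc[ok, "p"],
                                                  method="fdr_bh")[1]
    pk_res = pk_res.set_index("feature")

    rows = []
    for gene, gi, j in pairs:
        pname = peak_names[j]
        g_logfc = mk.at[gene, "logFC"]
        g_p, g_fdr = mk.at[gene, "p"], mk.at[gene, "fdr"]
        if pname in pk_res.index:
            p_beta = pk_res.at[pname, "beta"]
            p_p, p_fdr = pk_res.at[pname, "p"], pk_res.at[pname, "fdr"]
        else:
            p_beta = p_p = p_fdr = np.nan
        agrees = (np.sign(g_logfc) == np.sign(p_beta)
                  if np.isfinite(p_beta) and g_logfc != 0 else False)
        rows.append((gene, pname, g_logfc, g_p, g_fdr, p_beta, p_p, p_fdr,
                     bool(agrees)))
    out = pd.DataFrame(rows, columns=["gene", "peak", "gene_logFC",
                                      "gene_p", "gene_fdr", "peak_beta",
                                      "peak_p", "peak_fdr",
                                      "direction_agrees"])
    # FDR within modalities over the retained pairs
    out["gene_fdr"] = multipletests(out["gene_p"], method="fdr_bh")[1]
    ok = out["peak_p"].notna()
    out.loc[ok, "peak_fdr"] = multipletests(out.loc[ok, "peak_p"],
                                            method="fdr_bh")[1]
    out["gene_significant"] = out["gene_fdr"] < fdr_alpha
    out["peak_significant"] = out["peak_fdr"] < fdr_alpha
    out.attrs["n_dropped_no_peak"] = n_dropped_no_peak
    return out
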