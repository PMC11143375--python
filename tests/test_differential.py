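"""Lineage/class logistic LRTs, pseudobulk NB LRT, rank-sum markers,
promoter-gene concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats
import statsmodels.api as sm

import chromstate as cs
from chromstate.differential import (PseudobulkMatrix, _irls_logistic,
                                     _one_hot, scaled_log10)
from chromstate.embedding import log_normalize


class TestDeriveLineage:
    MAT = sp.csr_matrix(np.array([[1, 0], [1, 1], [0, 0], [0, 1]]))

    def test_ternary_coding(self):
        lin = cs.derive_lineage(self.MAT, ["CD4p", "CD8Ap"], "CD4p", "CD8Ap")
        assert lin.tolist() == [1, 0, 0, -1]

    def test_missing_peak_errors(self):
        with pytest.raises(KeyError):
            cs.derive_lineage(self.MAT, ["CD4p", "CD8Ap"], "CD4p", "nope")


class TestLogisticEngine:
    def test_irls_matches_statsmodels(self):
        rng = np.random.default_rng(0)
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        beta_true = np.array([-0.5, 1.0, 0.0, -0.7])
        y = (rng.random(n)
             < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
        beta, llf, ok = _irls_logistic(y, X)
        fit = sm.Logit(y, X).fit(disp=0)
        assert ok
        assert np.allclose(beta, fit.params, atol=1e-8)
        assert llf == pytest.approx(fit.llf, abs=1e-8)

    def test_separation_flagged(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones(40), x])
        _, _, ok = _irls_logistic(y, X)
        assert not ok


def _planted_lineage_dataset(seed, **overrides):
    kw = dict(n_samples=3, cells_per_sample=667, n_peaks=500, n_genes=100,
              markers_per_state=5, n_lineage_peaks=20, lineage_effect=1.5,
              seed=seed)
    kw.update(overrides)
    return cs.generate_multiome(cs.SynthConfig(**kw))


class TestLineageAssociation:
    def test_planted_peaks_recovered_with_correct_sign(self):
        ds = _planted_lineage_dataset(1)
        binary = ds.peak_counts > 0
        nfrag = np.asarray(ds.peak_counts.sum(axis=1)).ravel()
        res = cs.lineage_association(binary, ds.peaks["peak"].tolist(),
                                     ds.cells["lineage_true"],
                                     ds.cells["class_true"],
                                     ds.cells["sample"], nfrag)
        role = ds.peaks.set_index("peak")["role"]
        res["role"] = role.loc[res["feature"]].to_numpy()
        planted = res[res["role"].str.match("lineage:")]
        assert (planted["significant"]).mean() >= 0.8
        cd4 = planted[planted["role"] == "lineage:CD4"]
        cd8 = planted[planted["role"] == "lineage:CD8A"]
        assert (cd4["beta"] > 0).all() and (cd4["direction"] == "CD4").all()
        assert (cd8["beta"] < 0).all()

    def test_null_p_values_calibrated(self):
        """Background-peak LRT p-values are approximately uniform."""
        ps = []
        for seed in (1, 2):
            ds = _planted_lineage_dataset(seed)
            binary = ds.peak_counts > 0
            nfrag = np.asarray(ds.peak_counts.sum(axis=1)).ravel()
            res = cs.lineage_association(binary, ds.peaks["peak"].tolist(),
                                         ds.cells["lineage_true"],
                                         ds.cells["class_true"],
                                         ds.cells["sample"], nfrag)
            role = ds.peaks.set_index("peak")["role"]
            null = ~role.loc[res["feature"]].str.startswith(
                "lineage").to_numpy()
            ps.extend(res.loc[null, "p"].tolist())
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.03 <= frac <= 0.07

    def test_constant_peak_excluded(self):
        rng = np.random.default_rng(3)
        n = 200
        mat = sp.csr_matrix(np.column_stack([
            np.ones(n), rng.integers(0, 2, n)]))
        res = cs.lineage_association(mat, ["const", "varying"],
                                     rng.choice([-1, 0, 1], n),
                                     rng.integers(0, 2, n),
                                     rng.choice(["a", "b"], n),
                                     rng.integers(100, 1000, n))
        assert res["feature"].tolist() == ["varying"]


class TestClassLogisticLRT:
    def _sim(self, seed, effect=True, confound=False):
        rng = np.random.default_rng(seed)
        n = 1000
        cls = rng.integers(0, 2, n)
        samp = rng.integers(0, 3, n)
        nfrag = rng.lognormal(7, 0.4, n)
        if confound:
            p = np.where(samp == 0, 0.6, 0.1)  # sample-driven, not class
        elif effect:
            p = np.where(cls == 1, 0.7, 0.1)
        else:
            p = np.full(n, 0.3)
        y = (rng.random(n) < p).astype(int)
        mat = sp.csr_matrix(y[:, None])
        return mat, (cls == 1).astype(float), samp.astype(str), nfrag

    def test_planted_class_effect(self):
        mat, ind, samp, nfrag = self._sim(0, effect=True)
        res = cs.class_logistic_lrt(mat, ["pk"], ind, samp, nfrag)
        assert res.loc[0, "beta"] > 1.0
        assert res.loc[0, "p"] < 1e-10

    def test_null_uniform_over_replicates(self):
        ps = []
        for seed in range(200):
            mat, ind, samp, nfrag = self._sim(seed, effect=False)
            res = cs.class_logistic_lrt(mat, ["pk"], ind, samp, nfrag)
            ps.append(res.loc[0, "p"])
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 <= frac <= 0.09

    def test_sample_confound_adjusted(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n = 1000
            samp = rng.integers(0, 3, n)
            # class balanced within samples; peak driven by sample only
            cls = rng.integers(0, 2, n)
            nfrag = rng.lognormal(7, 0.4, n)
            y = (rng.random(n) < np.where(samp == 0, 0.6, 0.1)).astype(int)
            res = cs.class_logistic_lrt(sp.csr_matrix(y[:, None]), ["pk"],
                                        (cls == 1).astype(float),
                                        samp.astype(str), nfrag)
            hits += res.loc[0, "p"] >= 0.05
        assert hits >= 18

    def test_reference_relabeling_invariance(self):
        """The LRT statistic does not depend on which class/sample level is
        the reference category."""
        mat, ind, samp, nfrag = self._sim(5, effect=True)
        res_a = cs.class_logistic_lrt(mat, ["pk"], ind, samp, nfrag)
        remap = {"0": "z_last", "1": "1", "2": "2"}
        res_b = cs.class_logistic_lrt(mat, ["pk"], ind,
                                      np.vectorize(remap.get)(samp), nfrag)
        assert res_a.loc[0, "lrt_stat"] == pytest.approx(
            res_b.loc[0, "lrt_stat"], abs=1e-6)

    def test_random_intercept_strategy_agrees_on_effect(self):
        mat, ind, samp, nfrag = self._sim(7, effect=True)
        fixed = cs.class_logistic_lrt(mat, ["pk"], ind, samp, nfrag,
                                      sample_effect="fixed")
        rand = cs.class_logistic_lrt(mat, ["pk"], ind, samp, nfrag,
                                     sample_effect="random")
        assert rand.loc[0, "p"] < 1e-6
        assert fixed.loc[0, "beta"] == pytest.approx(rand.loc[0, "beta"],
                                                     rel=0.1)


class TestPseudobulk:
    def test_toy_sums(self):
        mat = sp.csr_matrix(np.arange(12).reshape(6, 2))
        samples = ["s1", "s1", "s1", "s2", "s2", "s2"]
        states = ["a", "b", "a", "a", "b", "b"]
        pb = cs.pseudobulk_counts(mat, ["p0", "p1"], samples, states,
                                  min_sample_cells=0, min_state_cells=0,
                                  min_combo_cells=0)
        assert pb.counts.loc[("s1", "a")].tolist() == [0 + 4, 1 + 5]
        assert pb.counts.loc[("s2", "b")].tolist() == [8 + 10, 9 + 11]

    def test_small_sample_masked(self):
        rng = np.random.default_rng(0)
        n = 300
        samples = np.array(["s1"] * 140 + ["s2"] * 160)
        states = rng.choice(["a", "b"], n)
        mat = sp.csr_matrix(rng.poisson(1, (n, 3)))
        pb = cs.pseudobulk_counts(mat, list("xyz"), samples, states)
        s1 = pb.included.index.get_level_values("sample") == "s1"
        assert not pb.included[s1].any()

    def test_combo_threshold_strict(self):
        samples = ["s1"] * 160 + ["s2"] * 160
        states = (["a"] * 10 + ["b"] * 150) + (["a"] * 150 + ["b"] * 10)
        mat = sp.csr_matrix(np.ones((320, 1)))
        pb = cs.pseudobulk_counts(mat, ["p"], samples, states,
                                  min_state_cells=100)
        assert not pb.included[("s1", "a")]  # exactly 10 cells: strict >
        assert pb.included[("s1", "b")]


def _direct_pseudobulk(counts_df, nfrag=None):
    idx = counts_df.index
    nf = counts_df.sum(axis=1) if nfrag is None else nfrag
    return PseudobulkMatrix(counts_df, pd.Series(999, index=idx),
                            pd.Series(nf, index=idx),
                            pd.Series(True, index=idx))


class TestNbLrt:
    def _pb(self, seed, n_peaks=30, fc=1.0, n_diff=0):
        rng = np.random.default_rng(seed)
        idx = pd.MultiIndex.from_product(
            [[f"s{i}" for i in range(6)], ["a", "b"]],
            names=["sample", "state"])
        base = np.exp(rng.normal(np.log(150), 0.6, n_peaks))
        depth = np.exp(rng.normal(0, 0.2, 12))
        mu = np.outer(depth, base)
        state_b = np.tile([0.0, 1.0], 6)
        lfc = np.zeros(n_peaks)
        lfc[:n_diff] = np.log(fc)
        mu *= np.exp(np.outer(state_b, lfc))
        y = rng.poisson(mu)
        # nFragments reflects overall pseudobulk depth: in genome-wide data
        # the tested peaks are a negligible share of the total, so depth is
        # not confounded with the planted state effects
        return _direct_pseudobulk(pd.DataFrame(
            y, index=idx, columns=[f"p{j}" for j in range(n_peaks)]),
            nfrag=depth * 1e4)

    def test_low_count_peak_excluded(self):
        pb = self._pb(0, n_peaks=2)
        pb.counts["p0"] = 0
        pb.counts.loc[("s0", "a"), "p0"] = 4  # only 4 reads total
        res = cs.nb_lrt_differential(pb)
        assert "p0" not in set(res["feature"])

    def test_planted_fold_change_detected(self):
        pb = self._pb(1, n_peaks=30, fc=4.0, n_diff=5)
        res = cs.nb_lrt_differential(pb).set_index("feature")
        assert res.loc[[f"p{j}" for j in range(5)], "differential"].all()

    def test_effect_size_recovered(self):
        """Planted log fold changes in a minority of peaks are recovered
        with small bias (effects in all peaks would leak into the depth
        covariate instead)."""
        betas = []
        for seed in range(5):
            pb = self._pb(seed, n_peaks=40, fc=4.0, n_diff=8)
            res = cs.nb_lrt_differential(pb).set_index("feature")
            betas.extend(res.loc[[f"p{j}" for j in range(8)],
                                 "beta"].tolist())
        assert abs(np.mean(betas) - np.log(4.0)) < 0.1 * np.log(4.0)

    def test_reference_relabeling_invariance(self):
        pb = self._pb(2, n_peaks=5, fc=3.0, n_diff=2)
        res_a = cs.nb_lrt_differential(pb)
        flipped = pb.counts.rename(index={"a": "zz"}, level="state")
        pb_b = _direct_pseudobulk(flipped, pb.n_fragments.to_numpy())
        res_b = cs.nb_lrt_differential(pb_b)
        # identical up to optimizer convergence tolerance
        assert np.allclose(res_a["lrt_stat"], res_b["lrt_stat"], atol=1e-2)

    def test_too_few_states_errors(self):
        pb = self._pb(3, n_peaks=2)
        with pytest.raises(ValueError):
            cs.nb_lrt_differential(pb, states=["a"])


def _exact_ranksum_p(a, b):
    """Two-sided exact rank-sum p by full enumeration (no ties assumed)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        r = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    us = np.asarray(us)
    mean_u = len(b) * n1 / 2
    return np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-9)


class TestWilcoxonMarkers:
    def test_perfectly_separated_feature(self):
        x = np.concatenate([np.full(20, 5.0), np.zeros(20)])[:, None]
        labels = np.repeat(["A", "B"], 20)
        res = cs.wilcoxon_markers(x, ["f"], labels)
        row = res[(res["group"] == "A")].iloc[0]
        assert row["auc"] == 1.0
        assert row["p"] < 1e-6
        assert row["logFC"] == pytest.approx(5.0)

    def test_identical_groups_auc_half(self):
        x = np.tile(np.arange(10.0), 2)[:, None]
        labels = np.repeat(["A", "B"], 10)
        res = cs.wilcoxon_markers(x, ["f"], labels)
        assert res.iloc[0]["auc"] == pytest.approx(0.5)

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 5)
        b = rng.normal(1, 1, 5)
        x = np.concatenate([a, b])[:, None]
        res = cs.wilcoxon_markers(x, ["f"], np.repeat(["A", "B"], 5))
        row = res[res["group"] == "A"].iloc[0]
        assert row["p"] == pytest.approx(_exact_ranksum_p(a, b), abs=1e-9)
        # AUC equals P(random A value > random B value)
        mc = np.mean(a[:, None] > b[None, :])
        assert row["auc"] == pytest.approx(mc)

    def test_auc_is_exceedance_probability(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.5, 1, 40)
        b = rng.normal(0, 1, 60)
        x = np.concatenate([a, b])[:, None]
        res = cs.wilcoxon_markers(x, ["f"], ["A"] * 40 + ["B"] * 60)
        exceed = np.mean(a[:, None] > b[None, :])
        row = res[res["group"] == "A"].iloc[0]
        assert row["auc"] == pytest.approx(exceed, abs=1e-9)


class TestConcordance:
    def _dataset(self, seed=21):
        cfg = cs.SynthConfig(n_samples=2, cells_per_sample=400, n_peaks=400,
                             n_genes=200, markers_per_state=10, seed=seed)
        return cs.generate_multiome(cfg)

    def test_superstate_pattern(self):
        """State-marker genes differ in expression while their promoter
        peaks stay equally accessible between sibling states."""
        ds = self._dataset()
        pair = ds.cells["state_true"].isin([0, 1]).to_numpy()
        gene_counts = ds.gene_counts[pair]
        peak_bin = (ds.peak_counts[pair] > 0).astype(float)
        res = cs.promoter_gene_concordance(
            gene_counts, log_normalize(gene_counts),
            ds.genes["gene"].tolist(), peak_bin,
            cs.tfidf_normalize(peak_bin), ds.peaks["peak"].tolist(),
            ds.peaks[["peak", "gene"]].dropna(),
            ds.cells.loc[pair, "state_true"].to_numpy(),
            np.asarray(ds.peak_counts[pair].sum(axis=1)).ravel(),
            sample_labels=ds.cells.loc[pair, "sample"].to_numpy())
        markers = set(ds.genes.loc[ds.genes["marker_state"].isin([0, 1]),
                                   "gene"])
        sub = res[res["gene"].isin(markers)]
        assert len(sub) > 10
        assert sub["gene_significant"].mean() >= 0.8
        assert sub["peak_significant"].mean() <= 0.1

    def test_peak_with_max_summed_accessibility_chosen(self):
        n = 120
        rng = np.random.default_rng(6)
        gene_counts = sp.csr_matrix(rng.poisson(2.0, (n, 1)))
        # two promoter peaks for the same gene; peak q1 has more signal
        p0 = (rng.random(n) < 0.3).astype(float)
        p1 = (rng.random(n) < 0.9).astype(float)
        peak_bin = sp.csr_matrix(np.column_stack([p0, p1]))
        pg = pd.DataFrame({"peak": ["q0", "q1"], "gene": ["g", "g"]})
        res = cs.promoter_gene_concordance(
            gene_counts, log_normalize(gene_counts), ["g"], peak_bin,
            peak_bin.copy(), ["q0", "q1"], pg,
            np.repeat(["a", "b"], n // 2),
            rng.integers(100, 500, n).astype(float), min_cells=10)
        assert res.loc[0, "peak"] == "q1"

    def test_low_detection_gene_dropped(self):
        n = 200
        gene = np.zeros(n)
        gene[:50] = 1.0  # detected in exactly 50 cells: strict > 50 fails
        gene_counts = sp.csr_matrix(gene[:, None])
        peak = sp.csr_matrix((np.random.default_rng(7).random(n)
                              < 0.5).astype(float)[:, None])
        pg = pd.DataFrame({"peak": ["q"], "gene": ["g"]})
        res = cs.promoter_gene_concordance(
            gene_counts, log_normalize(gene_counts), ["g"], peak,
            peak.copy(), ["q"], pg, np.repeat(["a", "b"], n // 2),
            np.full(n, 100.0), min_cells=50)
        assert len(res) == 0


def test_scaled_log10_unit_variance():
    v = scaled_log10(np.array([100, 1000, 10000, 100000.0]))
    assert v.mean() == pytest.approx(0.0, abs=1e-12)
    assert v.std(ddof=1) == pytest.approx(1.0)


def test_one_hot_drops_reference():
    m = _one_hot(["a", "b", "c", "a"])
    assert m.shape == (4, 2)
    assert m[0].tolist() == [0, 0]
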