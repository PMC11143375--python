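"""Signed scores, marker-derived sets, motif enrichment, SNP prioritization
and track export."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

import chromstate as cs
from chromstate.synthetic import SignedSet


class TestSignedScore:
    def test_hand_computed_example(self):
        x = np.array([[2.0, 0.0, 1.0]])
        s = cs.signed_score(sp.csr_matrix(x), ["p1", "p2", "p3"],
                            SignedSet("t", ["p1", "p2"], ["p3"]))
        assert s[0] == pytest.approx((2 + 0) / 2 - 1 / 1)

    def test_all_zero_cell(self):
        x = sp.csr_matrix((1, 3))
        s = cs.signed_score(x, ["a", "b", "c"], SignedSet("t", ["a"], ["b"]))
        assert s[0] == 0.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.random((100, 20))
        names = [f"f{i}" for i in range(20)]
        pos = list(rng.choice(names, 6, replace=False))
        neg = [n for n in rng.choice(names, 8, replace=False)
               if n not in pos]
        sset = SignedSet("t", pos, neg)
        got = cs.signed_score(sp.csr_matrix(x), names, sset)
        for i in range(100):
            want = (sum(x[i, names.index(f)] for f in pos) / len(pos)
                    - sum(x[i, names.index(f)] for f in neg) / len(neg))
            assert got[i] == pytest.approx(want, abs=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_linearity_in_matrix(self, alpha):
        rng = np.random.default_rng(1)
        x = rng.random((10, 5))
        names = list("abcde")
        sset = SignedSet("t", ["a", "c"], ["e"])
        s1 = cs.signed_score(sp.csr_matrix(x), names, sset)
        s2 = cs.signed_score(sp.csr_matrix(alpha * x), names, sset)
        assert np.allclose(s2, alpha * s1, rtol=1e-10)

    def test_empty_sets_error(self):
        with pytest.raises(ValueError):
            SignedSet("t", [], [])

    def test_missing_feature_error(self):
        with pytest.raises(KeyError):
            cs.signed_score(sp.csr_matrix((2, 2)), ["a", "b"],
                            SignedSet("t", ["zz"], []))


def _exact_ranksum_greater(a, b):
    """One-sided exact rank-sum p (group a greater) by enumeration."""
    import scipy.stats
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    n1 = len(a)
    u_obs = ranks[:n1].sum()
    total = 0
    ge = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        ge += ranks[list(comb)].sum() >= u_obs - 1e-9
    return ge / total


class TestScoreGroupTest:
    def test_shifted_group_small_p(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.normal(1, 1, 100),
                                 rng.normal(0, 1, 100)])
        mask = np.repeat([True, False], 100)
        assert cs.score_group_test(scores, mask, "greater") < 1e-6

    def test_null_uniform_over_replicates(self):
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            scores = rng.normal(size=80)
            mask = np.zeros(80, dtype=bool)
            mask[rng.choice(80, 40, replace=False)] = True
            ps.append(cs.score_group_test(scores, mask, "greater"))
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 <= frac <= 0.09

    def test_small_sample_matches_enumeration(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=8)
        mask = np.array([True] * 4 + [False] * 4)
        got = cs.score_group_test(scores, mask, "greater")
        assert got == pytest.approx(
            _exact_ranksum_greater(scores[:4], scores[4:]), abs=1e-9)

    def test_constant_scores(self):
        with pytest.warns(UserWarning, match="constant"):
            p = cs.score_group_test(np.ones(10),
                                    np.array([True] * 5 + [False] * 5))
        assert p == 1.0


class TestBuildSignedSets:
    def _table(self):
        return pd.DataFrame({
            "group": ["A", "A", "B", "B"],
            "feature": ["f1", "f2", "f3", "f4"],
            "fdr": [0.05, 0.5, 0.01, 0.05],
            "logFC": [0.3, 0.3, 0.5, 0.3],
            "auc": [0.65, 0.65, 0.59, 0.7]})

    def test_gene_mode_thresholds(self):
        sset = cs.build_signed_sets_from_markers(self._table(), 0.1, 0.25,
                                                 0.6)
        assert sset.positive == ["f1"]  # f2 fails FDR
        assert sset.negative == ["f4"]  # f3 fails AUC > 0.6

    def test_peak_mode_thresholds(self):
        sset = cs.build_signed_sets_from_markers(self._table(), 0.1, 0.1,
                                                 0.58)
        assert "f3" in sset.negative

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            cs.build_signed_sets_from_markers(pd.DataFrame(), 0.1, 0.25,
                                              0.6)


class TestClassSpecificPeaks:
    def test_planted_peak_in_one_set_only(self):
        rng = np.random.default_rng(4)
        n = 300
        cls = rng.choice(["A", "B", "C"], n)
        x = rng.random((n, 3)) * 0.1
        x[cls == "A", 0] += 2.0  # exclusive to class A
        sets = cs.class_specific_peaks(x, ["p0", "p1", "p2"], cls)
        assert "p0" in sets["A"]
        assert "p0" not in sets["B"] and "p0" not in sets["C"]

    def test_uniform_peak_in_no_set(self):
        rng = np.random.default_rng(5)
        n = 300
        cls = rng.choice(["A", "B"], n)
        x = rng.random((n, 1))
        sets = cs.class_specific_peaks(x, ["p0"], cls)
        assert all(not v for v in sets.values())

    def test_impossible_cutoffs_empty(self):
        rng = np.random.default_rng(6)
        n = 200
        cls = rng.choice(["A", "B"], n)
        x = rng.random((n, 2))
        x[cls == "A", 0] += 5.0
        sets = cs.class_specific_peaks(x, ["p0", "p1"], cls, fdr_max=0.0,
                                       log2fc_min=np.inf)
        assert all(not v for v in sets.values())


def _exact_hypergeom_tail(k, M, K, n):
    """Upper-tail P(X >= k) by direct summation of binomial terms."""
    def choose(a, b):
        return math.comb(a, b) if 0 <= b <= a else 0
    total = choose(M, n)
    return sum(choose(K, x) * choose(M - K, n - x)
               for x in range(k, min(K, n) + 1)) / total


class TestMotifEnrichment:
    def _annot(self, rng, M=200, n_motifs=4, freq=0.1):
        peaks = [f"p{i}" for i in range(M)]
        annot = pd.DataFrame(rng.random((M, n_motifs)) < freq,
                             index=peaks,
                             columns=[f"m{j}" for j in range(n_motifs)])
        return peaks, annot

    def test_matches_exact_tail_oracle(self):
        rng = np.random.default_rng(7)
        peaks, annot = self._annot(rng)
        annot.iloc[:50, 0] = rng.random(50) < 0.8  # planted in class set
        sets = {"c0": peaks[:50]}
        res = cs.motif_enrichment(sets, annot, peaks)
        for _, row in res.iterrows():
            want = _exact_hypergeom_tail(int(row["k_in_set"]), 200,
                                         int(row["K_background"]), 50)
            assert row["p"] == pytest.approx(want, rel=1e-9)

    def test_background_frequency_not_selected(self):
        rng = np.random.default_rng(8)
        peaks, annot = self._annot(rng)
        res = cs.motif_enrichment({"c0": peaks[:50]}, annot, peaks)
        assert res["enrichment"].max() < 5
        assert not res["selected"].any()

    def test_enrichment_threshold_strict(self):
        df = pd.DataFrame({"class": ["c"], "motif": ["m"], "k_in_set": [5],
                           "n_set": [10], "K_background": [20],
                           "M_background": [100], "p": [1e-5],
                           "p_adj": [10**-4.9]})
        # enrichment 4.9 with threshold 5 must not be selected
        df["enrichment"] = -np.log10(df["p_adj"])
        sel = (df["enrichment"] >= 5.0)
        assert not sel.any()

    def test_expression_filter(self):
        rng = np.random.default_rng(9)
        peaks, annot = self._annot(rng)
        annot.iloc[:50, 0] = True
        sets = {"c0": peaks[:50]}
        tf_expr = pd.DataFrame({"TF0": [0.01]}, index=["c0"])
        res = cs.motif_enrichment(sets, annot, peaks, tf_expression=tf_expr,
                                  motif_tf_gene=pd.Series({"m0": "TF0"}))
        row = res[(res["motif"] == "m0")].iloc[0]
        assert row["enrichment"] >= 5  # enriched, but TF not expressed
        assert not row["selected"]


class TestSnpOverlap:
    PEAKS = pd.DataFrame({"chrom": ["chr1"], "start": [900], "end": [1100],
                          "peak": ["pk"]})

    def _snps(self, pos, pip):
        return pd.DataFrame({"chrom": ["chr1"], "pos": [pos],
                             "id": ["rs1"], "pip": [pip]})

    def test_low_pip_excluded(self):
        out = cs.snp_peak_overlap(self._snps(1000, 0.05), self.PEAKS)
        assert len(out) == 0

    def test_contained_snp_matches(self):
        out = cs.snp_peak_overlap(self._snps(1000, 0.9), self.PEAKS)
        assert out.loc[0, "peak"] == "pk"

    def test_halfopen_end_excluded(self):
        out = cs.snp_peak_overlap(self._snps(1100, 0.9), self.PEAKS)
        assert len(out) == 0

    def test_start_included(self):
        out = cs.snp_peak_overlap(self._snps(900, 0.9), self.PEAKS)
        assert len(out) == 1


class TestAccessibilityProfile:
    def test_single_accessible_class_z_formula(self):
        n_classes = 24
        rng = np.random.default_rng(10)
        labels = np.repeat([f"c{i}" for i in range(n_classes)], 10)
        x = np.zeros((len(labels), 1))
        x[labels == "c0", 0] = 10.0
        prof = cs.class_accessibility_profile(x, ["pk"], labels, ["pk"])
        means = np.zeros(n_classes)
        means[0] = 10.0
        z0 = (10.0 - means.mean()) / means.std(ddof=1)
        assert prof["z"].loc["c0", "pk"] == pytest.approx(z0)
        assert prof["accessible"]["pk"].sum() == 1

    def test_uniform_means_no_accessible_class(self):
        labels = np.repeat(["a", "b", "c"], 5)
        x = np.ones((15, 1))
        with pytest.warns(UserWarning, match="zero-variance"):
            prof = cs.class_accessibility_profile(x, ["pk"], labels, ["pk"])
        assert prof["degenerate_peaks"] == ["pk"]
        assert not prof["accessible"]["pk"].any()

    def test_exact_wilcoxon_top_block(self):
        """When one cell type's 5 classes outrank the other 19, the exact
        one-sided rank-sum p equals 1 / C(24, 5)."""
        n_classes = 24
        labels = np.repeat([f"c{i:02d}" for i in range(n_classes)], 4)
        x = np.zeros((len(labels), 1))
        for i in range(5):
            x[labels == f"c{i:02d}", 0] = 10.0 + i
        for i in range(5, n_classes):
            x[labels == f"c{i:02d}", 0] = float(i) / 100
        ct = {f"c{i:02d}": ("T" if i < 5 else "other")
              for i in range(n_classes)}
        prof = cs.class_accessibility_profile(x, ["pk"], labels, ["pk"],
                                              class_cell_type=ct)
        p = prof["cell_type_p"]
        p_t = p.loc[(p["cell_type"] == "T"), "p"].iloc[0]
        assert p_t == pytest.approx(1.0 / math.comb(24, 5), rel=1e-9)


class TestBedgraphExport:
    def _frags(self):
        return pd.DataFrame({
            "chrom": ["chr1"] * 3, "start": [100, 120, 300],
            "end": [150, 170, 350],
            "barcode": ["a1", "a2", "a1"]})

    def test_empty_group_region(self):
        frags = self._frags()
        groups = {"g": ["a1", "a2"]}
        out = cs.export_class_bedgraph(frags, groups, ("chr2", 0, 500))
        assert len(out["g"]) == 0

    def test_hand_computed_coverage(self):
        frags = self._frags()
        out = cs.export_class_bedgraph(frags, {"g": ["a1", "a2"]},
                                       ("chr1", 100, 200))
        track = out["g"]
        scale = 3 / 1e7
        # [100,120): 1 fragment; [120,150): 2; [150,170): 1
        got = {(r.start, r.end): r.value for r in track.itertuples()}
        assert got[(100, 120)] == pytest.approx(1 / scale)
        assert got[(120, 150)] == pytest.approx(2 / scale)
        assert got[(150, 170)] == pytest.approx(1 / scale)

    def test_scale_invariance_under_duplication(self):
        frags = self._frags()
        doubled = pd.concat([frags, frags], ignore_index=True)
        a = cs.export_class_bedgraph(frags, {"g": ["a1", "a2"]},
                                     ("chr1", 0, 400))["g"]
        b = cs.export_class_bedgraph(doubled, {"g": ["a1", "a2"]},
                                     ("chr1", 0, 400))["g"]
        pd.testing.assert_frame_equal(a, b)

    def test_zero_total_reads_error(self):
        with pytest.raises(ValueError, match="zero total"):
            cs.export_class_bedgraph(self._frags(), {"g": ["zz"]},
                                     ("chr1", 0, 400))
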