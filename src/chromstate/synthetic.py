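"""Synthetic multi-sample multiome data under a superstate generative model.

The generator produces paired chromatin (cell x peak) and expression
(cell x gene) counts for cells organized as transcriptional states nested
inside chromatin classes: all states of a class share the class's peak
openness profile exactly (the superstate assumption), and differ only in
the negative-binomial means of their marker genes. Per-(sample, peak)
batch shifts act on the logit-openness scale, per-cell depths are
log-normal, and peak counts are Poisson draws from the cell's depth
allocated over its normalized openness simplex, so that depth and
composition are decoupled.

Fixtures for every downstream stage are included: raw reads with planted
PCR duplicates, overlapping sub-peaks with q-values, promoter/gene
pairings, CD4/CD8A-style lineage-coupled promoter peaks, signed feature
sets, enriched motif annotations, and fine-mapped SNPs planted in
class-specific peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit, logit

from .config import ConfigurationError, SynthConfig

PEAK_WIDTH = 200
PEAK_SPACING = 1000
FRAGMENT_LEN = 50
LINEAGE_BASE_OPENNESS = 0.2
# the two dedicated CD4/CD8A promoter peaks drive the ternary lineage label,
# so their openness is near-deterministic: the derived label and the true
# lineage can then disagree only via sampling noise
LINEAGE_PROMOTER_OPEN = 0.9
LINEAGE_PROMOTER_CLOSED = 0.005


@dataclass
class SignedSet:
    """Named positive/negative feature sets for signed per-cell scores."""

    name: str
    positive: list = field(default_factory=list)
    negative: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.positive) & set(self.negative):
            raise ValueError("positive and negative sets must be disjoint")
        if not self.positive and not self.negative:
            raise ValueError("both feature sets are empty")


@dataclass
class SyntheticDataset:
    """Container for one generated multiome dataset with ground truth.

    ``cells`` carries the true sample/class/state/lineage labels;
    ``peaks`` the coordinates, promoter flags, gene pairings and role of
    every peak (``background``, ``class_specific:<c>``, ``lineage:CD4``,
    ``lineage:CD8A``, ``lineage_promoter:CD4`` / ``:CD8A``).
    ``fragments``/``reads`` are populated on demand (``include_reads=True``)
    because read-level tables are large.
    """

    config: SynthConfig
    cells: pd.DataFrame
    peaks: pd.DataFrame
    genes: pd.DataFrame
    peak_counts: sp.csr_matrix
    gene_counts: sp.csr_matrix
    sub_peaks: pd.DataFrame
    signed_sets: dict
    motif_annot: pd.DataFrame
    motif_tf_gene: pd.Series
    snps: pd.DataFrame
    fragments: pd.DataFrame | None = None
    reads: pd.DataFrame | None = None


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic child generators derived from one integer seed."""
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


# ------------------------------------------------------------------- layout

def _make_peaks(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay peaks on a toy genome and assign their generative roles."""
    P = cfg.n_peaks
    n_chrom = max(1, min(5, P // 200))
    per_chrom = int(np.ceil(P / n_chrom))
    chroms, starts = [], []
    for j in range(P):
        c, i = divmod(j, per_chrom)
        chroms.append(f"chr{c + 1}")
        starts.append(PEAK_SPACING + i * PEAK_SPACING)
    peaks = pd.DataFrame({
        "peak": [f"peak_{j}" for j in range(P)],
        "chrom": chroms,
        "start": np.asarray(starts, dtype=np.int64),
    })
    peaks["end"] = peaks["start"] + PEAK_WIDTH
    peaks["summit"] = peaks["start"] + PEAK_WIDTH // 2

    role = np.array(["background"] * P, dtype=object)
    order = rng.permutation(P)
    cursor = 0
    # two dedicated lineage promoter peaks drive the ternary label
    cd4_peak, cd8a_peak = order[0], order[1]
    role[cd4_peak] = "lineage_promoter:CD4"
    role[cd8a_peak] = "lineage_promoter:CD8A"
    cursor = 2
    half = cfg.n_lineage_peaks // 2
    for j in order[cursor:cursor + half]:
        role[j] = "lineage:CD4"
    for j in order[cursor + half:cursor + cfg.n_lineage_peaks]:
        role[j] = "lineage:CD8A"
    cursor += cfg.n_lineage_peaks
    n_specific = int(round(cfg.frac_class_specific * P))
    per_class = n_specific // cfg.n_classes
    for c in range(cfg.n_classes):
        for j in order[cursor:cursor + per_class]:
            role[j] = f"class_specific:{c}"
        cursor += per_class
    peaks["role"] = role

    is_prom = np.zeros(P, dtype=bool)
    special = role != "background"
    is_prom[special] = True
    n_prom_target = int(round(cfg.frac_promoter * P))
    pool = order[cursor:]
    extra = max(0, n_prom_target - int(special.sum()))
    is_prom[pool[:extra]] = True
    peaks["is_promoter"] = is_prom
    peaks["gene"] = None
    return peaks


def _make_genes(cfg: SynthConfig, peaks: pd.DataFrame,
                rng: np.random.Generator) -> pd.DataFrame:
    """Gene table with state-marker assignments and promoter-peak pairing.

    Each state's marker genes are paired with promoter peaks specific to
    that state's class, so that markers are differentially *expressed*
    between sibling states while their promoter peaks stay equally
    accessible — the pattern the concordance analysis quantifies.
    """
    G = cfg.n_genes
    genes = pd.DataFrame({"gene": [f"gene_{g}" for g in range(G)]})
    genes["base_mean"] = rng.lognormal(mean=np.log(0.3), sigma=0.8, size=G)
    genes["marker_state"] = -1
    genes["class_of_state"] = -1
    state = 0
    g_cursor = 0
    state_class = []
    for c, n_states in enumerate(cfg.states_per_class):
        for _ in range(n_states):
            idx = np.arange(g_cursor, g_cursor + cfg.markers_per_state)
            genes.loc[idx, "marker_state"] = state
            genes.loc[idx, "class_of_state"] = c
            state_class.append(c)
            g_cursor += cfg.markers_per_state
            state += 1

    # pair genes with promoter peaks: markers get class-specific promoters
    peak_gene = np.array([None] * len(peaks), dtype=object)
    for c in range(cfg.n_classes):
        class_peaks = np.flatnonzero(
            peaks["role"].to_numpy() == f"class_specific:{c}")
        class_peaks = class_peaks[
            peaks["is_promoter"].to_numpy()[class_peaks]]
        markers = genes.index[genes["class_of_state"] == c].to_numpy()
        take = min(len(class_peaks), len(markers))
        chosen = rng.choice(class_peaks, size=take, replace=False)
        for p_idx, g_idx in zip(chosen, markers[:take]):
            peak_gene[p_idx] = genes.at[g_idx, "gene"]
    # remaining promoter peaks paired with non-marker genes round-robin
    other_prom = np.flatnonzero(peaks["is_promoter"].to_numpy()
                                & pd.isna(peak_gene)
                                & (peaks["role"].to_numpy() == "background"))
    non_markers = genes.index[genes["marker_state"] < 0].to_numpy()
    for k, p_idx in enumerate(other_prom):
        if k >= len(non_markers):
            break
        peak_gene[p_idx] = genes.at[non_markers[k], "gene"]
    peaks["gene"] = peak_gene
    peaks.loc[peaks["role"] == "lineage_promoter:CD4", "gene"] = "CD4"
    peaks.loc[peaks["role"] == "lineage_promoter:CD8A", "gene"] = "CD8A"
    return genes


def _make_cells(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Cell table with balanced class/state assignment and lineage labels."""
    state_class = []
    for c, n_states in enumerate(cfg.states_per_class):
        state_class.extend([c] * n_states)
    state_class = np.asarray(state_class)
    S = len(state_class)
    rows = []
    for s in range(cfg.n_samples):
        states = np.tile(np.arange(S), cfg.cells_per_sample // S + 1)
        states = states[:cfg.cells_per_sample]
        states = rng.permutation(states)
        for i, t in enumerate(states):
            rows.append((f"S{s}_BC{i:05d}", f"sample_{s}", int(t),
                         int(state_class[t])))
    cells = pd.DataFrame(rows, columns=["barcode", "sample", "state_true",
                                        "class_true"])
    cells["lineage_true"] = rng.choice([1, -1], size=len(cells))
    cells["depth"] = rng.lognormal(cfg.depth_mu, cfg.depth_sigma,
                                   size=len(cells))
    return cells


# ------------------------------------------------------------------- counts

def _openness(cfg: SynthConfig, cells: pd.DataFrame, peaks: pd.DataFrame,
              rng: np.random.Generator) -> np.ndarray:
    """Per-cell peak openness probabilities on the logit scale."""
    n, P = len(cells), len(peaks)
    role = peaks["role"].to_numpy()
    class_of_peak = np.full(P, -1)
    for c in range(cfg.n_classes):
        class_of_peak[role == f"class_specific:{c}"] = c

    lo, hi = logit(cfg.p_open_low), logit(cfg.p_open_high)
    base = np.full(P, lo)
    lin_base = logit(LINEAGE_BASE_OPENNESS)
    is_lineage = pd.Series(role).astype(str).str.startswith(
        "lineage:").to_numpy()
    base[is_lineage] = lin_base

    cls = cells["class_true"].to_numpy()
    lin = cells["lineage_true"].to_numpy()
    logits = np.broadcast_to(base, (n, P)).copy()
    specific = class_of_peak >= 0
    logits[:, specific] = np.where(
        cls[:, None] == class_of_peak[None, specific], hi, lo)

    # lineage-coupled peaks: CD4-associated open in +1 cells, CD8A in -1
    cd4_assoc = role == "lineage:CD4"
    cd8_assoc = role == "lineage:CD8A"
    logits[:, cd4_assoc] += cfg.lineage_effect * lin[:, None]
    logits[:, cd8_assoc] -= cfg.lineage_effect * lin[:, None]
    cd4p = np.flatnonzero(role == "lineage_promoter:CD4")
    cd8p = np.flatnonzero(role == "lineage_promoter:CD8A")
    p_on, p_off = logit(LINEAGE_PROMOTER_OPEN), logit(LINEAGE_PROMOTER_CLOSED)
    logits[:, cd4p] = np.where(lin[:, None] > 0, p_on, p_off)
    logits[:, cd8p] = np.where(lin[:, None] > 0, p_off, p_on)

    # per-(sample, peak) batch shift, fixed across cells of the sample
    samples = pd.Categorical(cells["sample"])
    b = rng.normal(0.0, cfg.batch_sigma,
                   size=(len(samples.categories), P))
    logits += b[samples.codes]
    return expit(logits)


def _peak_counts(cells: pd.DataFrame, pi: np.ndarray,
                 rng: np.random.Generator) -> sp.csr_matrix:
    comp = pi / pi.sum(axis=1, keepdims=True)
    lam = comp * cells["depth"].to_numpy()[:, None]
    return sp.csr_matrix(rng.poisson(lam))


def _gene_counts(cfg: SynthConfig, cells: pd.DataFrame, genes: pd.DataFrame,
                 rng: np.random.Generator) -> sp.csr_matrix:
    n, G = len(cells), len(genes)
    mu = np.broadcast_to(genes["base_mean"].to_numpy(), (n, G)).copy()
    marker_state = genes["marker_state"].to_numpy()
    state = cells["state_true"].to_numpy()
    is_marker = marker_state >= 0
    mu[:, is_marker] *= np.where(
        state[:, None] == marker_state[None, is_marker], cfg.expr_fc, 1.0)
    size_factor = rng.lognormal(0.0, 0.3, size=n)
    mu *= size_factor[:, None]
    size = cfg.nb_dispersion
    p = size / (size + mu)
    return sp.csr_matrix(rng.negative_binomial(size, p))


# ----------------------------------------------------------------- fixtures

def _make_sub_peaks(peaks: pd.DataFrame,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Overlapping raw sub-peaks whose consolidation recovers the peaks.

    Each true peak emits one well-localized sub-peak (best q, summit at the
    true summit) plus 0-2 jittered competitors that overlap it, exercising
    the greedy-by-q de-overlap.
    """
    rows = []
    for pk in peaks.itertuples(index=False):
        best_q = 10.0 ** -rng.uniform(6.0, 12.0)
        width = int(rng.integers(300, 600))
        rows.append((pk.chrom, max(0, pk.summit - width // 2),
                     pk.summit + width // 2, pk.summit, best_q))
        for _ in range(int(rng.integers(0, 3))):
            jit = int(rng.integers(-80, 81))
            q = 10.0 ** -rng.uniform(2.0, 5.0)
            width = int(rng.integers(300, 600))
            s = pk.summit + jit
            rows.append((pk.chrom, max(0, s - width // 2), s + width // 2,
                         s, q))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "summit",
                                       "q"])


def fragments_from_counts(dataset: "SyntheticDataset",
                          seed: int | None = None) -> pd.DataFrame:
    """Materialize a fragments table consistent with the peak counts.

    Every count in ``peak_counts`` becomes one 50-bp fragment placed
    uniformly inside the peak, so counting fragments back into the peaks
    reproduces the matrix exactly.
    """
    rng = np.random.default_rng(
        dataset.config.seed + 10_007 if seed is None else seed)
    counts = sp.coo_matrix(dataset.peak_counts)
    pstart = dataset.peaks["start"].to_numpy()
    pchrom = dataset.peaks["chrom"].to_numpy()
    barcodes = dataset.cells["barcode"].to_numpy()
    total = int(counts.data.sum())
    rows = np.repeat(counts.row, counts.data)
    cols = np.repeat(counts.col, counts.data)
    offsets = rng.integers(0, PEAK_WIDTH - FRAGMENT_LEN, size=total)
    starts = pstart[cols] + offsets
    frags = pd.DataFrame({"chrom": pchrom[cols], "start": starts,
                          "end": starts + FRAGMENT_LEN,
                          "barcode": barcodes[rows]})
    return (frags.sort_values(["chrom", "start", "barcode"],
                              kind="mergesort").reset_index(drop=True))


def generate_reads(fragments: pd.DataFrame, dup_rate: float,
                   seed: int) -> pd.DataFrame:
    """Emit a read table with planted within-cell PCR duplicates.

    Each fragment appears once plus ``k`` extra copies in the same cell,
    with ``k ~ Geometric(dup_rate)`` on {0, 1, ...} (``dup_rate=0`` means no
    duplicates). Reads carry ``mate_start`` (the fragment end) and a CIGAR
    so paired-mode deduplication keys on the full fragment identity.
    ``is_duplicate_truth`` marks the planted copies; coordinate collisions
    between *different* cells are left unmarked (they are real fragments).
    ``attrs["n_unique_truth"]`` stores the number of distinct
    (barcode, chrom, start, mate) records — two input fragments of one cell
    that coincide exactly are indistinguishable, hence one unique record.
    """
    if not 0.0 <= dup_rate < 1.0:
        raise ValueError("dup_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(fragments)
    extra = (rng.geometric(1.0 - dup_rate, size=n) - 1 if dup_rate > 0
             else np.zeros(n, dtype=np.int64))
    reps = 1 + extra
    idx = np.repeat(np.arange(n), reps)
    reads = fragments.iloc[idx].reset_index(drop=True)
    first = np.zeros(len(idx), dtype=bool)
    first[np.cumsum(reps) - reps] = True
    reads["is_duplicate_truth"] = ~first
    reads["mate_start"] = reads["end"]
    reads["cigar"] = f"{FRAGMENT_LEN}M"
    reads["mapq"] = 60
    reads.attrs["n_unique_truth"] = int(
        fragments.drop_duplicates(
            subset=["barcode", "chrom", "start", "end"]).shape[0])
    return reads


def generate_snps(peaks: pd.DataFrame, n_snps: int, seed: int,
                  frac_in_class_peaks: float = 0.5) -> pd.DataFrame:
    """Fine-mapped SNP fixture with a fraction planted inside class peaks.

    Planted SNPs fall uniformly inside class-specific peaks; the rest are
    intergenic (between peaks). PIPs are Beta(0.5, 2) draws.
    """
    cols = ["chrom", "pos", "id", "pip", "in_class_peak_truth", "peak_truth"]
    if n_snps == 0:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(seed)
    role = (peaks["role"].astype(str) if "role" in peaks
            else pd.Series(["class_specific:0"] * len(peaks)))
    class_peaks = np.flatnonzero(
        role.str.startswith("class_specific").to_numpy())
    if not len(peaks):
        raise ValueError("peaks table is empty")
    n_in = int(round(frac_in_class_peaks * n_snps))
    rows = []
    chosen = rng.choice(class_peaks, size=n_in,
                        replace=n_in > len(class_peaks))
    for k, j in enumerate(chosen):
        pk = peaks.iloc[j]
        pos = int(rng.integers(pk["start"], pk["end"]))
        rows.append((pk["chrom"], pos, f"rs{k}", True, pk["peak"]))
    for k in range(n_in, n_snps):
        j = int(rng.integers(0, len(peaks)))
        pk = peaks.iloc[j]
        pos = int(pk["end"] + rng.integers(50, PEAK_SPACING - PEAK_WIDTH - 50))
        rows.append((pk["chrom"], pos, f"rs{k}", False, None))
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "id",
                                       "in_class_peak_truth", "peak_truth"])
    snps.insert(3, "pip", rng.beta(0.5, 2.0, size=n_snps))
    return snps


def generate_motifs(peaks: pd.DataFrame, class_specific_sets: dict,
                    n_motifs: int, seed: int,
                    planted_freq: float = 0.8,
                    background_freq: float = 0.1) -> pd.DataFrame:
    """Binary peak x motif annotation with one planted motif per class.

    Motif ``MOTIF_c`` (for class ``c``) occurs at ``planted_freq`` inside
    that class's specific peaks and ``background_freq`` elsewhere; the
    remaining motifs are uniform background.
    """
    rng = np.random.default_rng(seed)
    P = len(peaks)
    annot = rng.random((P, n_motifs)) < background_freq
    names = [f"MOTIF_{m}" for m in range(n_motifs)]
    peak_index = pd.Index(peaks["peak"])
    for c, (cls, peak_ids) in enumerate(sorted(class_specific_sets.items())):
        if c >= n_motifs:
            break
        rows = peak_index.get_indexer(pd.Index(peak_ids))
        annot[rows[rows >= 0], c] = rng.random(int((rows >= 0).sum())) \
            < planted_freq
    return pd.DataFrame(annot, index=peak_index, columns=names)


# ------------------------------------------------------------------- driver

def generate_multiome(config: SynthConfig,
                      include_reads: bool = False) -> SyntheticDataset:
    """Generate one multi-sample paired multiome dataset with ground truth.

    All randomness derives from ``config.seed``; the same config yields
    byte-identical outputs. ``include_reads`` additionally materializes the
    fragments table and a read table with planted duplicates (large for big
    configs, hence off by default).
    """
    if not isinstance(config, SynthConfig):
        raise ConfigurationError("expected a SynthConfig")
    (rng_layout, rng_cells, rng_open, rng_counts, rng_expr, rng_sub,
     rng_snp, rng_motif, rng_reads) = _child_rngs(config.seed, 9)

    peaks = _make_peaks(config, rng_layout)
    genes = _make_genes(config, peaks, rng_layout)
    cells = _make_cells(config, rng_cells)
    pi = _openness(config, cells, peaks, rng_open)
    peak_counts = _peak_counts(cells, pi, rng_counts)
    gene_counts = _gene_counts(config, cells, genes, rng_expr)
    sub_peaks = _make_sub_peaks(peaks, rng_sub)

    class_sets = {
        f"class_{c}": peaks.loc[peaks["role"] == f"class_specific:{c}",
                                "peak"].tolist()
        for c in range(config.n_classes)}
    snps = generate_snps(peaks, config.n_snps,
                         int(rng_snp.integers(2**31)))
    motif_annot = generate_motifs(peaks, class_sets, config.n_motifs,
                                  int(rng_motif.integers(2**31)))
    # planted motif for class c corresponds to TF gene = first marker gene
    # of class c's first state (guaranteed expressed in that class)
    tf_gene = {}
    for c, cls in enumerate(sorted(class_sets)):
        if c >= config.n_motifs:
            break
        markers = genes.index[genes["class_of_state"] == c]
        tf_gene[f"MOTIF_{c}"] = genes.at[markers[0], "gene"] if len(markers) \
            else genes.at[0, "gene"]
    for m in range(len(tf_gene), config.n_motifs):
        tf_gene[f"MOTIF_{m}"] = genes.at[
            int(rng_motif.integers(config.n_genes)), "gene"]

    signed_sets = {}
    if config.n_classes >= 2:
        signed_sets["class0_vs_class1_peaks"] = SignedSet(
            "class0_vs_class1_peaks",
            positive=class_sets["class_0"][:50],
            negative=class_sets["class_1"][:50])
    cd4 = peaks.loc[peaks["role"] == "lineage:CD4", "peak"].tolist()
    cd8 = peaks.loc[peaks["role"] == "lineage:CD8A", "peak"].tolist()
    if cd4 or cd8:
        signed_sets["lineage_peaks"] = SignedSet("lineage_peaks",
                                                 positive=cd4, negative=cd8)

    ds = SyntheticDataset(
        config=config, cells=cells, peaks=peaks, genes=genes,
        peak_counts=peak_counts, gene_counts=gene_counts,
        sub_peaks=sub_peaks, signed_sets=signed_sets,
        motif_annot=motif_annot, motif_tf_gene=pd.Series(tf_gene),
        snps=snps)
    if include_reads:
        ds.fragments = fragments_from_counts(
            ds, seed=int(rng_reads.integers(2**31)))
        ds.reads = generate_reads(ds.fragments, config.dup_rate,
                                  seed=int(rng_reads.integers(2**31)))
    return ds
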