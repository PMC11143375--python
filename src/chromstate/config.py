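"""Configuration objects shared across the pipeline.

All stage parameters live in small dataclasses so that a run is fully
described by one JSON-serializable object plus a single integer seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SynthConfig:
    """Parameters of the superstate generative model.

    The generator emulates a multi-sample single-cell multiome dataset in
    which transcriptional states are nested inside chromatin classes: states
    of the same class share the class's accessibility profile (the
    "superstate" assumption) and differ only in expression of their marker
    genes.

    Parameters
    ----------
    n_samples, cells_per_sample
        Number of donors/samples and cells per sample.
    n_classes, states_per_class
        Chromatin classes and the number of transcriptional states nested in
        each (``len(states_per_class) == n_classes``).
    n_peaks, frac_class_specific
        Total ATAC peaks and the fraction of them that are class-specific
        (split evenly across classes); the rest are shared background.
    p_open_high, p_open_low
        Bernoulli openness of a class-specific peak in cells of its class
        (high) and everywhere else (low).
    depth_mu, depth_sigma
        Log-normal parameters of per-cell fragment depth.
    batch_sigma
        SD of the per-(sample, peak) shift applied on the logit-openness
        scale, emulating sample-level technical variation.
    n_genes, markers_per_state, expr_fc, nb_dispersion
        RNA channel: genes, marker genes per state, the fold change applied
        to a state's markers in its cells, and the negative-binomial size
        (dispersion) parameter.
    frac_promoter
        Fraction of peaks flagged as promoter peaks.
    n_lineage_peaks, lineage_effect
        Number of lineage-coupled promoter peaks (half CD4-, half
        CD8A-associated) and the logit shift applied per unit of the ternary
        lineage code. Two dedicated CD4/CD8A promoter peaks are always added
        on top of these.
    dup_rate
        Within-cell PCR duplication probability used by ``generate_reads``.
    n_snps, n_motifs
        Fixture sizes for fine-mapped SNPs and motif annotations.
    seed
        Single integer seed; all sub-generators derive child seeds from it
        deterministically.
    """

    n_samples: int = 3
    cells_per_sample: int = 1000
    n_classes: int = 3
    states_per_class: list[int] = field(default_factory=lambda: [2, 2, 1])
    n_peaks: int = 2000
    frac_class_specific: float = 0.3
    p_open_high: float = 0.4
    p_open_low: float = 0.05
    depth_mu: float = math.log(2000.0)
    depth_sigma: float = 0.5
    batch_sigma: float = 0.3
    n_genes: int = 1000
    markers_per_state: int = 20
    expr_fc: float = 4.0
    nb_dispersion: float = 2.0
    frac_promoter: float = 0.25
    n_lineage_peaks: int = 20
    lineage_effect: float = 1.5
    dup_rate: float = 0.3
    n_snps: int = 100
    n_motifs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_class_specific", "p_open_high", "p_open_low",
                     "frac_promoter", "dup_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must lie in [0, 1]")
        if self.dup_rate >= 1.0:
            raise ConfigurationError("dup_rate must be < 1")
        if len(self.states_per_class) != self.n_classes:
            raise ConfigurationError(
                "states_per_class must have one entry per class")
        if self.n_total_states <= 0:
            raise ConfigurationError("total state count must be positive")
        n_special = self.n_lineage_peaks + 2 + int(
            round(self.frac_class_specific * self.n_peaks))
        if self.n_peaks < n_special:
            raise ConfigurationError(
                f"n_peaks={self.n_peaks} smaller than the {n_special} "
                "special (lineage + class-specific) peaks it must contain")
        total_markers = self.markers_per_state * self.n_total_states
        if total_markers > self.n_genes:
            raise ConfigurationError("more marker genes than genes")

    @property
    def n_total_states(self) -> int:
        return int(sum(self.states_per_class))

    @property
    def n_cells(self) -> int:
        return self.n_samples * self.cells_per_sample


@dataclass
class QCThresholds:
    """Cell-level QC gates for the ATAC and RNA modalities.

    ATAC cells pass with strictly more than ``min_reads`` deduplicated reads,
    at least ``min_frac_in_peak_neighborhood`` of those reads in peak
    neighborhoods (peaks dilated to ``neighborhood_scale`` times their full
    size), at least ``min_frac_promoter`` in promoter regions, and not more
    than ``max_frac_mito`` / ``max_frac_blacklist`` mitochondrial /
    blacklisted reads. RNA cells need at least ``rna_min_genes`` detected
    genes and strictly less than ``rna_max_frac_mito`` mitochondrial reads.
    """

    min_reads: int = 10000
    min_frac_in_peak_neighborhood: float = 0.5
    neighborhood_scale: int = 5
    min_frac_promoter: float = 0.10
    max_frac_mito: float = 0.10
    max_frac_blacklist: float = 0.10
    rna_min_genes: int = 500
    rna_max_frac_mito: float = 0.20

    def __post_init__(self) -> None:
        for name in ("min_frac_in_peak_neighborhood", "min_frac_promoter",
                     "max_frac_mito", "max_frac_blacklist",
                     "rna_max_frac_mito"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must lie in [0, 1]")


@dataclass
class RunConfig:
    """Top-level configuration for :func:`chromstate.pipeline.run_pipeline`.

    Dialect flags record choices the upstream literature leaves open so that
    alternative conventions can be compared: the TF-IDF scale factor, the
    Fisher OR estimate (conditional MLE vs sample OR) and the sample-effect
    strategy of the single-cell logistic models.
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    seed: int = 0
    # embedding / clustering
    n_components_broad: int = 20
    n_components_fine: int = 10
    n_variable_features: int = 1000
    snn_k: int = 20
    snn_prune: float = 1.0 / 15.0
    resolution: float = 0.1
    batch_method: str = "center"
    # superstate statistics
    knn_k: int = 5
    min_state_cells: int = 10
    or_fdr: float = 0.05
    or_estimate: str = "conditional"
    lda_train_frac: float = 0.75
    lda_min_cells: int = 50
    # differential tests
    lineage_fdr: float = 0.20
    pseudobulk_fdr: float = 0.10
    sample_effect: str = "fixed"
    # scores / enrichment / variants
    enrich_min: float = 5.0
    expr_min: float = 0.05
    pip_min: float = 0.1
    # dialects
    tfidf_scale: float = 1e4

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["synth"] = SynthConfig(**d["synth"])
        d["qc"] = QCThresholds(**d["qc"])
        return cls(**d)

    def config_hash(self) -> str:
        """Short stable hash embedded in every output file header."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
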