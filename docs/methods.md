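# Methods

`chromstate` implements a chromatin-class / transcriptional-state analysis
for paired single-cell ATAC + RNA data, together with a generative model of
such data used to exercise and validate every stage. This note documents the
models, the defaults and why they were chosen, the numerical decisions, and
what the synthetic validation does and does not establish about real data.

## The superstate model

The central object is the relationship between *chromatin classes* (clusters
defined from accessibility alone) and *transcriptional cell states* (fine
clusters defined from expression). A chromatin class is a **superstate**
when several transcriptional states nest inside it: they share one
accessibility profile and differ only transcriptionally, e.g. through
transcription-factor activity on already-open chromatin. The package
quantifies this relationship three ways:

1. **Class x state odds-ratio matrix.** For each (class, state) pair a 2x2
   contingency table of cell membership is tested with Fisher's exact test;
   the reported OR is the conditional maximum-likelihood estimate under the
   noncentral hypergeometric model (the convention of the classical
   `fisher.test` routines; the sample OR is available as an option). BH FDR
   is applied across all tested pairs at level 0.05, and states with 10 or
   fewer cells are excluded. For display, the natural-log OR of an infinite
   estimate is capped at plus-or-minus (1 + ceiling of the maximal finite
   |log OR| in the table).
2. **Pairwise LDA discriminability.** For every unordered pair of states
   with at least 50 cells each, a linear discriminant model predicts the
   state from the 10 fine-grain chromatin PCs plus one-hot sample dummies
   and scale(log10 fragment count), trained on a stratified 75% of cells
   and scored by AUC on the held-out 25%. Superstates manifest as
   within-class pair AUCs near 0.5 against across-class AUCs near 1. The
   75/25 split is stratified by state (re-drawn if a side lacks a state)
   and is computed from a label-independent permutation, so the AUC is
   exactly symmetric in the two states' roles. Pairs with a degenerate
   predictor (a single sample, constant depth) are marked skipped; a
   singular within-class covariance falls back to a small-shrinkage solver.
3. **Differential sparsity.** Promoter peaks are tested between states
   with single-cell logistic LRTs and with pseudobulk negative-binomial
   LRTs; under the superstate model genes differ while their promoter peaks
   do not, which the promoter-gene concordance table makes explicit.

## Processing chain

*Deduplication* is cell-aware: within each barcode, reads sharing
(start, mate start, CIGAR) — or start alone when mate information is absent,
as in single-end style inputs — collapse to one record, while identical
coordinates in different cells are kept, since independent cells genuinely
produce fragments at the same positions. Reads with MAPQ < 60, without a
barcode, or overlapping a blacklist are dropped first, with per-category
counts reported.

*Peak consolidation* trims each called sub-peak to 200 bp around its summit
and resolves overlaps greedily in ascending q-value order (ties broken by
chromosome and start for determinism), so the output is a fixed-width,
non-overlapping, coordinate-sorted peak set. Summits within 100 bp of a
contig start are clipped to [0, 200) with a warning rather than dropped.
Coordinates are 0-based half-open everywhere; overlap means at least one
shared base pair.

*Cell QC* keeps ATAC cells with strictly more than 10,000 reads, at least
50% of reads in 5x peak neighborhoods, at least 10% in promoters, and not
more than 10% mitochondrial or blacklisted reads; RNA cells need at least
500 genes and strictly less than 20% mitochondrial reads. Boundary
semantics are read literally from that phrasing ("more than" strict, "at
least"/"not more than" inclusive).

*Chromatin classing* binarizes the cell x peak matrix, restricts to peaks
with minimal accessibility (a fragment in at least 0.5% of the cell type's
cells, or an absolute 50-cell floor for sparse cell types), normalizes by
log(1 + 1e4 * TF * IDF), selects variable features by standardized variance
under a lowess mean-variance trend (fit on the 2nd-98th percentile of the
mean distribution and extrapolated flat, so isolated extreme features
cannot set their own expectation), scales, takes truncated PCA (20
components for broad cell types, 10 for fine-grain classes; component signs
fixed by making the largest-magnitude loading positive), adjusts batches,
and clusters an SNN graph (k = 20 neighbors, Jaccard edge weights pruned
below 1/15) with Louvain at a configurable resolution. Cluster labels are
renumbered by descending size.

The **batch-adjustment contract** is that per-sample component means equal
the global mean afterwards. The default adjuster is per-sample centering —
deliberately simple and deterministic; the interface accepts externally
adjusted embeddings so that mixing-based correctors can be injected for
real data where technical variation is not an additive shift.

The **clustering resolution** default for the fine-grain stage is 0.1,
chosen the way such resolutions are chosen in practice: scanning resolutions
on the default generator and keeping the value at which cluster boundaries
track the planted class structure rather than within-class depth
substructure, which emerges at higher resolutions. The resolution is a
config key recorded in every output.

*Label transfer* assumes reference and query share one embedding (the
synthetic data provides this directly; for real data a harmonized joint
embedding is an input, not computed here). A query cell takes the majority
label of its five nearest reference neighbors; ties go to the nearest
neighbor carrying a tied label; a call is high-confidence when at least 3
of the 5 neighbors agree. The direction is reversible (states onto
multiome cells, or classes onto reference cells).

## Differential models

Single-cell tests regress binarized peak accessibility on the tested term
with covariates, comparing full and null models by likelihood ratio:

- **lineage**: peak ~ lineage + class + sample + scale(log10 nFragments),
  null drops the ternary lineage code (+1 CD4-only open, -1 CD8A-only open,
  0 otherwise); positive beta = CD4-associated; FDR < 0.20.
- **class**: peak ~ class + sample + scale(log10 nFragments) with a
  one-vs-rest indicator, null drops the class term. The class beta is the
  reported effect; displays follow the source convention of labeling it
  "log2FC" even though it is a natural-log-odds coefficient (noted in the
  column documentation, not rescaled).

The sample term is a pluggable strategy. The default uses fixed-effect
one-hot sample dummies: deterministic, dependency-light, and — because the
sample terms appear in both the full and the null model — with the same LRT
degrees of freedom for the tested term as a random-intercept formulation,
to which it is asymptotically equivalent here. An optional
Laplace-approximated random intercept (`sample_effect="random"`) profiles
per-sample intercepts at their conditional modes and maximizes the
approximate marginal likelihood over the intercept SD. Peaks uniformly open
or closed after binarization are excluded before fitting; non-converged
fits (including quasi-separation, detected as diverging coefficients) are
flagged and excluded from the FDR correction with a reported count. The
logistic fits use a hand-written IRLS with step halving for speed across
thousands of peaks; unit tests pin it to statsmodels `Logit` at 1e-8.

Pseudobulk tests sum raw counts by (sample, state), mask samples with at
most 150 cells, states with at most 130, and combinations with at most 10
(strict thresholds), drop peaks with fewer than 5 reads across pseudobulks,
and compare NB regressions (one-hot state + one-hot sample +
scale(log10 nFragments)) with and without the state term, LRT df =
(#states - 1), BH FDR, differential at FDR < 0.10. The NB dispersion is
estimated by joint maximum likelihood within each model (the `glm.nb`
convention); a Poisson GLM fallback is used and flagged when the NB fit
fails. With 12 pseudobulks the asymptotic chi-square reference is adequate
for Poisson-like counts (the type-I rate is verified at 3-7% in the
acceptance suite) but becomes anticonservative under strong extra-Poisson
dispersion at this sample size — a documented limitation for small designs.

Expression markers use two-sided rank-sum tests on log-normalized values
(library size to 10,000), reporting AUC = U/(n1*n2) and logFC = difference
of group means of normalized values (the convention of the common
`wilcoxauc` routines), BH FDR over the whole feature x group table.
Signed-set construction uses the standard cutoffs FDR < 0.1, logFC > 0.25,
AUC > 0.6 for genes and FDR < 0.1, logFC > 0.1, AUC > 0.58 for peaks.

Promoter-gene concordance pairs each retained gene (signal in strictly more
than 50 cells of the state pair) with its promoter peak of maximal summed
normalized accessibility, tests genes by rank-sum and peaks by logistic
LRT (without the sample term when a single pooled sample is analyzed), and
corrects FDR separately within the two modalities.

## Scores, enrichment, variants

A signed score is the mean normalized signal over a positive feature set
minus the mean over a negative set; it is linear in the matrix and is used
for lineage, methylation-region and fibroblast-identity scores alike, with
one-sided rank-sum group tests. Motif enrichment in class-specific peaks
(one-vs-rest rank-sum markers at FDR <= 0.1 and log2FC >= 0.5) is a
hypergeometric upper tail against the peak universe, BH-adjusted; the
display filter keeps motifs with enrichment (-log10 adjusted p) of at
least 5, within 95% of the class maximum, and whose TF has mean normalized
expression of at least 0.05 in the class; heat-map values are scaled to the
percentage of each motif's cross-class maximum. SNP prioritization keeps
fine-mapped variants with PIP > 0.1, joins them to containing peaks
(half-open containment), z-scores each peak's class means across the class
axis, calls classes with z > 1 accessible, and tests cell-type specificity
with a one-sided *exact* rank-sum test on the class-level z values — exact
because the number of classes is small (~24), where the normal
approximation is poor. The per-peak z (rather than a joint z across the
peak x class grid) is the default scaling; the joint option exists because
the choice is genuinely ambiguous. Coverage tracks are per-bp counts scaled
by (group total reads / 1e7) so classes of different sizes are comparable.

## The synthetic generator

`generate_multiome` draws, per cell i (sample s, class c, state t):

- depth_i ~ LogNormal(depth_mu, depth_sigma);
- peak openness pi_ij = logistic(logit(p_high if peak j is specific to c,
  else p_low) + b_sj + lineage shift), with b_sj ~ Normal(0, batch_sigma)
  fixed per (sample, peak);
- counts_ij ~ Poisson(depth_i * pi_ij / sum_j pi_ij) — Poisson on a
  per-cell normalized openness simplex rather than per-peak Bernoulli, so
  that depth and composition are decoupled and depth-confound tests are
  possible;
- gene counts NB(size = nb_dispersion) with the mean multiplied by expr_fc
  for the cell's state's markers, times a log-normal cell size factor.

States of one class share the class's openness exactly — the superstate
assumption is built in, and each state's marker genes are paired with
promoter peaks specific to the state's class, giving the concordance
analysis its planted pattern. Two dedicated CD4/CD8A promoter peaks drive
the ternary lineage label with near-deterministic openness (0.9 matching /
0.005 non-matching), so the derived label disagrees with the true lineage
only via sampling noise; a configurable number of lineage-coupled peaks
receive a logit shift of lineage_effect per unit code. Fixtures for every
stage are generated alongside: fragments placed uniformly inside peaks (so
counting them back reproduces the matrix exactly), reads with planted
within-cell PCR duplicates (k extra copies, k ~ Geometric(dup_rate)),
overlapping sub-peaks with q-values whose consolidation recovers the peaks,
signed peak sets, one planted motif per class (frequency 0.8 in that
class's specific peaks vs 0.1 background), and fine-mapped SNPs with
Beta(0.5, 2) PIPs, half planted inside class-specific peaks. One integer
seed determines everything; sub-generators use spawned child seeds.

Default conditions: 3 samples x 1000 cells, 3 classes with states
[2, 2, 1], 2000 peaks of which 30% are class-specific, openness 0.4/0.05
(class-specific in/out of class), depth LogNormal(log 2000, 0.5), batch SD
0.3 on the logit scale, 1000 genes with 20 markers per state at 4-fold,
NB size 2. The accessibility effect sizes are not reported by upstream
studies; these defaults were chosen once to produce data of realistic
sparsity and class separability and are documented here as the package's
own choice. Lineage analyses use 500 peaks with 20 lineage-coupled peaks
at logit shift 1.5 over ~2000 cells; pseudobulk analyses use 6 samples x
400 cells (null: one class, two sibling states; planted: two classes at
openness 0.2/0.05, i.e. ~4-fold count effects).

**What the generator does not emulate:** genome sequence, fragment-length
or Tn5 insertion biases, doublets, ambient contamination, protein/hashtag
channels, nonlinear batch effects, or cluster-free continuous topologies.
Passing the validation suite therefore demonstrates the statistical
machinery is correct and calibrated under the stated model — not that any
biological conclusion transfers to a particular real dataset.

## Numerical choices and degenerate inputs

- All FDR corrections are Benjamini-Hochberg, applied within the scopes
  stated per analysis (per analysis; per modality for concordance).
- Exact tests (rank-sum with few groups, hypergeometric) are used wherever
  the sample size makes the normal approximation questionable; both are
  pinned to enumeration oracles in the tests.
- TF-IDF scale (1e4), OR estimate mode, and the sample-effect strategy are
  recorded in result-file headers so dialect drift is auditable.
- Zero-variance peaks in the accessibility profile get NaN z and a flag;
  all-zero cells normalize to zero rows with a warning; empty classes,
  single-cell samples, and missing chromosomes warn and degrade gracefully
  rather than fail.
- Louvain uses Python's `random` module under igraph; the clustering
  function saves, seeds and restores that state, making runs reproducible.

## Validation problem sizes

The test and acceptance suites run the full chain on 20 simulations of
3000 cells for class recovery, OR-matrix and LDA checks; 10 seeds of 2000
cells for the lineage LRT; a 1000-peak null and 20 planted-effect seeds for
the pseudobulk NB test; and exhaustive small-instance oracles (all 2x2
tables with margins <= 15; all hypergeometric instances with N <= 30; all
rank-sum sizes up to 10 per group). These sizes were chosen to estimate
the relevant rates stably while keeping the default suite quick on a
single core.
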