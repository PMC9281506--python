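# Methods

This note documents the models, defaults and design choices behind
`clonetraj`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Expression layers

All scoring operates on one of three gene × cell layers. Raw UMI counts
are log-normalized as `E = log2(1 + CPM/10)`, with counts-per-million
standing in for TPM: droplet UMI data carries no transcript-length bias,
so no length correction is applied. The relative layer `Er` centers each
gene across cells (per-gene mean 0), used where cross-gene comparability
matters more than absolute level.

QC removes cells expressing fewer than 1,500 distinct genes or with more
than 12% mitochondrial reads (genes prefixed `MT-`, case-insensitive —
the human convention; the rule is configurable), then keeps genes
detected in at least 10 of the surviving cells. The inequalities are
strict readings of "fewer than" and "more than": a cell at exactly 1,500
genes or exactly 12% mito is kept. Cell filters run before the gene
filter; because removing cells can push genes under the detection
threshold, re-running QC on its own output can drop further genes (a
fixed point is reached by the second pass), which is why the order is
part of the contract. On the bundled synthetic universe of ~2,000 genes
the demo uses a scaled-down distinct-gene cutoff of 300.

Clustering is the standard scanpy chain — dispersion-ranked highly
variable genes (default 5,000, clamped to the gene count), scaling, PCA
(default 50 components, reduced with a warning when cells are scarce),
k-NN graph, Leiden partition — all seeded, so labels are reproducible.
Only determinism and separability are contractual; the algorithm and
resolution are configuration. Cell-cycle regression is out of scope.

## Expression-inferred CNV

Copy proxies are estimated per gene and cell by the usual
expression-smoothing recipe:

1. drop genes with mean `E` below 0.1 or detected in fewer than 5 cells;
2. order the rest by chromosome and start position;
3. center each gene on its mean in the reference (non-malignant) cells;
4. clip to ±3 to bound outlier influence;
5. smooth along each chromosome with a centered 101-gene moving average,
   truncated at chromosome ends (chromosomes with fewer than 3 genes
   pass through unsmoothed, with a warning);
6. subtract each cell's median smoothed value;
7. subtract the residual per-gene reference mean;
8. denoise: residuals within 1.5 reference standard deviations are set
   to zero, so reference-like cells land exactly at baseline;
9. map the residual, which at this point is a log2 dosage ratio, to a
   copy proxy `c = clamp(2^r, 0, 2)` anchored at the reference median.

The window (101) and clip (±3) follow common expression-CNV practice and
are configurable. The moving average is computed as literal windowed
means rather than a cumulative-sum so that it is bit-identical to its
definition. The 0–2 mapping deliberately avoids rescaling by reference
percentiles: stretching the reference spread onto a fixed interval would
turn pure noise into apparent copy changes, whereas the identity-scale
exponential keeps a noise-only input at proxy ≈ 1 (measured reference
mean 1.004, and the contract asserted in tests is a reference grand mean
within [0.95, 1.05]). When raw counts are supplied, cells with totals
outside [5×10², 6×10⁶] are excluded before inference, mirroring the
min/max count filter convention of CNV-inference tools; it is not part
of global QC.

**Burden and malignancy.** The per-cell CNV level is
`Σ_g (c_g − 1)²` over the genes with raw count > 0 in that cell
("expressed" read as nonzero count; the definition makes the statistic
additive over disjoint gene sets and invariant to gene order). Cells are
called malignant when a 2-component Gaussian mixture on log1p burden
finds a bimodal split (model comparison by BIC against one component;
Otsu threshold as fallback) and both the cell and its cluster's mean sit
above the split point. The cluster-level gate uses the same split
threshold rather than the global median: in a mostly-malignant cohort
the median falls inside the malignant range and would flip borderline
clusters. A per-cluster majority vote smooths singleton flips, reference
cells are never called malignant, and a unimodal burden triggers a
warning path that labels clusters by mean burden only.

**Subclones.** Ward-linkage hierarchical clustering of cell CNV
profiles; k is chosen by maximal mean silhouette over 2–6 unless fixed.
A best silhouette below 0.1 flags the result low-confidence (the
expected outcome when no CNV differences exist). Differential CNV
between subclones is a per-gene two-sided Mann–Whitney on copy proxies
with BH adjustment and a mean-difference effect size; genes constant in
both groups get p = 1 by convention.

## Signature scoring and cell typing

Module scores use the binned-control scheme: genes are ranked into 25
equal-frequency bins by mean expression; each signature gene draws 100
control genes from its bin (with replacement when the bin is small, so
tiny gene universes cannot crash); the score is mean signature
expression minus mean control expression per cell. Bin and control
counts follow the established module-score convention since no
problem-specific values exist; both are configurable. All signatures in
one classification run share the control-sampling seed, which makes
scores comparable across signatures and gives identical gene lists
identical scores (ties are then broken by input order, with a warning).

SE (signature enrichment) typing averages per-cell scores within
clusters and assigns each cluster the arg-max cell type. rSE reverses
the direction: markers extracted from each unlabeled query cluster
(one-vs-rest Wilcoxon, BH within group, positive log fold change, top
100 by fold change) are scored on a typed reference, and the cluster
takes the reference type with the highest mean score. The agreement
statistic between the two routes is the proportion of clusters with
identical calls plus the Pearson correlation of the two cluster × type
score tables; no canonical formula exists, so this operationalization is
the package's own. Log fold changes are differences of mean `E` (a
log2-based quantity), documented so thresholds are interpretable.

The `undiff_score` is a deliberately simplified, gene-count-based
differentiation score, not a reimplementation of full
differentiation-potential estimators: cells expressing many distinct
genes are treated as less differentiated. Per-cell distinct-gene counts
are correlated with each gene's expression; the mean expression of the
200 most-correlated genes (optionally k-NN smoothed) is rank-normalized
to [0, 1]. A constant gene count across cells falls back to the rank of
the count itself, with a warning.

## Trajectory score and survival

The trajectory score is the module score of an undifferentiated marker
set minus that of a differentiated marker set, computed on the same
layer with the same parameters and seed; the pipeline derives the two
sets from NSC-like cells of the stem-dominant subclone and EpC-like
cells of the most differentiated subclone, falling back to plain
type-vs-rest markers when subclone labels are missing. The score is
antisymmetric under swapping the marker sets, and identical sets give
exactly zero.

Sample stratification uses the unweighted mean of per-sample mean scores
(not the pooled-cell mean) as the high/low threshold; ties go to low.
Survival uses Kaplan–Meier product-limit curves per group and the
two-group log-rank test, both via lifelines; a cohort with no events is
flagged rather than given a p-value. The log-rank χ²(1) reference is
asymptotic: its finite-sample bias against an exact permutation null is
on the order of 0.005 at a few dozen observations per group and falls
inside Monte-Carlo error (10⁵ draws) around 150 per group, which is the
size the validation test uses.

## Permutation statistics

The two-sample Fisher–Pitman test uses the linear statistic T = sum of
responses in one group. Exact mode enumerates all `C(n, n1)`
assignments; Monte-Carlo samples them with the +1 estimator correction.
The asymptotic mode does **not** use the plain normal reference (kept as
`mode="normal"` for parity with the R `coin` convention): it combines an
Edgeworth expansion on the exact finite-population cumulants of T
(second to fourth moments, verified against enumeration) near the
distribution center with a double-saddlepoint (Lugannani–Rice) tail
approximation beyond |z| = 1.5. The plain normal approximation deviates
from the exact p by up to ~0.03 at 10 observations per group; the
higher-order mode stays within ~0.02 there (measured over repeated
100-dataset draws), which is the tolerance asserted in the tests.
Two-sided p-values double the smaller tail, capped at 1, and are never 0.

Composition contrasts apply the test per cell type with BH adjustment
across types: between subclones, cells are the units and responses are
0/1 type indicators; between conditions, samples are the units and
responses are per-sample type proportions. How a single composition
p-value should be constructed is genuinely ambiguous, so the per-type
table plus the generic two-sample test is the exposed surface.

## Crosstalk

The interaction score for (source type, target type, ligand, receptor)
is mean ligand `E` in the source times mean receptor `E` in the target —
the product-of-means statistic — with significance from shuffling
cell-type labels (default 1,000 permutations,
`p = (1 + #{null ≥ obs}) / (n_perm + 1)`, BH across tuples). This is a
deliberately simple, fully specified stand-in for pathway-level
communication-probability models; the package's testable claims (null
calibration, recovery of planted axes, the recurrent-vs-primary
contrast) do not require the heavier model. The condition contrast tests
each ligand/receptor gene per cell type with a one-sided Mann–Whitney
(recurrent > primary), matching the directional question asked of
relapse cohorts. A small synthetic ligand–receptor table ships for tests
and the demo; real analyses should supply a curated database.

## Synthetic cohorts

`generate_cohort` draws negative-binomial (gamma-Poisson) counts with a
single shared dispersion (θ = 2) around a factorized mean: a lognormal
per-gene baseline (median 2.0, σ = 1.0; ~8,800 UMIs and ~1,450 detected
genes per cell of a 2,010-gene universe — detection is deliberately
high because the universe is ~10× smaller than a real transcriptome),
×4 type-marker boosts (40 exclusive genes per type), stem/differentiated
endpoint programs (60 genes each) interpolated linearly along each
malignant cell's planted pseudotime, multiplicative CNV dosage on
planted segments (malignant cells only; the dosage model is exactly the
assumption expression-inferred CNV relies on), and a library factor that
shrinks from 1.6 to 0.8 along the gradient so differentiated cells
express fewer distinct genes — the signal the gene-count score reads.
Gene identity (baselines and program membership) comes from a fixed
internal stream so cohorts generated with different seeds share the same
biology and signatures transfer between them like between patients.

Defaults plant: 7 malignant states (NSC-, RGC-, OPC-, AS-, OD-, NEU-,
EpC-like, 1,040 cells) plus microglia, endothelial and neuron
populations (300 cells, flat genome — the CNV reference); two equally
sized subclones carrying a 1.5× whole-chromosome gain (chr1) and a 0.5×
whole-chromosome loss (chr2) — chromosome-scale events being the
typical scale of ependymoma CNVs, and effect sizes chosen for
testability since real subclonal effect sizes are not published; 12
samples (6 primary / 6 recurrent) with stem-like cells preferentially
assigned to recurrent samples (logit tilt 1.5); a 10-gene "relapse
program" upregulated ×2 in every cell of recurrent samples (the planted
analogue of relapse-elevated ligand/receptor expression); 5%
mitochondrial reads; and exponential survival per sample whose hazard is
multiplied by `survival_effect^(stemness − 0.5)` (default effect 30,
administrative censoring at 72 months).

What passing tests show — and do not. The generator contains no
doublets, no ambient RNA, no batch effects, no cell-cycle structure, and
its noise is a single-dispersion NB. Recovery results (subclone ARI 1.0,
malignancy AUROC ≈ 0.96, trajectory Spearman ≈ −0.97 at default
settings) therefore certify the correctness of the algorithms under the
model's own assumptions, not their power on real tumors, where effect
sizes are smaller and confounders abound.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds (`numpy`
`default_rng`); the pipeline fans a single global seed out to per-stage
seeds by fixed offsets, and re-running a config byte-identically
reproduces every output file. Degenerate inputs take documented paths:
zero-total cells are an error in normalization, empty QC output is an
error, all-identical CNV profiles return one subclone with a warning,
no-event survival flags the p-value, missing ligand/receptor genes score
0 with p = 1. Outputs are plain TSV/MTX; the full gene × cell CNV proxy
matrix is not dumped by default (tens of MB as text) but is available as
a DataFrame.

## Known limitations

- No HMM-style CNV state calling; the copy proxy is a smoothed dosage
  ratio, so focal events much smaller than the window are attenuated.
- The burden statistic sums over expressed genes, so it scales with
  detection depth; comparisons across cells with very different depths
  inherit that bias.
- `undiff_score` is a heuristic; it will mis-rank cells whose
  distinct-gene count varies for technical rather than developmental
  reasons.
- The crosstalk score ignores pathway topology, cofactors and
  multi-subunit receptors.
- Log-rank is implemented for two groups only, matching its use here.
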