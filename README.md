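# clonetraj

Subclone, trajectory and crosstalk analysis for single-cell tumor
transcriptomics, built around the analysis style used for pediatric
ependymoma (EPN) cohorts: malignant cells are separated from the
microenvironment by expression-inferred copy number, split into CNV
subclones, placed on a neural-stem-cell (NSC) → ependymocyte (EpC)
differentiation axis by a per-cell *trajectory score*, and compared across
primary and recurrent samples in composition, survival and
ligand–receptor crosstalk.

The package is aimed at computational biologists who want these bespoke
steps as tested, reusable functions rather than one-off analysis scripts.
A built-in synthetic cohort generator plants every effect the pipeline
estimates (CNV subclones, a differentiation gradient, condition-linked
composition and survival, relapse-upregulated ligands), so the whole
pipeline is exercisable and testable without any data download.

## Methods at a glance

- **Expression-inferred CNV.** With log expression `E = log2(1 + CPM/10)`,
  genes are ordered along the genome, centered on a non-malignant
  reference population, clipped, and smoothed by a 101-gene moving
  average per chromosome. After per-cell median centering and a
  reference-noise denoising step, the residual log2 dosage ratio `r` maps
  to a copy proxy `c = clamp(2^r, 0, 2)` with 1 = normal copy.
- **CNV burden and subclones.** Per-cell burden is the quadratic sum
  `Σ (c_g − 1)^2` over that cell's expressed genes; malignancy is called
  from its bimodality, and subclones come from Ward-linkage hierarchical
  clustering of cell CNV profiles (k chosen by silhouette).
- **Module scores.** A signature's score is its mean expression minus the
  mean of expression-matched control genes (25 bins, 100 controls per
  gene), the binned-control scheme standard in single-cell tool kits.
- **Trajectory score.** `score(cell) = module_score(undifferentiated NSC
  markers) − module_score(differentiated EpC markers)`; higher = more
  stem-like. Sample means split cohorts into high/low trajectory groups
  for Kaplan–Meier / log-rank survival comparison.
- **Statistics.** Two-sample Fisher–Pitman permutation test (exact,
  Monte-Carlo and a higher-order asymptotic mode), Wilcoxon/Mann–Whitney
  and Kruskal–Wallis with exact small-sample modes, BH correction,
  permutation-based ligand–receptor interaction scores
  (product-of-means, CellPhoneDB style).

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from scipy.stats import spearmanr
from clonetraj import (SimConfig, generate_cohort, normalize_e, infer_cnv,
                       cnv_level, call_subclones, SignatureSet,
                       ModuleScoreParams, trajectory_score)

cohort = generate_cohort(SimConfig(rng_seed=0))   # ~1,300 cells, 2 subclones
counts, genes, meta, truth = cohort
e = normalize_e(counts)

reference = list(truth.loc[~truth.true_malignant, "cell_id"][:300])
cnv = infer_cnv(e, genes, reference)
sub = call_subclones(cnv, cells=list(truth.loc[truth.true_malignant, "cell_id"]))
ari = adjusted_rand_score(
    truth.set_index("cell_id").loc[sub.labels.index, "true_subclone"], sub.labels)
print(f"subclones: k={sub.k}, silhouette={sub.silhouette:.2f}, ARI vs truth={ari:.2f}")

traj = trajectory_score(
    e, SignatureSet("undiff", cohort.programs["stem_program"]),
    SignatureSet("diff", cohort.programs["diff_program"]),
    ModuleScoreParams(rng_seed=0))
rho = spearmanr(traj.loc[sub.labels.index, "trajectory_score"],
                truth.set_index("cell_id").loc[sub.labels.index,
                                               "true_pseudotime"]).statistic
print(f"trajectory score vs planted pseudotime: Spearman rho = {rho:.2f}")
```

prints

```
subclones: k=2, silhouette=0.40, ARI vs truth=1.00
trajectory score vs planted pseudotime: Spearman rho = -0.97
```

The two planted subclones (a 1.5× whole-chromosome gain and a 0.5× loss)
are recovered perfectly from expression alone, and the trajectory score
orders malignant cells along the planted differentiation gradient
(negative correlation because pseudotime 0 is the stem end).

The same analysis end-to-end, from files on disk to TSV outputs:

```bash
clonetraj demo --seed 7 --workdir demo_run
ls demo_run/output   # QC report, cell types, CNV burden, subclones,
                     # trajectory scores, composition tests, KM curves,
                     # crosstalk tables, run log
```

## Layout

| module | contents |
| --- | --- |
| `clonetraj.simulate` | synthetic cohort generator (`SimConfig`, `generate_cohort`, `write_10x_mtx`) |
| `clonetraj.io_qc` | MTX reading, QC filters, normalization, Leiden clustering |
| `clonetraj.signatures` | module scores, marker detection, SE/rSE typing, gene-count differentiation score |
| `clonetraj.cnv` | CNV inference, burden, subclones, malignancy, differential CNV |
| `clonetraj.trajectory` | trajectory score, sample stratification, rank tests, KM/log-rank |
| `clonetraj.crosstalk` | ligand–receptor permutation scores, recurrent-vs-primary contrast |
| `clonetraj.stats` | Fisher–Pitman permutation test, composition contrasts, correlation |
| `clonetraj.pipeline` / `clonetraj.cli` | stage orchestration, YAML config, `clonetraj` command |

See `docs/methods.md` for model assumptions, parameter defaults and known
limitations.
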