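"""Synthetic single-cell cohorts with planted structure.

Generates ependymoma-like UMI count matrices in which every quantity the
pipeline later estimates is known by construction: malignant cell states
arranged along a neural-stem-cell (NSC) to ependymocyte (EpC)
differentiation gradient, two CNV-defined subclones acting multiplicatively
on gene dosage, non-malignant reference populations with a flat genome,
mitochondrial read fractions, multi-sample structure with primary/recurrent
conditions, and per-sample survival whose hazard depends on planted
stemness.

The count model is negative-binomial (gamma-Poisson) with a single shared
dispersion. The mean of gene ``g`` in cell ``c`` factorizes as

    mu[g, c] = base[g] * marker[g, type(c)] * gradient[g, pt(c)]
               * cnv[g, subclone(c)] * lib(c)

where ``pt`` is the planted pseudotime (0 = most stem-like), ``cnv`` is the
copy factor of any planted segment covering ``g`` (malignant cells only),
and ``lib`` shrinks with pseudotime so that differentiated cells express
fewer distinct genes — the signal a gene-count differentiation score
recovers.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .containers import CellMeta, ExpressionMatrix, validate_gene_annotation

MALIGNANT_TYPES = (
    "NSC-like",
    "RGC-like",
    "OPC-like",
    "AS-like",
    "OD-like",
    "NEU-like",
    "EpC-like",
)
NORMAL_TYPES = ("Mic", "EC", "Neuron")

# effect sizes of the planted programs (fold change on the NB mean)
MARKER_BOOST = 4.0
GRADIENT_BOOST = 2.5
MARKERS_PER_TYPE = 40
PROGRAM_SIZE = 60
RELAPSE_SIZE = 10       # genes upregulated cohort-wide in recurrent samples
RELAPSE_BOOST = 2.0
BASE_MEAN = 2.0         # median of the per-gene baseline NB means
BASE_SIGMA = 1.0        # lognormal spread of the baseline means
LIB_STEM = 1.6          # library-size factor at pseudotime 0
LIB_DIFF = 0.8          # ... and at pseudotime 1
LIB_NOISE_SD = 0.15
PSEUDOTIME_SD = 0.08
CONDITION_TILT = 1.5    # log-odds scale of stem-cell enrichment in recurrent samples
BASE_HAZARD = 1.0 / 36.0
CENSOR_HORIZON = 72.0


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    ``cnv_segments`` rows are ``(subclone, chromosome, start_gene, end_gene,
    copy_factor)`` with within-chromosome gene indices, start inclusive and
    end exclusive. Mitochondrial genes are appended on ``chrM`` beyond
    ``n_genes``.
    """

    n_cells_per_type: dict[str, int] = field(
        default_factory=lambda: {
            "NSC-like": 220,
            "RGC-like": 150,
            "OPC-like": 130,
            "AS-like": 120,
            "OD-like": 120,
            "NEU-like": 120,
            "EpC-like": 180,
            "Mic": 120,
            "EC": 80,
            "Neuron": 100,
        }
    )
    n_genes: int = 2000
    n_chromosomes: int = 10
    genes_per_chromosome: int = 200
    cnv_segments: list[tuple] = field(
        default_factory=lambda: [
            ("subclone1", "chr1", 0, 200, 1.5),
            ("subclone2", "chr2", 0, 200, 0.5),
        ]
    )
    subclone_fractions: dict[str, float] = field(
        default_factory=lambda: {"subclone1": 0.5, "subclone2": 0.5}
    )
    gradient_types: tuple[str, ...] = MALIGNANT_TYPES
    nb_dispersion: float = 2.0
    mito_gene_count: int = 10
    mito_fraction_mean: float = 0.05
    n_samples: int = 12
    condition_per_sample: tuple[str, ...] = ()
    survival_effect: float = 30.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.condition_per_sample:
            self.condition_per_sample = tuple(
                "primary" if i % 2 == 0 else "recurrent" for i in range(self.n_samples)
            )
        self.validate()

    def validate(self) -> None:
        if self.n_genes != self.n_chromosomes * self.genes_per_chromosome:
            raise ValueError("n_genes must equal n_chromosomes * genes_per_chromosome")
        total = sum(self.subclone_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subclone fractions sum to {total}, expected 1")
        chroms = {f"chr{i + 1}" for i in range(self.n_chromosomes)}
        for sub, chrom, start, end, factor in self.cnv_segments:
            if sub not in self.subclone_fractions:
                raise ValueError(f"segment references unknown subclone {sub!r}")
            if chrom not in chroms:
                raise ValueError(f"segment on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= self.genes_per_chromosome):
                raise ValueError(
                    f"segment [{start}, {end}) outside chromosome of "
                    f"{self.genes_per_chromosome} genes"
                )
            if factor <= 0:
                raise ValueError("copy factor must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.mito_fraction_mean < 1:
            raise ValueError("mito_fraction_mean must lie in [0, 1)")
        if len(self.condition_per_sample) != self.n_samples:
            raise ValueError("condition_per_sample length must equal n_samples")
        bad = set(self.condition_per_sample) - {"primary", "recurrent"}
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")
        unknown = [t for t in self.gradient_types if t not in self.n_cells_per_type]
        if unknown:
            raise ValueError(f"gradient types without cell counts: {unknown}")

    def to_yaml(self, path) -> None:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        d["cnv_segments"] = [list(s) for s in self.cnv_segments]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "cnv_segments" in d:
            d["cnv_segments"] = [tuple(s) for s in d["cnv_segments"]]
        for key in ("gradient_types", "condition_per_sample"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Cohort:
    """Bundle returned by :func:`generate_cohort`.

    Iterating yields ``(counts, genes, cell_meta, truth)`` so the bundle
    unpacks like a tuple; ``samples`` and ``programs`` expose per-sample
    ground truth and the planted gene programs.
    """

    counts: ExpressionMatrix
    genes: pd.DataFrame
    cell_meta: CellMeta
    truth: pd.DataFrame
    samples: pd.DataFrame
    programs: dict[str, list[str]]

    def __iter__(self):
        return iter((self.counts, self.genes, self.cell_meta, self.truth))


def _gene_universe(config: SimConfig) -> pd.DataFrame:
    rows = []
    g = 0
    for c in range(config.n_chromosomes):
        for i in range(config.genes_per_chromosome):
            rows.append((f"G{g:05d}", f"chr{c + 1}", i * 10_000, i * 10_000 + 1_000))
            g += 1
    for m in range(config.mito_gene_count):
        rows.append((f"MT-G{m + 1}", "chrM", m * 1_000, m * 1_000 + 500))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])


def generate_cohort(config: SimConfig | None = None) -> Cohort:
    """Draw one synthetic cohort from ``config`` (deterministic per seed)."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    # gene identity (baseline abundance, program membership) is a property of
    # the simulated tissue, not of one cohort draw: it comes from a fixed
    # stream so cohorts generated with different seeds share the same biology
    # and signatures transfer between them, as between patients.
    gene_rng = np.random.default_rng(990331)
    genes = _gene_universe(config)
    n_auto = config.n_genes
    gene_ids = genes["gene_id"].to_numpy()

    # ---- per-gene baseline means (lognormal, heavy-tailed like real UMI data)
    base = gene_rng.lognormal(mean=np.log(BASE_MEAN), sigma=BASE_SIGMA, size=n_auto)

    # ---- genes claimed by planted CNV segments (kept free of programs)
    seg_mask = np.zeros(n_auto, dtype=bool)
    chrom_offset = {
        f"chr{i + 1}": i * config.genes_per_chromosome for i in range(config.n_chromosomes)
    }
    for _, chrom, start, end, _ in config.cnv_segments:
        off = chrom_offset[chrom]
        seg_mask[off + start : off + end] = True

    # ---- planted gene programs: type markers + gradient endpoint programs
    all_types = list(config.n_cells_per_type)
    free = np.flatnonzero(~seg_mask)
    gene_rng.shuffle(free)
    need = len(all_types) * MARKERS_PER_TYPE + 2 * PROGRAM_SIZE + RELAPSE_SIZE
    if need > len(free):
        raise ValueError("gene universe too small for the planted programs")
    cursor = 0
    programs: dict[str, list[str]] = {}
    marker_idx: dict[str, np.ndarray] = {}
    for t in all_types:
        idx = np.sort(free[cursor : cursor + MARKERS_PER_TYPE])
        cursor += MARKERS_PER_TYPE
        marker_idx[t] = idx
        programs[f"markers:{t}"] = list(gene_ids[idx])
    stem_idx = np.sort(free[cursor : cursor + PROGRAM_SIZE])
    cursor += PROGRAM_SIZE
    diff_idx = np.sort(free[cursor : cursor + PROGRAM_SIZE])
    cursor += PROGRAM_SIZE
    relapse_idx = np.sort(free[cursor : cursor + RELAPSE_SIZE])
    programs["stem_program"] = list(gene_ids[stem_idx])
    programs["diff_program"] = list(gene_ids[diff_idx])
    programs["relapse_program"] = list(gene_ids[relapse_idx])

    # ---- cells: types, pseudotime, subclones
    types, pts = [], []
    grad = list(config.gradient_types)
    for t, n in config.n_cells_per_type.items():
        types.extend([t] * n)
        if t in grad:
            center = 0.5 if len(grad) == 1 else grad.index(t) / (len(grad) - 1)
            pts.extend(np.clip(rng.normal(center, PSEUDOTIME_SD, size=n), 0, 1))
        else:
            pts.extend([np.nan] * n)
    types = np.array(types)
    pts = np.array(pts)
    n_cells = len(types)
    malignant = np.isin(types, grad)

    sub_names = list(config.subclone_fractions)
    sub_probs = np.array([config.subclone_fractions[s] for s in sub_names])
    subclones = np.full(n_cells, None, dtype=object)
    n_mal = int(malignant.sum())
    subclones[malignant] = rng.choice(sub_names, size=n_mal, p=sub_probs)

    # ---- sample assignment: recurrent samples enriched for stem-like cells
    sample_ids = np.array([f"S{i + 1:02d}" for i in range(config.n_samples)])
    cond = np.array(config.condition_per_sample)
    z = np.where(cond == "recurrent", 1.0, -1.0)
    assign = np.empty(n_cells, dtype=object)
    u = rng.random(n_cells)
    for i in range(n_cells):
        if malignant[i]:
            w = np.exp(CONDITION_TILT * z * (0.5 - pts[i]))
        else:
            w = np.ones(config.n_samples)
        w = w / w.sum()
        assign[i] = sample_ids[np.searchsorted(np.cumsum(w), u[i])]

    # ---- mean matrix (genes x cells)
    mu = np.tile(base[:, None], (1, n_cells))
    for t in all_types:
        cols = types == t
        mu[np.ix_(marker_idx[t], cols)] *= MARKER_BOOST
    mal_cols = np.flatnonzero(malignant)
    p_mal = pts[mal_cols]
    mu[np.ix_(stem_idx, mal_cols)] *= 1 + GRADIENT_BOOST * (1 - p_mal)
    mu[np.ix_(diff_idx, mal_cols)] *= 1 + GRADIENT_BOOST * p_mal
    for sub, chrom, start, end, factor in config.cnv_segments:
        off = chrom_offset[chrom]
        cols = np.flatnonzero(subclones == sub)
        if len(cols):
            mu[np.ix_(np.arange(off + start, off + end), cols)] *= factor

    # relapse program: upregulated in every cell of a recurrent sample
    cond_of_sample = dict(zip(sample_ids, cond))
    recurrent_cells = np.flatnonzero(
        np.array([cond_of_sample[s] == "recurrent" for s in assign])
    )
    if len(recurrent_cells):
        mu[np.ix_(relapse_idx, recurrent_cells)] *= RELAPSE_BOOST

    lib = np.ones(n_cells)
    lib[mal_cols] = LIB_STEM + (LIB_DIFF - LIB_STEM) * p_mal
    lib *= rng.lognormal(0.0, LIB_NOISE_SD, size=n_cells)

    # mitochondrial means sized so the realized fraction tracks the target
    if config.mito_gene_count:
        f = config.mito_fraction_mean
        mito_total = (f / (1 - f)) * base.sum() if f > 0 else 0.0
        mito_base = np.full(config.mito_gene_count, mito_total / config.mito_gene_count)
        mu = np.vstack([mu, np.tile(mito_base[:, None], (1, n_cells))])
    mu *= lib[None, :]

    # ---- negative-binomial draws (gamma-Poisson)
    theta = config.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(np.int64)

    cell_ids = [f"C{i:05d}" for i in range(n_cells)]
    matrix = ExpressionMatrix(counts, list(gene_ids), cell_ids, layer="counts")

    # ---- per-sample truth: stemness -> hazard -> survival
    stemness = np.full(config.n_samples, 0.5)
    for j, s in enumerate(sample_ids):
        in_s = (assign == s) & malignant
        if in_s.any():
            stemness[j] = np.mean(1 - pts[in_s])
    hazard = BASE_HAZARD * config.survival_effect ** (stemness - 0.5)
    raw_t = rng.exponential(1 / hazard)
    surv_time = np.minimum(raw_t, CENSOR_HORIZON)
    event = raw_t < CENSOR_HORIZON
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": cond,
            "true_stemness": stemness,
            "true_hazard": hazard,
            "survival_time": surv_time,
            "event": event,
        }
    )

    sample_row = {s: j for j, s in enumerate(sample_ids)}
    rows = [sample_row[s] for s in assign]
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "true_type": types,
            "true_subclone": [s if s is not None else pd.NA for s in subclones],
            "true_pseudotime": pts,
            "true_malignant": malignant,
            "sample_id": assign,
            "condition": cond[rows],
            "survival_time": surv_time[rows],
            "event_flag": event[rows],
        }
    )
    meta = CellMeta(
        pd.DataFrame(
            {"cell_id": cell_ids, "sample_id": assign, "condition": cond[rows]}
        )
    )
    return Cohort(matrix, validate_gene_annotation(genes), meta, truth, samples, programs)


# ---------------------------------------------------------------- disk I/O


def write_10x_mtx(
    matrix: ExpressionMatrix,
    gene_annotation: pd.DataFrame | None,
    cell_meta: CellMeta | None,
    directory,
    gzipped: bool = False,
) -> Path:
    """Write a 10x-style MTX triplet (plus metadata tables) to ``directory``.

    Produces ``matrix.mtx``, ``genes.tsv`` (gene id plus position columns
    when an annotation is given) and ``barcodes.tsv``; ``cell_meta.tsv`` is
    written when metadata is supplied. Round-trips losslessly through
    :func:`clonetraj.io_qc.read_counts_mtx`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzipped else ""
    opener = gzip.open if gzipped else open

    coo = sp.coo_matrix(matrix.values)
    with opener(directory / f"matrix.mtx{suffix}", "wb") as fh:
        scipy.io.mmwrite(fh, coo, field="integer" if matrix.layer == "counts" else "real")

    if gene_annotation is not None:
        ann = validate_gene_annotation(gene_annotation).set_index("gene_id")
        ann = ann.loc[matrix.gene_ids].reset_index()
        gene_table = ann[["gene_id", "chromosome", "start", "end"]]
    else:
        gene_table = pd.DataFrame({"gene_id": matrix.gene_ids})
    with opener(directory / f"genes.tsv{suffix}", "wt") as fh:
        gene_table.to_csv(fh, sep="\t", header=False, index=False)
    with opener(directory / f"barcodes.tsv{suffix}", "wt") as fh:
        fh.write("".join(c + "\n" for c in matrix.cell_ids))
    if cell_meta is not None:
        cell_meta.table.to_csv(directory / "cell_meta.tsv", sep="\t", index=False)
    return directory
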