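"""Reading 10x-style inputs, QC filtering, normalization and clustering.

QC follows the strict reading of the thresholds: cells are removed when
they express *fewer than* ``min_genes`` distinct genes or when
mitochondrial reads make up *more than* ``max_mito_frac`` of their total;
genes are then kept when expressed in at least ``min_cells_per_gene`` of
the surviving cells. Cell filters run before the gene filter, and the order
matters: a second pass can drop further genes whose supporting cells were
removed.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io

from .containers import ExpressionMatrix, QCReport, validate_gene_annotation

MITO_PREFIX = "mt-"  # matched case-insensitively


def _find(directory: Path, names: list[str]) -> Path:
    for name in names:
        for suffix in ("", ".gz"):
            p = directory / (name + suffix)
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {names} (or .gz) found in {directory}")


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts_mtx(directory) -> ExpressionMatrix:
    """Read a 10x-style MTX triplet (plain or gzipped) as a counts matrix."""
    directory = Path(directory)
    mtx = _find(directory, ["matrix.mtx"])
    genes_path = _find(directory, ["genes.tsv", "features.tsv"])
    barcodes_path = _find(directory, ["barcodes.tsv"])

    opener = gzip.open if mtx.suffix == ".gz" else open
    with opener(mtx, "rb") as fh:
        values = scipy.io.mmread(fh)
    gene_ids = _read_lines(genes_path)
    cell_ids = _read_lines(barcodes_path)
    if values.shape != (len(gene_ids), len(cell_ids)):
        raise ValueError(
            f"matrix header {values.shape} does not match "
            f"{len(gene_ids)} genes / {len(cell_ids)} barcodes"
        )
    return ExpressionMatrix(values, gene_ids, cell_ids, layer="counts")


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a BED-like 4-column gene position table (TSV, no header or with)."""
    df = pd.read_csv(path, sep="\t")
    expected = ["gene_id", "chromosome", "start", "end"]
    if list(df.columns[:4]) != expected:
        df = pd.read_csv(path, sep="\t", header=None, names=expected)
    return validate_gene_annotation(df[expected])


def mito_mask(gene_ids) -> np.ndarray:
    return np.array([g.lower().startswith(MITO_PREFIX) for g in gene_ids])


def qc_filter(
    counts: ExpressionMatrix,
    min_genes: int = 1500,
    max_mito_frac: float = 0.12,
    min_cells_per_gene: int = 10,
) -> tuple[ExpressionMatrix, QCReport]:
    """Apply the cell- then gene-level QC filters to a counts matrix."""
    if counts.layer != "counts":
        raise ValueError("qc_filter expects the counts layer")
    v = counts.values
    mito = mito_mask(counts.gene_ids)
    totals = v.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, v[mito].sum(axis=0) / totals, 0.0)
    genes_per_cell = (v > 0).sum(axis=0)

    fail_mito = mito_frac > max_mito_frac
    fail_genes = genes_per_cell < min_genes
    keep_cells = ~(fail_mito | fail_genes)
    if not keep_cells.any():
        raise ValueError("empty after QC: no cell passes the filters")

    kept = v[:, keep_cells]
    keep_genes = (kept > 0).sum(axis=1) >= min_cells_per_gene
    report = QCReport(
        n_cells_in=counts.n_cells,
        n_cells_kept=int(keep_cells.sum()),
        n_removed_mito=int(fail_mito.sum()),
        n_removed_genes_per_cell=int(fail_genes.sum()),
        n_genes_in=counts.n_genes,
        n_genes_kept=int(keep_genes.sum()),
    )
    out = ExpressionMatrix(
        kept[keep_genes],
        [g for g, k in zip(counts.gene_ids, keep_genes) if k],
        [c for c, k in zip(counts.cell_ids, keep_cells) if k],
        layer="counts",
    )
    return out, report


def normalize_e(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Log-normalize counts: ``E = log2(1 + CPM/10)``.

    CPM (counts per million within each cell) stands in for TPM on UMI data,
    where there is no transcript-length bias to correct.
    """
    if counts.layer != "counts":
        raise ValueError("normalize_e expects the counts layer")
    totals = counts.values.sum(axis=0).astype(float)
    if np.any(totals == 0):
        bad = [c for c, t in zip(counts.cell_ids, totals) if t == 0]
        raise ValueError(f"cells with zero total counts: {bad[:5]}")
    cpm = counts.values / totals[None, :] * 1e6
    return ExpressionMatrix(
        np.log2(1 + cpm / 10), counts.gene_ids, counts.cell_ids, layer="E"
    )


def relative_er(e: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene across cells: ``Er = E - mean_cells(E)``."""
    if e.layer not in ("E", "Er"):
        raise ValueError("relative_er expects the E layer")
    centered = e.values - e.values.mean(axis=1, keepdims=True)
    return ExpressionMatrix(centered, e.gene_ids, e.cell_ids, layer="Er")


def preprocess_cluster(
    e: ExpressionMatrix,
    n_hvg: int = 5000,
    n_pcs: int = 50,
    rng_seed: int = 0,
    resolution: float = 1.0,
) -> pd.Series:
    """Cluster cells: HVG selection, PCA, neighbor graph, Leiden partition.

    Returns integer cluster labels indexed by cell id, deterministic under
    ``rng_seed``. ``n_hvg`` is clamped to the gene count and ``n_pcs`` to
    ``n_cells - 1`` (with a warning).
    """
    import scanpy as sc
    from anndata import AnnData

    if e.layer not in ("E", "Er"):
        raise ValueError("preprocess_cluster expects a log-expression layer")
    adata = AnnData(X=np.asarray(e.values, dtype=np.float32).T.copy())
    adata.obs_names = e.cell_ids
    adata.var_names = e.gene_ids

    n_hvg = min(n_hvg, e.n_genes)
    if e.n_cells <= n_pcs:
        warnings.warn(
            f"n_pcs reduced from {n_pcs} to {e.n_cells - 1} (too few cells)"
        )
        n_pcs = max(1, e.n_cells - 1)
    if n_hvg < e.n_genes:
        sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg, flavor="seurat")
        adata = adata[:, adata.var["highly_variable"]].copy()
    sc.pp.scale(adata, max_value=10)
    sc.tl.pca(adata, n_comps=min(n_pcs, adata.n_vars - 1), random_state=rng_seed)
    sc.pp.neighbors(adata, n_pcs=min(n_pcs, adata.obsm["X_pca"].shape[1]),
                    random_state=rng_seed)
    sc.tl.leiden(
        adata,
        resolution=resolution,
        random_state=rng_seed,
        flavor="leidenalg",
        n_iterations=-1,
    )
    labels = adata.obs["leiden"].astype(int)
    labels.index.name = "cell_id"
    labels.name = "cluster"
    return pd.Series(labels, index=pd.Index(e.cell_ids, name="cell_id"), name="cluster")
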