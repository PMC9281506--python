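"""Core in-memory containers shared by all pipeline stages.

The package works on gene-by-cell matrices carrying one of three layers:

``counts``
    raw UMI counts (non-negative integers),
``E``
    log-normalized expression, ``E = log2(1 + CPM/10)``,
``Er``
    relative expression: ``E`` centered per gene (mean 0 across cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

LAYERS = ("counts", "E", "Er")


@dataclass
class ExpressionMatrix:
    """Gene x cell expression matrix with an explicit layer tag.

    Parameters
    ----------
    values
        Dense or sparse ``(n_genes, n_cells)`` array. Sparse input is
        densified; the scales this package targets fit comfortably in memory.
    gene_ids, cell_ids
        Unique, ordered identifiers for rows and columns.
    layer
        One of ``counts`` / ``E`` / ``Er``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str = "counts"

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = np.asarray(self.values.todense())
        self.values = np.asarray(self.values)
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids")
        if self.layer == "counts":
            if self.values.size and (
                np.any(self.values < 0) or np.any(self.values != np.round(self.values))
            ):
                raise ValueError("counts layer must hold non-negative integers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes) -> np.ndarray:
        """Row indices of ``genes`` (raises KeyError for absent genes)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def cell_index(self, cells) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        return np.array([lookup[c] for c in cells], dtype=int)

    def subset(self, genes=None, cells=None) -> "ExpressionMatrix":
        gi = np.arange(self.n_genes) if genes is None else self.gene_index(genes)
        ci = np.arange(self.n_cells) if cells is None else self.cell_index(cells)
        return ExpressionMatrix(
            self.values[np.ix_(gi, ci)],
            [self.gene_ids[i] for i in gi],
            [self.cell_ids[i] for i in ci],
            self.layer,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class QCReport:
    """Bookkeeping from :func:`clonetraj.io_qc.qc_filter`."""

    n_cells_in: int
    n_cells_kept: int
    n_removed_mito: int
    n_removed_genes_per_cell: int
    n_genes_in: int
    n_genes_kept: int

    def __post_init__(self) -> None:
        if self.n_cells_kept > self.n_cells_in or self.n_genes_kept > self.n_genes_in:
            raise ValueError("kept counts exceed input counts")


def validate_gene_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check and normalize a BED-like gene table.

    Requires columns ``gene_id, chromosome, start, end`` with 0-based
    half-open coordinates; returns a copy sorted by chromosome then start.
    """
    required = {"gene_id", "chromosome", "start", "end"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    ann = annotation.copy()
    ann["gene_id"] = ann["gene_id"].astype(str)
    if ann["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in gene annotation")
    if (ann["end"] <= ann["start"]).any():
        raise ValueError("gene annotation has end <= start")
    return ann.sort_values(["chromosome", "start"], kind="mergesort").reset_index(drop=True)


@dataclass
class CellMeta:
    """Per-cell metadata, filled in progressively by the pipeline stages."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("cell_id", "sample_id", "condition")
    CONDITIONS = ("primary", "recurrent")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"cell meta missing column {col!r}")
        bad = set(self.table["condition"]) - set(self.CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        if self.table["cell_id"].duplicated().any():
            raise ValueError("duplicate cell_id in cell meta")
        for col in ("cluster", "cell_type", "subclone", "malignant"):
            if col not in self.table.columns:
                self.table[col] = pd.NA
        self.table = self.table.reset_index(drop=True)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table["cell_id"])

    def aligned(self, cell_ids) -> pd.DataFrame:
        """Rows reordered to ``cell_ids`` (all must be present)."""
        t = self.table.set_index("cell_id")
        return t.loc[list(cell_ids)].reset_index()
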