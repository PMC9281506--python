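"""Expression-inferred copy-number profiles, subclones and malignancy.

The inference mirrors the standard expression-CNV recipe: genes are ordered
along the genome, expression is centered on a non-malignant reference
population, outliers are clipped, and a wide moving average along each
chromosome turns gene-level noise into segment-level dosage signal. The
residual log-ratios are mapped onto a 0-2 copy-proxy scale (1 = normal
copy) anchored on the reference distribution, so that reference cells sit
at ~1 by construction.

Downstream: a per-cell CNV burden (``cnv_level``, the quadratic sum of
re-standardized proxies over that cell's expressed genes), Ward-linkage
hierarchical clustering of CNV profiles into subclones, a malignancy call
from the burden bimodality, and per-gene differential CNV between
subclones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, validate_gene_annotation


@dataclass
class CNVMatrix:
    """Gene x cell copy proxies on the 0-2 scale (1 = normal copy)."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    reference_cell_ids: list[str]
    window_size: int
    gene_annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("CNVMatrix shape mismatch")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 2):
            raise ValueError("copy proxies must lie in [0, 2]")

    def cell_index(self, cells) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        return np.array([lookup[c] for c in cells], dtype=int)


@dataclass
class SubcloneResult:
    labels: pd.Series                  # per-cell subclone label
    linkage: np.ndarray                # scipy linkage matrix (merge heights)
    k: int
    silhouette: float
    low_confidence: bool = False
    silhouette_by_k: dict[int, float] = field(default_factory=dict)


def sample_reference(
    cell_meta,
    cell_type: str,
    n: int = 300,
    rng_seed: int = 0,
    type_column: str = "cell_type",
) -> list[str]:
    """Sample ``n`` cells of ``cell_type`` (without replacement) as the
    common CNV reference; takes all available (with a warning) if fewer."""
    table = cell_meta.table if hasattr(cell_meta, "table") else cell_meta
    pool = table.loc[table[type_column] == cell_type, "cell_id"].to_numpy()
    if len(pool) == 0:
        raise ValueError(f"no cells of type {cell_type!r}")
    if len(pool) < n:
        warnings.warn(
            f"only {len(pool)} cells of type {cell_type!r} available "
            f"(requested {n}); taking all"
        )
        return list(pool)
    rng = np.random.default_rng(rng_seed)
    return list(rng.choice(pool, size=n, replace=False))


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0, truncated at the ends.

    Position ``i`` averages rows ``max(0, i-h) .. min(n, i+h+1)`` with
    ``h = window // 2``; the window simply shrinks near the boundaries.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    n = x.shape[0]
    h = window // 2
    # direct windowed means (not a cumulative-sum trick) so the smoother is
    # bit-identical to its definition; fast enough at genome scale
    out = np.empty_like(x, dtype=float)
    for i in range(n):
        out[i] = x[max(0, i - h):min(n, i + h + 1)].mean(axis=0)
    return out


def infer_cnv(
    e: ExpressionMatrix,
    gene_annotation: pd.DataFrame,
    reference_ids,
    window: int = 101,
    expr_cutoff: float = 0.1,
    min_cells_per_gene: int = 5,
    clip: float = 3.0,
    denoise_sd: float = 1.5,
    counts: ExpressionMatrix | None = None,
    min_counts_per_cell: float = 5e2,
    max_counts_per_cell: float = 6e6,
) -> CNVMatrix:
    """Infer gene x cell copy proxies from log expression.

    Steps: gene filtering (mean expression and detection-rate cutoffs),
    genomic ordering, reference centering, clipping, per-chromosome moving
    average, per-cell median centering, residual reference centering, a
    reference-spread denoising step (residuals within ``denoise_sd``
    reference standard deviations are set to baseline), and an exponential
    mapping onto the 0-2 copy scale anchored so reference cells sit at 1.

    When raw ``counts`` are supplied, cells whose totals fall outside
    ``[min_counts_per_cell, max_counts_per_cell]`` are dropped first
    (reference cells among them included).
    """
    if e.layer not in ("E", "Er"):
        raise ValueError("infer_cnv expects a log-expression layer")
    if window % 2 != 1:
        raise ValueError("window must be odd")
    reference_ids = list(reference_ids)
    missing_ref = set(reference_ids) - set(e.cell_ids)
    if missing_ref:
        raise ValueError(f"reference cells absent from matrix: {sorted(missing_ref)[:5]}")

    if counts is not None:
        totals = pd.Series(counts.values.sum(axis=0), index=counts.cell_ids)
        keep = [
            c for c in e.cell_ids
            if min_counts_per_cell <= totals.get(c, np.inf) <= max_counts_per_cell
        ]
        if len(keep) < e.n_cells:
            warnings.warn(
                f"{e.n_cells - len(keep)} cell(s) outside the per-cell count "
                "range dropped before CNV inference"
            )
            e = e.subset(cells=keep)
            reference_ids = [c for c in reference_ids if c in set(keep)]
            if not reference_ids:
                raise ValueError("all reference cells removed by the count filter")

    ann = validate_gene_annotation(gene_annotation)
    ann = ann[ann["gene_id"].isin(set(e.gene_ids))]
    if ann.empty:
        raise ValueError("gene annotation does not overlap the matrix")

    # gene filters use expression across all cells
    ann = ann.reset_index(drop=True)
    gene_pos = {g: i for i, g in enumerate(e.gene_ids)}
    rows = np.array([gene_pos[g] for g in ann["gene_id"]])
    mean_expr = e.values[rows].mean(axis=1)
    detected = (e.values[rows] > 0).sum(axis=1)
    mask = (mean_expr >= expr_cutoff) & (detected >= min_cells_per_gene)
    ann = ann[mask].reset_index(drop=True)
    if ann.empty:
        raise ValueError("no genes survive the CNV expression filters")
    rows = np.array([gene_pos[g] for g in ann["gene_id"]])

    x = e.values[rows].astype(float)                    # genes x cells, ordered
    ref_cols = e.cell_index(reference_ids)

    x = x - x[:, ref_cols].mean(axis=1, keepdims=True)  # reference centering
    x = np.clip(x, -clip, clip)

    smoothed = np.empty_like(x)
    for chrom, sub in ann.groupby("chromosome", sort=False):
        idx = sub.index.to_numpy()
        if len(idx) < 3:
            warnings.warn(
                f"chromosome {chrom!r} has {len(idx)} gene(s); passed through unsmoothed"
            )
            smoothed[idx] = x[idx]
        else:
            smoothed[idx] = moving_average(x[idx], window)

    smoothed = smoothed - np.median(smoothed, axis=0, keepdims=True)  # cell centering
    resid = smoothed - smoothed[:, ref_cols].mean(axis=1, keepdims=True)

    # denoise against the reference spread: residuals indistinguishable from
    # reference noise are pulled to the baseline, so reference-like cells
    # land at proxy ~1 while segment-scale dosage shifts pass through
    resid = resid - np.median(resid[:, ref_cols])
    if denoise_sd > 0:
        sigma_ref = resid[:, ref_cols].std()
        resid[np.abs(resid) <= denoise_sd * sigma_ref] = 0.0

    # exponential mapping onto the 0-2 copy scale: the smoothed residual is
    # a log2 dosage ratio already (expression scales with copy number), so
    # it maps through 2^r, clamped to [0, 2]; pure-noise input stays at 1.
    proxies = np.clip(2.0 ** resid, 0.0, 2.0)

    return CNVMatrix(
        values=proxies,
        gene_ids=list(ann["gene_id"]),
        cell_ids=list(e.cell_ids),
        reference_cell_ids=reference_ids,
        window_size=window,
        gene_annotation=ann,
    )


def cnv_level(cnv: CNVMatrix, counts: ExpressionMatrix | None = None) -> pd.Series:
    """Per-cell CNV burden: sum of squared re-standardized proxies.

    Proxies are shifted to the -1..1 scale (``s = c - 1``) and summed as
    ``sum(s^2)`` over the genes *expressed* in each cell (raw count > 0).
    Without a counts matrix all genes count as expressed.
    """
    s = cnv.values - 1.0
    if counts is None:
        level = (s ** 2).sum(axis=0)
    else:
        shared = [g for g in cnv.gene_ids if g in set(counts.gene_ids)]
        sub = counts.subset(genes=shared, cells=cnv.cell_ids)
        srows = {g: i for i, g in enumerate(cnv.gene_ids)}
        s_shared = s[[srows[g] for g in shared]]
        level = ((s_shared ** 2) * (sub.values > 0)).sum(axis=0)
    return pd.Series(level, index=pd.Index(cnv.cell_ids, name="cell_id"),
                     name="cnv_level")


def call_subclones(
    cnv: CNVMatrix,
    cells=None,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 6),
) -> SubcloneResult:
    """Ward-linkage hierarchical clustering of cell CNV profiles.

    ``k`` is chosen by maximal mean silhouette over ``k_range`` unless
    fixed. All-identical profiles yield a single cluster with a warning.
    """
    cells = list(cells) if cells is not None else list(cnv.cell_ids)
    cols = cnv.cell_index(cells)
    profiles = cnv.values[:, cols].T            # cells x genes
    if np.allclose(profiles, profiles[0]):
        warnings.warn("all CNV profiles identical; returning a single subclone")
        labels = pd.Series(1, index=pd.Index(cells, name="cell_id"), name="subclone")
        return SubcloneResult(labels, np.empty((0, 4)), 1, np.nan, True)

    linkage = sch.linkage(profiles, method="ward")
    sil_by_k: dict[int, float] = {}
    if k is None:
        best_k, best_sil = None, -np.inf
        for kk in range(k_range[0], k_range[1] + 1):
            if kk >= len(cells):
                break
            lab = sch.fcluster(linkage, kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            sil = silhouette_score(profiles, lab)
            sil_by_k[kk] = sil
            if sil > best_sil:
                best_k, best_sil = kk, sil
        if best_k is None:
            warnings.warn("no valid cut found; returning a single subclone")
            labels = pd.Series(1, index=pd.Index(cells, name="cell_id"),
                               name="subclone")
            return SubcloneResult(labels, linkage, 1, np.nan, True, sil_by_k)
        k, sil = best_k, best_sil
    else:
        lab = sch.fcluster(linkage, k, criterion="maxclust")
        sil = silhouette_score(profiles, lab) if len(np.unique(lab)) > 1 else np.nan

    lab = sch.fcluster(linkage, k, criterion="maxclust")
    low_conf = not np.isfinite(sil) or sil < 0.1
    if low_conf:
        warnings.warn(f"subclone separation is weak (silhouette {sil:.3f})")
    labels = pd.Series(lab, index=pd.Index(cells, name="cell_id"), name="subclone")
    return SubcloneResult(labels, linkage, int(k), float(sil), low_conf, sil_by_k)


def classify_malignancy(
    levels: pd.Series,
    cluster_labels: pd.Series,
    reference_ids=None,
) -> pd.Series:
    """Call cells malignant from the CNV-burden distribution.

    A 2-component Gaussian mixture on the (log1p) burden finds the split
    threshold (Otsu-style maximal between-class variance as fallback); a
    cell is malignant when its burden exceeds the threshold AND its CNV
    cluster's mean burden exceeds the global median. Per-cluster majority
    vote then smooths singleton flips. Reference cells are never called
    malignant. With a unimodal burden the threshold is flagged unreliable
    and clusters are labeled by their mean burden alone.
    """
    levels = levels.astype(float)
    cluster_labels = cluster_labels.reindex(levels.index)
    x = np.log1p(levels.to_numpy())

    unreliable = False
    thresh = None
    if np.ptp(x) < 1e-12:
        unreliable = True
    else:
        try:
            gm = GaussianMixture(n_components=2, random_state=0, n_init=3)
            gm.fit(x.reshape(-1, 1))
            gm1 = GaussianMixture(n_components=1, random_state=0)
            gm1.fit(x.reshape(-1, 1))
            means = gm.means_.ravel()
            if gm1.bic(x.reshape(-1, 1)) <= gm.bic(x.reshape(-1, 1)):
                unreliable = True  # one component explains the burden better
            else:
                grid = np.linspace(x.min(), x.max(), 512)
                comp = gm.predict(grid.reshape(-1, 1))
                hi = np.argmax(means)
                crossings = np.flatnonzero(np.diff((comp == hi).astype(int)) != 0)
                thresh = grid[crossings[0]] if len(crossings) else np.mean(means)
        except Exception:
            thresh = None
        if thresh is None and not unreliable:
            # Otsu on the 1-D burden
            order = np.sort(x)
            best, best_var = None, -np.inf
            for i in range(1, len(order)):
                w0, w1 = i / len(order), 1 - i / len(order)
                m0, m1 = order[:i].mean(), order[i:].mean()
                var = w0 * w1 * (m0 - m1) ** 2
                if var > best_var:
                    best, best_var = (order[i - 1] + order[i]) / 2, var
            thresh = best

    xs = pd.Series(x, index=levels.index)
    cluster_mean = xs.groupby(cluster_labels).mean()

    if unreliable:
        warnings.warn(
            "CNV burden looks unimodal; malignancy threshold unreliable, "
            "labeling by cluster mean burden only"
        )
        cluster_high = cluster_mean > float(np.median(x))
        call = cluster_labels.map(cluster_high).fillna(False).astype(bool)
    else:
        # the cluster-level gate uses the same bimodal split point: with a
        # mostly-malignant cohort the global median sits inside the
        # malignant range and would flip borderline malignant clusters
        cluster_high = cluster_mean > thresh
        above = xs > thresh
        call = above & cluster_labels.map(cluster_high).fillna(False).astype(bool)
        # majority vote within clusters smooths singleton flips
        maj = call.groupby(cluster_labels).transform("mean") > 0.5
        call = maj.fillna(call).astype(bool)

    if reference_ids is not None:
        call.loc[call.index.intersection(list(reference_ids))] = False
    call.name = "malignant"
    return call


def differential_cnv(
    cnv: CNVMatrix,
    group_a,
    group_b,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene differential copy proxy between two cell groups.

    Two-sided Mann-Whitney per gene with BH adjustment; effect size is
    ``mean(A) - mean(B)``. Genes constant in both groups get p = 1.
    """
    a_idx, b_idx = cnv.cell_index(list(group_a)), cnv.cell_index(list(group_b))
    if len(a_idx) < 3 or len(b_idx) < 3:
        raise ValueError("both groups need at least 3 cells")
    a, b = cnv.values[:, a_idx], cnv.values[:, b_idx]
    delta = a.mean(axis=1) - b.mean(axis=1)
    pvals = np.ones(cnv.values.shape[0])
    pooled = np.hstack([a, b])
    nonconst = np.ptp(pooled, axis=1) > 0
    if nonconst.any():
        pvals[nonconst] = scipy.stats.mannwhitneyu(
            a[nonconst], b[nonconst], axis=1, alternative="two-sided"
        ).pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene_id": cnv.gene_ids,
        "delta_mean_proxy": delta,
        "p_value": pvals,
        "q_value": qvals,
        "significant": (qvals < alpha),
    })
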