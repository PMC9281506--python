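"""Gene-signature scoring, marker detection and cell-type classification.

Module scores follow the binned-control-gene scheme: genes are binned by
their average expression across all cells, each signature gene draws
control genes from its own bin, and the score is the mean expression of the
signature minus the mean expression of the sampled controls. This removes
the depth/abundance component a naive signature mean would carry.

Cell types are assigned by signature enrichment (SE): per-cell scores for
every candidate signature are averaged within clusters and each cluster
takes the arg-max cell type. The reverse procedure (rSE) extracts markers
from the unlabeled clusters and scores them on a typed reference; the two
routes agreeing is the internal consistency check.

``undiff_score`` is a simplified gene-count-based differentiation score:
cells that express many distinct genes score as less differentiated. It is
a deliberately lightweight stand-in for full differentiation-potential
estimators and is labeled as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix


@dataclass
class SignatureSet:
    """A named cell-type gene list."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        self.genes = list(map(str, self.genes))
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")


@dataclass
class ModuleScoreParams:
    n_bins: int = 25
    n_ctrl_per_gene: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.n_ctrl_per_gene < 1:
            raise ValueError("n_bins and n_ctrl_per_gene must be >= 1")


def read_signatures(path) -> list[SignatureSet]:
    """Read signatures from a two-column TSV (set name, gene id)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "gene_id"],
                     comment="#", dtype=str)
    return [
        SignatureSet(name, list(sub["gene_id"]))
        for name, sub in df.groupby("name", sort=False)
    ]


def write_signatures(signatures: list[SignatureSet], path) -> None:
    rows = [(s.name, g) for s in signatures for g in s.genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ------------------------------------------------------------- marker genes


def find_markers(
    e: ExpressionMatrix,
    labels,
    min_pct: float = 0.1,
    min_logfc: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker detection per group.

    For each group, genes passing the detection-fraction and log-fold-change
    prefilters are tested with a two-sided Wilcoxon rank-sum test;
    Benjamini-Hochberg adjustment is applied within each group's tested set.
    The log fold change is the difference of group means on the log scale.
    Returns the full tested table with an ``is_marker`` column
    (``q < alpha`` and positive log fold change).
    """
    labels = pd.Series(np.asarray(labels), index=e.cell_ids)
    groups = [g for g in labels.unique()]
    if len(groups) < 2:
        raise ValueError("find_markers needs at least 2 groups")
    v = e.values
    out = []
    for group in groups:
        in_g = (labels == group).to_numpy()
        if in_g.sum() < 3:
            warnings.warn(f"group {group!r} has fewer than 3 cells; skipped")
            continue
        a, b = v[:, in_g], v[:, ~in_g]
        pct_in = (a > 0).mean(axis=1)
        pct_out = (b > 0).mean(axis=1)
        logfc = a.mean(axis=1) - b.mean(axis=1)
        tested = ((np.maximum(pct_in, pct_out) >= min_pct)
                  & (np.abs(logfc) >= min_logfc))
        idx = np.flatnonzero(tested)
        if idx.size == 0:
            continue
        pvals = scipy.stats.mannwhitneyu(
            a[idx], b[idx], axis=1, alternative="two-sided"
        ).pvalue
        qvals = multipletests(pvals, method="fdr_bh")[1]
        out.append(pd.DataFrame({
            "gene_id": [e.gene_ids[i] for i in idx],
            "group": group,
            "log_fold_change": logfc[idx],
            "p_value": pvals,
            "q_value": qvals,
            "pct_in_group": pct_in[idx],
            "pct_out_group": pct_out[idx],
            "is_marker": (qvals < alpha) & (logfc[idx] > 0),
        }))
    if not out:
        return pd.DataFrame(columns=[
            "gene_id", "group", "log_fold_change", "p_value", "q_value",
            "pct_in_group", "pct_out_group", "is_marker",
        ])
    return pd.concat(out, ignore_index=True)


# ------------------------------------------------------------ module score


def _expression_bins(e: ExpressionMatrix, n_bins: int) -> np.ndarray:
    """Equal-frequency bins of genes by average expression (rank-based)."""
    avg = e.values.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    return (ranks * n_bins) // len(order)


def module_score(
    e: ExpressionMatrix,
    signature: SignatureSet,
    params: ModuleScoreParams | None = None,
) -> pd.Series:
    """Per-cell module score for one signature (binned control genes).

    score(cell) = mean_sig E(cell) - mean_ctrl E(cell), with controls drawn
    per signature gene from that gene's expression bin (with replacement
    when the bin is smaller than ``n_ctrl_per_gene``). Deterministic under
    ``params.rng_seed``.
    """
    params = params or ModuleScoreParams()
    present = [g for g in signature.genes if g in set(e.gene_ids)]
    dropped = len(signature.genes) - len(present)
    if dropped:
        warnings.warn(
            f"signature {signature.name!r}: {dropped} gene(s) absent from matrix"
        )
    if not present:
        raise ValueError(f"signature {signature.name!r} has no genes in the matrix")

    rng = np.random.default_rng(params.rng_seed)
    n_bins = min(params.n_bins, e.n_genes)
    bins = _expression_bins(e, n_bins)
    sig_idx = e.gene_index(present)

    ctrl_rows: list[np.ndarray] = []
    for gi in sig_idx:
        pool = np.flatnonzero(bins == bins[gi])
        replace = len(pool) < params.n_ctrl_per_gene
        ctrl_rows.append(rng.choice(pool, size=params.n_ctrl_per_gene, replace=replace))
    ctrl = np.concatenate(ctrl_rows)

    score = e.values[sig_idx].mean(axis=0) - e.values[ctrl].mean(axis=0)
    return pd.Series(score, index=pd.Index(e.cell_ids, name="cell_id"),
                     name=signature.name)


def score_signatures(
    e: ExpressionMatrix,
    signatures: list[SignatureSet],
    params: ModuleScoreParams | None = None,
) -> pd.DataFrame:
    """Per-cell score for each signature (columns).

    Every signature is scored with the same control-sampling seed so that
    scores are comparable across signatures and identical gene lists give
    identical scores.
    """
    params = params or ModuleScoreParams()
    return pd.DataFrame({sig.name: module_score(e, sig, params)
                         for sig in signatures})


# --------------------------------------------------------- SE / rSE typing


def se_classify(
    e: ExpressionMatrix,
    clusters,
    signatures: list[SignatureSet],
    params: ModuleScoreParams | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Signature-enrichment typing: clusters take the arg-max signature.

    Returns ``(cluster -> cell type, cluster x signature mean-score table)``.
    Ties are broken by signature input order (with a warning).
    """
    clusters = pd.Series(np.asarray(clusters), index=e.cell_ids)
    cell_scores = score_signatures(e, signatures, params)
    table = cell_scores.groupby(clusters.to_numpy()).mean()
    table.index.name = "cluster"

    assignment = {}
    for cluster, row in table.iterrows():
        best = row.max()
        winners = [c for c in table.columns if row[c] == best]
        if len(winners) > 1:
            warnings.warn(
                f"cluster {cluster!r}: tie between {winners}; taking first listed"
            )
        assignment[cluster] = winners[0]
    return assignment, table


def rse_classify(
    query_e: ExpressionMatrix,
    query_clusters,
    reference_e: ExpressionMatrix,
    reference_types,
    params: ModuleScoreParams | None = None,
    se_result: tuple[dict, pd.DataFrame] | None = None,
    max_markers: int = 100,
) -> dict:
    """Reverse signature enrichment: query-cluster markers scored on a typed
    reference.

    Markers of each query cluster (top ``max_markers`` by log fold change)
    become a signature scored on the reference cells; the cluster takes the
    reference type with the highest mean score. Clusters without markers are
    left unassigned (``None``) and flagged.

    When ``se_result`` (the output of :func:`se_classify` on the query) is
    given, the returned dict also carries the SE/rSE agreement: the
    proportion of clusters with identical calls and the Pearson correlation
    of the two cluster x type score tables over shared labels.
    """
    query_clusters = pd.Series(np.asarray(query_clusters), index=query_e.cell_ids)
    reference_types = pd.Series(np.asarray(reference_types), index=reference_e.cell_ids)
    markers = find_markers(query_e, query_clusters)

    assignment: dict = {}
    rows = {}
    for cluster in query_clusters.unique():
        sub = markers[(markers["group"] == cluster) & markers["is_marker"]]
        sub = sub.sort_values("log_fold_change", ascending=False).head(max_markers)
        genes = [g for g in sub["gene_id"] if g in set(reference_e.gene_ids)]
        if not genes:
            warnings.warn(f"cluster {cluster!r} has no usable markers; unassigned")
            assignment[cluster] = None
            continue
        sig = SignatureSet(f"cluster_{cluster}", genes)
        scores = module_score(reference_e, sig, params)
        by_type = scores.groupby(reference_types.to_numpy()).mean()
        assignment[cluster] = by_type.idxmax()
        rows[cluster] = by_type
    score_table = pd.DataFrame(rows).T
    score_table.index.name = "cluster"

    result = {"assignment": assignment, "score_table": score_table}
    if se_result is not None:
        se_assign, se_table = se_result
        shared = [c for c in se_assign if c in assignment and assignment[c] is not None]
        agree = [c for c in shared if se_assign[c] == assignment[c]]
        result["concordance"] = len(agree) / len(shared) if shared else np.nan
        common_types = [t for t in se_table.columns if t in score_table.columns]
        if shared and len(common_types) >= 2:
            a = se_table.loc[shared, common_types].to_numpy().ravel()
            b = score_table.loc[shared, common_types].to_numpy().ravel()
            result["score_correlation"] = float(np.corrcoef(a, b)[0, 1])
        else:
            result["score_correlation"] = np.nan
    return result


# ------------------------------------------- gene-count differentiation score


def undiff_score(
    e: ExpressionMatrix,
    n_top_genes: int = 200,
    knn_smooth: int = 0,
) -> pd.Series:
    """Gene-count-based undifferentiation score, rank-normalized to [0, 1].

    Per-cell distinct-gene counts are correlated gene-by-gene with
    expression; the mean expression of the ``n_top_genes`` most-correlated
    genes (optionally k-NN smoothed over cells in that score space) is
    rank-normalized so the most differentiated cell scores 0 and the most
    stem-like 1. Simplified gene-count heuristic, not a full
    differentiation-potential estimator.
    """
    if e.n_genes < n_top_genes:
        n_top_genes = e.n_genes
    g = (e.values > 0).sum(axis=0).astype(float)
    if np.ptp(g) == 0:
        warnings.warn("gene counts constant across cells; falling back to rank of g")
        score = g.copy()
    else:
        gc = g - g.mean()
        denom_g = np.sqrt((gc ** 2).sum())
        x = e.values - e.values.mean(axis=1, keepdims=True)
        sx = np.sqrt((x ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(sx > 0, (x @ gc) / (sx * denom_g), 0.0)
        top = np.argsort(corr)[::-1][:n_top_genes]
        score = e.values[top].mean(axis=0)
        if knn_smooth > 0:
            order = np.argsort(score)
            smoothed = score.copy()
            for pos, i in enumerate(order):
                lo = max(0, pos - knn_smooth)
                hi = min(len(order), pos + knn_smooth + 1)
                smoothed[i] = score[order[lo:hi]].mean()
            score = smoothed
    ranks = scipy.stats.rankdata(score, method="average") - 1
    if len(ranks) > 1:
        ranks = ranks / (len(ranks) - 1)
    return pd.Series(ranks, index=pd.Index(e.cell_ids, name="cell_id"),
                     name="undiff_score")
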