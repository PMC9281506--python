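"""Ligand-receptor crosstalk scoring between cell types.

The interaction score for a (source type, target type, ligand, receptor)
tuple is the product of the ligand's mean expression in the source type
and the receptor's mean expression in the target type — the classic
product-of-means statistic. Significance comes from a label-permutation
null: cell-type labels are shuffled, the scores recomputed, and
``p = (1 + #{null >= observed}) / (n_perm + 1)`` so p is never exactly 0.

The recurrent-vs-primary contrast tests, per ligand/receptor gene and cell
type, whether expression is higher in recurrent samples (one-sided
Mann-Whitney, BH-adjusted).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix


def read_lr_pairs(path) -> pd.DataFrame:
    """Read a 3-column (ligand, receptor, pathway) TSV of L-R pairs."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["ligand", "receptor", "pathway"], comment="#",
                     dtype=str)
    return validate_lr_pairs(df)


def validate_lr_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    for col in ("ligand", "receptor"):
        if col not in pairs.columns:
            raise ValueError(f"L-R table missing column {col!r}")
    if "pathway" not in pairs.columns:
        pairs = pairs.assign(pathway="")
    if pairs.duplicated(subset=["ligand", "receptor"]).any():
        raise ValueError("duplicate (ligand, receptor) rows")
    return pairs.reset_index(drop=True)


def _type_means(values: np.ndarray, type_codes: np.ndarray, n_types: int) -> np.ndarray:
    """Mean expression per (gene, type); genes x types."""
    sums = np.zeros((values.shape[0], n_types))
    counts = np.bincount(type_codes, minlength=n_types).astype(float)
    for t in range(n_types):
        cols = type_codes == t
        if cols.any():
            sums[:, t] = values[:, cols].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / counts, 0.0)


def lr_score(
    e: ExpressionMatrix,
    cell_types,
    pairs: pd.DataFrame,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Score every (source, target, ligand, receptor) tuple with a
    permutation p-value and BH q-value.

    Pairs whose ligand or receptor is absent from the matrix are retained
    with score 0 and p = 1, flagged in the ``missing_gene`` column.
    """
    pairs = validate_lr_pairs(pairs)
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    types = pd.Series(np.asarray(cell_types), index=e.cell_ids).astype(str)
    type_names = sorted(types.unique())
    if len(type_names) < 2:
        raise ValueError("need at least 2 cell types")
    code_of = {t: i for i, t in enumerate(type_names)}
    codes = types.map(code_of).to_numpy()

    gene_set = set(e.gene_ids)
    used_genes = sorted(
        {g for g in pd.concat([pairs["ligand"], pairs["receptor"]]) if g in gene_set}
    )
    gene_row = {g: i for i, g in enumerate(used_genes)}
    sub = e.values[e.gene_index(used_genes)] if used_genes else np.empty((0, e.n_cells))

    n_types = len(type_names)
    obs_means = _type_means(sub, codes, n_types)

    rng = np.random.default_rng(rng_seed)
    rows = []
    valid = []  # (row_index, ligand_row, receptor_row, source_code, target_code)
    for _, pr in pairs.iterrows():
        lig, rec, path = pr["ligand"], pr["receptor"], pr["pathway"]
        missing = lig not in gene_row or rec not in gene_row
        for s in range(n_types):
            for t in range(n_types):
                if missing:
                    rows.append([type_names[s], type_names[t], lig, rec, path,
                                 0.0, 1.0, True])
                else:
                    score = obs_means[gene_row[lig], s] * obs_means[gene_row[rec], t]
                    valid.append((len(rows), gene_row[lig], gene_row[rec], s, t))
                    rows.append([type_names[s], type_names[t], lig, rec, path,
                                 float(score), np.nan, False])
    out = pd.DataFrame(rows, columns=[
        "source", "target", "ligand", "receptor", "pathway",
        "score", "p_value", "missing_gene",
    ])
    if out["missing_gene"].any():
        warnings.warn(
            f"{out['missing_gene'].sum() // (n_types ** 2)} pair(s) with genes "
            "absent from the matrix scored 0"
        )

    if valid:
        v = np.array([(lr, rr, s, t) for _, lr, rr, s, t in valid])
        obs = out.loc[[i for i, *_ in valid], "score"].to_numpy()
        exceed = np.zeros(len(valid), dtype=int)
        for _ in range(n_perm):
            perm_codes = rng.permutation(codes)
            means = _type_means(sub, perm_codes, n_types)
            null = means[v[:, 0], v[:, 2]] * means[v[:, 1], v[:, 3]]
            exceed += null >= obs - 1e-12
        pvals = (1 + exceed) / (n_perm + 1)
        out.loc[[i for i, *_ in valid], "p_value"] = pvals
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def lr_condition_differential(
    e: ExpressionMatrix,
    cell_types,
    conditions,
    pairs: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per ligand/receptor gene and cell type: is expression higher in
    recurrent than primary cells? One-sided Mann-Whitney with BH adjustment.

    Cell types present in only one condition are skipped with a warning;
    genes absent from the matrix are skipped and logged.
    """
    pairs = validate_lr_pairs(pairs)
    types = pd.Series(np.asarray(cell_types), index=e.cell_ids).astype(str)
    conds = pd.Series(np.asarray(conditions), index=e.cell_ids).astype(str)
    if not {"primary", "recurrent"} <= set(conds.unique()):
        raise ValueError("both conditions must be present")

    gene_set = set(e.gene_ids)
    roles = [(g, "ligand") for g in pd.unique(pairs["ligand"])] + [
        (g, "receptor") for g in pd.unique(pairs["receptor"])
    ]
    skipped = [g for g, _ in roles if g not in gene_set]
    if skipped:
        warnings.warn(f"genes absent from matrix skipped: {sorted(set(skipped))}")

    rows = []
    for cell_type in sorted(types.unique()):
        in_type = types == cell_type
        rec_mask = (in_type & (conds == "recurrent")).to_numpy()
        pri_mask = (in_type & (conds == "primary")).to_numpy()
        if rec_mask.sum() == 0 or pri_mask.sum() == 0:
            warnings.warn(
                f"cell type {cell_type!r} absent in one condition; skipped"
            )
            continue
        for gene, role in roles:
            if gene not in gene_set:
                continue
            gi = e.gene_index([gene])[0]
            rec, pri = e.values[gi, rec_mask], e.values[gi, pri_mask]
            if np.ptp(np.concatenate([rec, pri])) == 0:
                stat, p = 0.0, 1.0
            else:
                res = scipy.stats.mannwhitneyu(rec, pri, alternative="greater")
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append([gene, role, cell_type, float(rec.mean() - pri.mean()),
                         stat, p])
    out = pd.DataFrame(rows, columns=[
        "gene_id", "role", "cell_type", "delta_mean", "statistic", "p_value",
    ])
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["q_value"] < alpha
    else:
        out["q_value"] = []
        out["significant"] = []
    return out


def bundled_lr_pairs() -> pd.DataFrame:
    """A small synthetic L-R table for tests and the demo (includes the
    MDK->NCL midkine axis); real analyses should supply a curated database."""
    rows = [
        ("MDK", "NCL", "MK"),
        ("MDK", "LRP1", "MK"),
        ("PTN", "PTPRZ1", "PTN"),
        ("EGF", "EGFR", "EGFR"),
        ("TGFA", "EGFR", "EGFR"),
        ("CX3CL1", "CX3CR1", "CX3C"),
        ("CSF1", "CSF1R", "CSF"),
        ("VEGFA", "FLT1", "VEGF"),
        ("DLL3", "NOTCH1", "NOTCH"),
        ("JAG1", "NOTCH2", "NOTCH"),
    ]
    return pd.DataFrame(rows, columns=["ligand", "receptor", "pathway"])
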