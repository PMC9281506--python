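"""Per-cell trajectory score, sample summaries and survival comparison.

The trajectory score is the module score of an undifferentiated marker set
(NSC-like cells of the stem-dominant subclone) minus the module score of a
differentiated marker set (EpC-like cells of the differentiated subclone),
computed on the same expression layer with the same control-gene seed so
the two components are directly comparable. Higher scores mean more
stem-like cells; sample means stratify cohorts into high/low trajectory
groups whose survival is compared with Kaplan-Meier curves and the
two-group log-rank test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .containers import ExpressionMatrix
from .signatures import ModuleScoreParams, SignatureSet, module_score


def trajectory_score(
    e: ExpressionMatrix,
    undiff_markers: SignatureSet,
    diff_markers: SignatureSet,
    params: ModuleScoreParams | None = None,
) -> pd.DataFrame:
    """Per-cell undifferentiated score, differentiated score and their
    difference (the trajectory score)."""
    params = params or ModuleScoreParams()
    undiff = module_score(e, undiff_markers, params)
    diff = module_score(e, diff_markers, params)
    return pd.DataFrame(
        {
            "undiff_traj_score": undiff,
            "diff_traj_score": diff,
            "trajectory_score": undiff - diff,
        }
    )


def summarize_by_sample(
    trajectory_table: pd.DataFrame, cell_meta
) -> pd.DataFrame:
    """Per-sample mean trajectory score and the high/low split.

    The split threshold is the unweighted mean of the sample means; samples
    strictly above it are ``high``, ties fall to ``low``. A single sample
    yields means without a split.
    """
    meta = cell_meta.table if hasattr(cell_meta, "table") else cell_meta
    merged = meta.merge(
        trajectory_table["trajectory_score"], left_on="cell_id", right_index=True
    )
    per_sample = (
        merged.groupby("sample_id")
        .agg(
            mean_trajectory_score=("trajectory_score", "mean"),
            n_cells=("trajectory_score", "size"),
            condition=("condition", "first"),
        )
        .reset_index()
    )
    if len(per_sample) < 2:
        warnings.warn("single sample: no high/low split performed")
        per_sample["group"] = pd.NA
        return per_sample
    threshold = per_sample["mean_trajectory_score"].mean()
    per_sample["group"] = np.where(
        per_sample["mean_trajectory_score"] > threshold, "high", "low"
    )
    return per_sample


def compare_groups(scores, grouping, test: str = "mann_whitney",
                   mode: str = "auto") -> dict:
    """Rank-based comparison of score distributions across groups.

    ``mann_whitney`` (two groups, two-sided) or ``kruskal_wallis`` (two or
    more groups), both tie-corrected. ``mode="exact"`` computes the exact
    permutation p-value (Mann-Whitney via the exact U distribution;
    Kruskal-Wallis by enumerating every assignment of observations to
    groups — only feasible for small samples). ``mode="auto"`` leaves the
    reference distribution to scipy (exact U for small tie-free samples,
    chi-square for Kruskal-Wallis).
    """
    scores = np.asarray(scores, dtype=float)
    grouping = np.asarray(grouping)
    groups = pd.unique(grouping)
    samples = [scores[grouping == g] for g in groups]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    if test == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("mann_whitney needs exactly 2 groups")
        method = "exact" if mode == "exact" else "auto"
        res = scipy.stats.mannwhitneyu(samples[0], samples[1],
                                       alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "kruskal_wallis":
        if len(groups) < 2:
            raise ValueError("kruskal_wallis needs at least 2 groups")
        res = scipy.stats.kruskal(*samples)
        stat, p = float(res.statistic), float(res.pvalue)
        if mode == "exact":
            p = _kruskal_exact_p(scores, [len(s) for s in samples], stat)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "statistic": stat,
        "p_value": p,
        "method": test if mode != "exact" else f"{test}_exact",
        "n_per_group": {str(g): int(len(s)) for g, s in zip(groups, samples)},
    }


def _kruskal_exact_p(scores: np.ndarray, sizes: list[int], h_obs: float,
                     max_assignments: int = 500_000) -> float:
    """Exact permutation p for the Kruskal-Wallis H statistic: enumerate
    every split of the pooled sample into groups of the given sizes."""
    from itertools import combinations as _comb
    from math import comb as _ncomb

    n = len(scores)
    total = 1
    rest = n
    for s in sizes[:-1]:
        total *= _ncomb(rest, s)
        rest -= s
    if total > max_assignments:
        raise ValueError(f"{total} assignments; too many for exact mode")
    ranks = scipy.stats.rankdata(scores)
    tie_corr = _kruskal_tie_correction(ranks)

    def h_of(split_ranks: list[np.ndarray]) -> float:
        h = 12 / (n * (n + 1)) * sum(
            r.sum() ** 2 / len(r) for r in split_ranks
        ) - 3 * (n + 1)
        return h / tie_corr if tie_corr > 0 else 0.0

    count = 0
    n_total = 0

    def recurse(remaining: np.ndarray, depth: int, chosen: list[np.ndarray]) -> None:
        nonlocal count, n_total
        if depth == len(sizes) - 1:
            h = h_of(chosen + [remaining])
            n_total += 1
            count += h >= h_obs - 1e-9
            return
        for pick in _comb(range(len(remaining)), sizes[depth]):
            mask = np.zeros(len(remaining), dtype=bool)
            mask[list(pick)] = True
            recurse(remaining[~mask], depth + 1, chosen + [remaining[mask]])

    recurse(ranks, 0, [])
    return count / n_total


def _kruskal_tie_correction(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    n = len(ranks)
    return 1 - (counts ** 3 - counts).sum() / (n ** 3 - n)


def km_logrank(records: pd.DataFrame) -> dict:
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    ``records`` needs columns ``sample_id, time, event, group``. Returns
    per-group step curves (time, survival), medians, the log-rank
    chi-square and its chi-square(1) p-value. With no events at all the
    p-value is flagged undefined.
    """
    required = {"sample_id", "time", "event", "group"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"survival records missing columns {sorted(missing)}")
    if (records["time"] < 0).any():
        raise ValueError("negative survival times")
    groups = list(pd.unique(records["group"]))
    if len(groups) != 2:
        raise ValueError("km_logrank compares exactly 2 groups")

    curves, medians = {}, {}
    for g in groups:
        sub = records[records["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"].astype(bool))
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
        medians[g] = float(kmf.median_survival_time_)

    if int(records["event"].astype(bool).sum()) == 0:
        warnings.warn("no events observed; log-rank p undefined")
        return {"curves": curves, "medians": medians, "chi_square": 0.0,
                "p_value": None, "events": 0}

    a = records[records["group"] == groups[0]]
    b = records[records["group"] == groups[1]]
    res = logrank_test(
        a["time"], b["time"],
        event_observed_A=a["event"].astype(bool),
        event_observed_B=b["event"].astype(bool),
    )
    return {
        "curves": curves,
        "medians": medians,
        "chi_square": float(res.test_statistic),
        "p_value": float(res.p_value),
        "events": int(records["event"].astype(bool).sum()),
    }
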