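"""Permutation and correlation statistics shared across pipeline stages.

The two-sample Fisher-Pitman permutation test works on the linear statistic
T = sum of responses in the first group. Under permutation of group labels
the exact moments of T follow finite-population (sampling without
replacement) formulas; the exact mode enumerates all ``C(n, n1)``
assignments and the Monte-Carlo mode samples them. The asymptotic mode
approximates the permutation distribution to higher order than the plain
normal reference: an Edgeworth expansion on the exact cumulants near the
center and a double-saddlepoint (Lugannani-Rice) tail approximation beyond
— the plain normal reference remains available as ``mode="normal"``.
Two-sided p-values double the smaller tail (capped at 1).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from statsmodels.stats.multitest import multipletests

MAX_EXACT = 200_000      # enumeration guard
_EDGEWORTH_CUT = 1.5     # |z| below which the Edgeworth expansion is used


def _perm_central_moments(x: np.ndarray, m: int) -> tuple[float, float, float]:
    """Exact central moments (2nd..4th) of the sum of a uniform m-subset
    of ``x`` (sampling without replacement); verified against enumeration."""
    N = len(x)
    d = x - x.mean()
    s2, s3, s4 = (d ** 2).sum(), (d ** 3).sum(), (d ** 4).sum()
    f1 = m / N
    f2 = m * (m - 1) / (N * (N - 1))
    f3 = m * (m - 1) * (m - 2) / (N * (N - 1) * (N - 2))
    f4 = m * (m - 1) * (m - 2) * (m - 3) / (N * (N - 1) * (N - 2) * (N - 3))
    mu2 = (f1 - f2) * s2
    mu3 = (f1 - 3 * f2 + 2 * f3) * s3
    mu4 = (f1 * s4 + 3 * f2 * (s2 * s2 - s4) - 4 * f2 * s4
           + 6 * f3 * (2 * s4 - s2 * s2) + f4 * (3 * s2 * s2 - 6 * s4))
    return mu2, mu3, mu4


def _edgeworth_cdf(z: float, g1: float, g2: float) -> float:
    """Edgeworth CDF with skewness g1 and excess kurtosis g2."""
    he2 = z * z - 1
    he3 = z ** 3 - 3 * z
    he5 = z ** 5 - 10 * z ** 3 + 15 * z
    return scipy.stats.norm.cdf(z) - scipy.stats.norm.pdf(z) * (
        g1 / 6 * he2 + g2 / 24 * he3 + g1 * g1 / 72 * he5
    )


def _saddle_sf(x: np.ndarray, m: int, t: float) -> float | None:
    """Double-saddlepoint P(T >= t) for the m-subset-sum permutation null;
    None when the tilting equations do not converge."""
    N = len(x)

    def cgf(a: float, b: float) -> float:
        return float(np.logaddexp(0, a + b * x).sum())

    a0 = np.log(m / (N - m))
    ab = np.array([a0, 0.0])
    for _ in range(100):
        e = scipy.special.expit(ab[0] + ab[1] * x)
        resid = np.array([e.sum() - m, (e * x).sum() - t])
        if np.max(np.abs(resid)) < 1e-11:
            break
        w = e * (1 - e)
        jac = np.array([[w.sum(), (w * x).sum()],
                        [(w * x).sum(), (w * x * x).sum()]])
        try:
            step = np.linalg.solve(jac, resid)
        except np.linalg.LinAlgError:
            return None
        ab = ab - np.clip(step, -10, 10)
    else:
        return None
    a, b = ab
    e = scipy.special.expit(a + b * x)
    w_ = e * (1 - e)
    jac = np.array([[w_.sum(), (w_ * x).sum()],
                    [(w_ * x).sum(), (w_ * x * x).sum()]])
    num = max((a * m + b * t - cgf(a, b)) - (a0 * m - cgf(a0, 0.0)), 0.0)
    w = np.sign(b) * np.sqrt(2 * num)
    u = b * np.sqrt(max(np.linalg.det(jac), 0.0) / (N * (m / N) * (1 - m / N)))
    if abs(w) < 1e-6 or abs(u) < 1e-8:
        return None
    return float(np.clip(
        scipy.stats.norm.sf(w) - scipy.stats.norm.pdf(w) * (1 / w - 1 / u), 0, 1
    ))


def fisher_pitman(
    responses,
    labels,
    mode: str = "asymptotic",
    n_mc: int = 10_000,
    rng_seed: int = 0,
) -> dict:
    """Two-sample Fisher-Pitman permutation test.

    Parameters
    ----------
    responses
        Numeric observations.
    labels
        Two-group labels aligned with ``responses``.
    mode
        ``asymptotic`` (higher-order approximation of the permutation
        distribution: Edgeworth near the center, saddlepoint in the
        tails), ``normal`` (plain normal reference, the convention of the
        R ``coin`` asymptotic test), ``exact`` (full enumeration) or
        ``monte_carlo`` (``n_mc`` sampled assignments).

    Returns a dict with the standardized statistic, p-value, method and
    group sizes. Constant responses give p = 1.
    """
    x = np.asarray(responses, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(x)):
        raise ValueError("responses must be finite")
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    g1 = labels == groups[0]
    n1, n2 = int(g1.sum()), int((~g1).sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 observations")
    n = n1 + n2

    t_obs = x[g1].sum()
    xbar = x.mean()
    mu_t = n1 * xbar
    var_t = n1 * n2 / (n * (n - 1)) * ((x - xbar) ** 2).sum()
    if var_t < 1e-300:
        return {"statistic": 0.0, "p_value": 1.0, "method": f"fisher_pitman_{mode}",
                "n_per_group": (n1, n2)}
    z = (t_obs - mu_t) / np.sqrt(var_t)

    if mode == "asymptotic":
        mu2, mu3, mu4 = _perm_central_moments(x, n1)
        g1 = mu3 / mu2 ** 1.5
        g2 = mu4 / mu2 ** 2 - 3
        if abs(z) <= _EDGEWORTH_CUT:
            lo = _edgeworth_cdf(z, g1, g2)
            p = min(1.0, 2 * min(max(lo, 0.0), max(1 - lo, 0.0)))
        else:
            hi = _saddle_sf(x, n1, t_obs)
            lo = _saddle_sf(-x, n1, -t_obs)
            if hi is None or lo is None:
                cdf = _edgeworth_cdf(z, g1, g2)
                p = min(1.0, 2 * min(max(cdf, 0.0), max(1 - cdf, 0.0)))
            else:
                p = min(1.0, 2 * min(hi, lo))
    elif mode == "normal":
        p = 2 * scipy.stats.norm.sf(abs(z))
    elif mode == "exact":
        total = scipy.special.comb(n, n1, exact=True)
        if total > MAX_EXACT:
            raise ValueError(f"{total} assignments; too many for exact mode")
        idx = np.fromiter(
            (i for comb in combinations(range(n), n1) for i in comb),
            dtype=np.intp, count=total * n1,
        ).reshape(total, n1)
        t_all = x[idx].sum(axis=1)
        eps = 1e-9 * max(1.0, abs(t_obs))
        lo = int((t_all <= t_obs + eps).sum())
        hi = int((t_all >= t_obs - eps).sum())
        p = min(1.0, 2 * min(lo, hi) / total)
    elif mode == "monte_carlo":
        rng = np.random.default_rng(rng_seed)
        draws = np.empty(n_mc)
        for i in range(n_mc):
            draws[i] = x[rng.choice(n, size=n1, replace=False)].sum()
        eps = 1e-9 * max(1.0, abs(t_obs))
        lo = (1 + np.sum(draws <= t_obs + eps)) / (n_mc + 1)
        hi = (1 + np.sum(draws >= t_obs - eps)) / (n_mc + 1)
        p = min(1.0, 2 * min(lo, hi))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {"statistic": float(z), "p_value": float(p),
            "method": f"fisher_pitman_{mode}", "n_per_group": (n1, n2)}


def composition_contrast(
    cell_meta,
    unit: str = "subclone",
    type_column: str = "cell_type",
    mode: str = "asymptotic",
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Per-cell-type composition contrast between two groups.

    ``unit="subclone"`` contrasts the two subclones within the cell table
    (cells are the observational units, responses are 0/1 type
    indicators); ``unit="condition"`` contrasts primary vs recurrent
    samples (samples are the units, responses are per-sample type
    proportions). Fisher-Pitman is applied per cell type with BH
    adjustment across types.
    """
    table = cell_meta.table if hasattr(cell_meta, "table") else cell_meta
    table = table.dropna(subset=[type_column])
    if unit == "subclone":
        table = table.dropna(subset=["subclone"])
        group_col = "subclone"
        units = table
    elif unit == "condition":
        group_col = "condition"
        units = table
    else:
        raise ValueError("unit must be 'subclone' or 'condition'")
    groups = pd.unique(units[group_col].to_numpy())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 {group_col} groups, got {list(groups)}")
    for g in groups:
        if (units[group_col] == g).sum() == 0:
            raise ValueError(f"group {g!r} has no cells")

    rows = []
    types = sorted(pd.unique(table[type_column].astype(str)))
    if unit == "subclone":
        labels = table[group_col].to_numpy()
        for t in types:
            resp = (table[type_column].astype(str) == t).to_numpy().astype(float)
            res = fisher_pitman(resp, labels, mode=mode, rng_seed=rng_seed)
            rows.append((t, res["statistic"], res["p_value"]))
    else:
        prop = (
            table.groupby(["sample_id", group_col])[type_column]
            .value_counts(normalize=True)
            .rename("proportion")
            .reset_index()
        )
        samples = table[["sample_id", group_col]].drop_duplicates()
        for t in types:
            sub = prop[prop[type_column].astype(str) == t]
            merged = samples.merge(
                sub[["sample_id", "proportion"]], on="sample_id", how="left"
            ).fillna({"proportion": 0.0})
            res = fisher_pitman(
                merged["proportion"].to_numpy(),
                merged[group_col].to_numpy(),
                mode=mode,
                rng_seed=rng_seed,
            )
            rows.append((t, res["statistic"], res["p_value"]))
    out = pd.DataFrame(rows, columns=["cell_type", "statistic", "p_value"])
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def correlate(scores: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix with t-based p-values.

    ``scores`` holds one variable per column (equal lengths >= 3).
    Zero-variance columns yield NaN correlations (flagged via a warning by
    pandas semantics: NaN entries).
    """
    if len(scores) < 3:
        raise ValueError("need at least 3 observations")
    cols = list(scores.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            xa, xb = scores[a].to_numpy(float), scores[b].to_numpy(float)
            if np.std(xa) == 0 or np.std(xb) == 0:
                rij, pij = np.nan, np.nan
            else:
                res = scipy.stats.pearsonr(xa, xb)
                rij, pij = res.statistic, res.pvalue
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p
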