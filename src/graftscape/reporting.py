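"""Statistical reporting: severity correlations and group comparisons.

Ties cell-type frequencies (as % of total cells per biopsy) to a scalar
inflammation-severity covariate and to diagnostic group labels:

* rank (Spearman) or linear (Pearson) correlation with a 95% CI from the
  Fisher z-transform — for Spearman the Bonett-Wright standard error
  sqrt((1 + r^2/2) / (n - 3)) is used;
* two-sided p-values: exhaustive permutation for small n, asymptotic
  otherwise;
* Kruskal-Wallis omnibus across diagnostic groups with Dunn's pairwise
  post-hoc z tests, Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["CorrelationResult", "severity_correlation", "group_compare", "dunn_test"]

# exhaustive permutation p-value is used up to this n (n! enumerations);
# beyond it a seeded Monte-Carlo permutation p is used up to MC_MAX_N,
# then the asymptotic approximation
EXACT_MAX_N = 9
MC_MAX_N = 12
MC_RESAMPLES = 10000


@dataclass
class CorrelationResult:
    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    method: str
    evaluable: bool = True


def _fisher_ci(r: float, n: int, method: str, level: float = 0.95) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    if method == "spearman":
        se = math.sqrt((1 + r**2 / 2) / (n - 3))
    else:
        se = math.sqrt(1.0 / (n - 3))
    zc = stats.norm.ppf(0.5 + level / 2)
    return (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


def _corr_stat(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.pearsonr(x, y).statistic)


def _permutation_p(x: np.ndarray, y: np.ndarray, method: str, seed: int | None) -> float:
    """Two-sided permutation p for the correlation; exhaustive for small n."""
    n = len(x)
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    obs = abs(_plain_r(x, y))
    if n <= EXACT_MAX_N:
        perms = itertools.permutations(range(n))
        count = 0
        total = 0
        for p in perms:
            total += 1
            if abs(_plain_r(x, y[list(p)])) >= obs - 1e-12:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(MC_RESAMPLES):
        if abs(_plain_r(x, y[rng.permutation(n)])) >= obs - 1e-12:
            count += 1
    return (1 + count) / (MC_RESAMPLES + 1)


def _plain_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom) if denom > 0 else 0.0


def severity_correlation(
    freq: pd.DataFrame,
    cell_type: str,
    method: str = "spearman",
    severity_col: str = "severity",
    seed: int | None = 0,
) -> CorrelationResult:
    """Correlate one cell type's frequency with inflammation severity.

    ``freq`` holds one row per biopsy with a ``severity`` column and one
    frequency column per cell type.  Returns the coefficient, its Fisher-z
    95% CI, and a two-sided p-value (permutation for n <= 12, asymptotic
    otherwise).  Zero-variance inputs are flagged non-evaluable.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    sub = freq[[severity_col, cell_type]].dropna()
    x = sub[severity_col].to_numpy(dtype=float)
    y = sub[cell_type].to_numpy(dtype=float)
    n = len(sub)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, n, method, evaluable=False)
    r = _corr_stat(x, y, method)
    lo, hi = _fisher_ci(r, n, method)
    if n <= MC_MAX_N:
        p = _permutation_p(x, y, method, seed)
    else:
        p = float(
            stats.spearmanr(x, y).pvalue if method == "spearman" else stats.pearsonr(x, y).pvalue
        )
    return CorrelationResult(r, lo, hi, p, n, method)


# ------------------------------------------------------------- group compare
def dunn_test(values: np.ndarray, groups: np.ndarray, adjust: str = "fdr_bh") -> pd.DataFrame:
    """Dunn's post-hoc pairwise z tests on pooled ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    with tie correction T = sum(t^3 - t) / (12 (N - 1)).  Two-sided normal
    p-values, multiplicity-adjusted (Benjamini-Hochberg by default).
    Pairs involving a single-observation group are flagged.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ranks = stats.rankdata(values)
    N = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1)) if N > 1 else 0.0
    labels = pd.unique(groups)
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        se = math.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_rank[g1] - mean_rank[g2]) / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                "z": z,
                "p_value": p,
                "small_n": sizes[g1] < 2 or sizes[g2] < 2,
            }
        )
    df = pd.DataFrame(rows)
    ok = df["p_value"].notna()
    adj = np.full(len(df), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(df.loc[ok, "p_value"], method=adjust)[1]
    df["p_adjusted"] = adj
    return df


def group_compare(
    freq: pd.DataFrame,
    cell_type: str,
    group_col: str = "group",
    adjust: str = "fdr_bh",
) -> tuple[dict, pd.DataFrame]:
    """Kruskal-Wallis omnibus plus Dunn pairwise comparisons for one cell type.

    All groups (including n = 1 groups) enter the omnibus test; pairs with a
    single-observation group are flagged in the pairwise table.  Returns
    ``({"H": ..., "p_value": ..., "df": ...}, pairwise DataFrame)``.
    """
    sub = freq[[group_col, cell_type]].dropna()
    samples = [g[cell_type].to_numpy(dtype=float) for _, g in sub.groupby(group_col)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    H, p = stats.kruskal(*samples)
    omnibus = {"H": float(H), "p_value": float(p), "df": len(samples) - 1}
    pairwise = dunn_test(sub[cell_type].to_numpy(dtype=float), sub[group_col].to_numpy(), adjust=adjust)
    return omnibus, pairwise
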