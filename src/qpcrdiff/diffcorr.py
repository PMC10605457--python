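"""Differential gene–gene correlation between experimental groups.

Per group, a symmetric gene–gene correlation matrix (Spearman or
Pearson, one method per run) is computed on pairwise-complete
observations. Coefficients whose p-value exceeds the significance
threshold alpha are zeroed — a non-significant coefficient carries no
evidence of correlation — giving the gated matrix. The differential
correlation statistic for a gene pair between two groups is

    dR-val = | r_gated(group A) − r_gated(group B) |

which ranges from 0 (no change in correlation profile) to 2 (a flip
from perfect positive to perfect negative correlation or vice versa).
Only group pairs containing the user's reference group are reported by
default; the full set of n(n−1)/2 group pairs is available on request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats

from .compare import NORMALITY_ALPHA, ks_normality
from .tables import NormalizedTable

__all__ = [
    "GroupCorrelation",
    "dr_val",
    "choose_corr_method",
    "correlation_matrix",
    "drval_table",
    "pair_scatter_stats",
    "spearman_with_p",
    "pearson_with_p",
]

PEARSON = "pearson"
SPEARMAN = "spearman"
_EXACT_SPEARMAN_MAX_N = 9


def dr_val(r_group1: float, r_group2: float) -> float:
    """Absolute difference of two (gated) correlation coefficients.

    The dR-val ranges from 0 to 2; missing input yields NaN.
    """
    return abs(r_group1 - r_group2)


@lru_cache(maxsize=None)
def _spearman_null(n: int) -> np.ndarray:
    """Null distribution of Spearman rho over all rank permutations."""
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n**2 - 1)
    rhos = np.array(
        [1.0 - 6.0 * np.sum((base - np.array(perm)) ** 2) / denom
         for perm in permutations(range(1, n + 1))]
    )
    return rhos


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with two-sided p.

    Exact permutation p for n ≤ 9 without ties (null distribution of
    rho cached per n); the t-distribution approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rho = float(stats.spearmanr(x, y).statistic)
    if math.isnan(rho):
        return rho, float("nan")
    no_ties = np.unique(x).size == n and np.unique(y).size == n
    if n <= _EXACT_SPEARMAN_MAX_N and no_ties:
        null = _spearman_null(n)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        return rho, min(p, 1.0)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided t-distribution p."""
    res = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupCorrelation:
    """Correlation matrices for one group (raw, p, gated)."""

    group: str
    method: str
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    alpha: float
    r_gated: pd.DataFrame


def choose_corr_method(
    norm: NormalizedTable,
    groups: list[str] | None = None,
    override: str | None = None,
    variable: str | None = None,
) -> str:
    """Pearson iff every gene looks normal in every selected group.

    One method is used for the whole run so dR-val compares like with
    like; an override is honored as given.
    """
    if override is not None:
        if override not in (PEARSON, SPEARMAN):
            raise ValueError(f"unknown correlation method: {override!r}")
        return override
    labels = norm.labels(variable)
    if groups is None:
        groups = sorted(labels.dropna().unique())
    for grp in groups:
        sub = norm.neg_delta_ct.loc[labels == grp]
        for gene in norm.genes:
            vals = sub[gene].dropna().to_numpy()
            if vals.size < 3:
                continue
            if ks_normality(vals) < NORMALITY_ALPHA:
                return SPEARMAN
    return PEARSON


def correlation_matrix(
    norm: NormalizedTable,
    group: str,
    method: str = SPEARMAN,
    alpha: float = 0.05,
    variable: str | None = None,
) -> GroupCorrelation:
    """Gene–gene correlations within one group, with p-gated zeroing.

    Pairwise-complete observations; pairs with fewer than 3 complete
    observations get missing r (gated to 0 for dR-val purposes is left
    to the caller: here they stay missing and are flagged by ``n``).
    """
    labels = norm.labels(variable)
    if group not in set(labels):
        raise KeyError(f"unknown group: {group!r}")
    if method not in (PEARSON, SPEARMAN):
        raise ValueError(f"unknown correlation method: {method!r}")
    sub = norm.neg_delta_ct.loc[labels == group]
    if sub.shape[0] < 3:
        raise ValueError(f"group {group!r} has fewer than 3 samples")

    genes = norm.genes
    k = len(genes)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    arr = sub.to_numpy(dtype=float)
    valid = ~np.isnan(arr)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i in range(k):
        n[i, i] = int(valid[:, i].sum())
    corr_fn = spearman_with_p if method == SPEARMAN else pearson_with_p
    for i, j in combinations(range(k), 2):
        both = valid[:, i] & valid[:, j]
        m = int(both.sum())
        n[i, j] = n[j, i] = m
        if m < 3:
            continue
        xi, yj = arr[both, i], arr[both, j]
        if np.unique(xi).size < 2 or np.unique(yj).size < 2:
            continue  # constant vector: correlation undefined
        rij, pij = corr_fn(xi, yj)
        r[i, j] = r[j, i] = rij
        p[i, j] = p[j, i] = pij

    r_df = pd.DataFrame(r, index=genes, columns=genes)
    p_df = pd.DataFrame(p, index=genes, columns=genes)
    # p > alpha zeroes the coefficient; undefined coefficients stay missing
    gated = r_df.where(p_df <= alpha, other=0.0).where(r_df.notna(), other=np.nan)
    return GroupCorrelation(
        group=group,
        method=method,
        r=r_df,
        p=p_df,
        n=pd.DataFrame(n, index=genes, columns=genes),
        alpha=alpha,
        r_gated=gated,
    )


def drval_table(
    correlations: dict[str, GroupCorrelation],
    reference: str,
    all_pairs: bool = False,
) -> pd.DataFrame:
    """dR-val for every gene pair across group pairs with the reference.

    ``all_pairs=True`` enumerates the full n(n−1)/2 group-pair set
    instead. Gene pairs lacking a usable coefficient in either group
    (fewer than 3 complete observations) carry missing dR-val and sort
    last. Result is sorted by dR-val descending.
    """
    groups = list(correlations)
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} not computed")
    methods = {c.method for c in correlations.values()}
    alphas = {c.alpha for c in correlations.values()}
    if len(methods) > 1 or len(alphas) > 1:
        raise ValueError("group correlations must share method and alpha")
    if all_pairs:
        group_pairs = list(combinations(groups, 2))
    else:
        group_pairs = [(reference, g) for g in groups if g != reference]

    genes = list(correlations[reference].r.columns)
    rows = []
    for ga, gb in group_pairs:
        ra = correlations[ga].r_gated
        rb = correlations[gb].r_gated
        for gi, gj in combinations(genes, 2):
            va = ra.at[gi, gj]
            vb = rb.at[gi, gj]
            dr = dr_val(va, vb) if not (pd.isna(va) or pd.isna(vb)) else np.nan
            rows.append(
                {
                    "gene_i": gi,
                    "gene_j": gj,
                    "group_a": ga,
                    "group_b": gb,
                    "r_gated_a": va,
                    "r_gated_b": vb,
                    "dr_val": dr,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(
        "dr_val", ascending=False, kind="stable", na_position="last"
    ).reset_index(drop=True)


def pair_scatter_stats(
    norm: NormalizedTable,
    gene_x: str,
    gene_y: str,
    groups: list[str],
    method: str = SPEARMAN,
    variable: str | None = None,
) -> pd.DataFrame:
    """Raw (ungated) correlation and trend line per group for one pair."""
    labels = norm.labels(variable)
    for g in (gene_x, gene_y):
        if g not in norm.genes:
            raise KeyError(f"unknown gene: {g!r}")
    corr_fn = spearman_with_p if method == SPEARMAN else pearson_with_p
    rows = []
    for grp in groups:
        if grp not in set(labels):
            raise KeyError(f"unknown group: {grp!r}")
        sub = norm.neg_delta_ct.loc[labels == grp, [gene_x, gene_y]].dropna()
        if gene_x == gene_y:
            sub = norm.neg_delta_ct.loc[labels == grp, [gene_x]].dropna()
            sub = pd.concat([sub, sub.set_axis([f"{gene_y}__copy"], axis=1)], axis=1)
        if sub.shape[0] < 3:
            raise ValueError(
                f"group {grp!r} has fewer than 3 complete observations "
                f"for {gene_x!r}/{gene_y!r}"
            )
        x = sub.iloc[:, 0].to_numpy()
        y = sub.iloc[:, 1].to_numpy()
        r, p = corr_fn(x, y)
        slope, intercept = np.polyfit(x, y, 1)
        rows.append(
            {
                "group": grp,
                "r": r,
                "p": p,
                "n": int(sub.shape[0]),
                "slope": float(slope),
                "intercept": float(intercept),
                "method": method,
            }
        )
    return pd.DataFrame(rows)
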