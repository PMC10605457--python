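"""Two-group expression comparisons on normalized (−ΔCt) data.

Per-group normality is assessed with a one-sample Kolmogorov–Smirnov
test against a normal law with that group's sample mean and SD
(plug-in parameters, no Lilliefors correction). Any group failing at
alpha = 0.05 routes the comparison to the Mann–Whitney test; otherwise
the classical equal-variance Student t-test is used. Fold change
between groups is 2 to the power of the difference of group median
−ΔCt values, so it reads as a linear-scale expression ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .tables import NormalizedTable

__all__ = [
    "ComparisonRecord",
    "normality_by_group",
    "route_test",
    "compare_groups",
    "pairwise_table",
    "stars",
    "MANN_WHITNEY",
    "STUDENT_T",
]

MANN_WHITNEY = "mann-whitney"
STUDENT_T = "student-t"
NORMALITY_ALPHA = 0.05
_EXACT_MW_MAX_N = 25


@dataclass
class ComparisonRecord:
    """One two-group comparison for one gene."""

    gene: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    fold_change: float
    p_value: float
    test_name: str

    @property
    def stars(self) -> str | None:
        return stars(self.p_value)

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["stars"] = self.stars
        return d


def ks_normality(values: np.ndarray) -> float:
    """Two-sided one-sample KS p against N(sample mean, sample SD)."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 3:
        return float("nan")
    mu = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        return 0.0  # degenerate point mass is maximally non-normal
    return float(stats.kstest(values, "norm", args=(mu, sd)).pvalue)


def normality_by_group(
    norm: NormalizedTable,
    gene: str,
    groups: list[str] | None = None,
    variable: str | None = None,
) -> pd.Series:
    """KS normality p per group for one gene (NaN below 3 values)."""
    labels = norm.labels(variable)
    if gene not in norm.genes:
        raise KeyError(f"unknown gene: {gene!r}")
    if groups is None:
        groups = sorted(labels.dropna().unique())
    out = {}
    for grp in groups:
        if grp not in set(labels):
            raise KeyError(f"unknown group: {grp!r}")
        vals = norm.neg_delta_ct.loc[labels == grp, gene].dropna().to_numpy()
        if vals.size < 3:
            warnings.warn(
                f"group {grp!r} has fewer than 3 values for {gene!r}; "
                "normality p is missing"
            )
            out[grp] = float("nan")
        else:
            out[grp] = ks_normality(vals)
    return pd.Series(out, name="normality_p")


def route_test(normality_p: pd.Series, override: str | None = None) -> str:
    """Pick the comparison test from per-group normality p-values."""
    if override is not None:
        if override not in (MANN_WHITNEY, STUDENT_T):
            raise ValueError(f"unknown test: {override!r}")
        return override
    finite = pd.Series(normality_p).dropna()
    if finite.empty:
        raise ValueError("no finite normality p-value to route on")
    return MANN_WHITNEY if (finite < NORMALITY_ALPHA).any() else STUDENT_T


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann–Whitney p.

    Exact null distribution when the pooled size is ≤ 25 without ties;
    otherwise the normal approximation with continuity and tie
    correction.
    """
    pooled = np.concatenate([a, b])
    exact = pooled.size <= _EXACT_MW_MAX_N and not _has_ties(pooled)
    res = stats.mannwhitneyu(
        a, b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.pvalue)


def compare_groups(
    norm: NormalizedTable,
    gene: str,
    group_a: str,
    group_b: str,
    test: str,
    variable: str | None = None,
) -> ComparisonRecord:
    """Compare −ΔCt of ``gene`` between two groups with ``test``."""
    if group_a == group_b:
        raise ValueError("group_a and group_b must differ")
    if test not in (MANN_WHITNEY, STUDENT_T):
        raise ValueError(f"unknown test: {test!r}")
    a = norm.values_for(gene, group_a, variable).to_numpy()
    b = norm.values_for(gene, group_b, variable).to_numpy()
    for name, vals in ((group_a, a), (group_b, b)):
        if vals.size < 2:
            raise ValueError(
                f"group {name!r} has fewer than 2 values for {gene!r}"
            )
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if test == MANN_WHITNEY:
        p = mann_whitney_p(a, b)
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        if math.isnan(p):  # zero variance in both groups
            p = 1.0
    return ComparisonRecord(
        gene=gene,
        group_a=group_a,
        group_b=group_b,
        n_a=int(a.size),
        n_b=int(b.size),
        median_a=med_a,
        median_b=med_b,
        fold_change=float(2.0 ** (med_a - med_b)),
        p_value=min(p, 1.0),
        test_name=test,
    )


def pairwise_table(
    norm: NormalizedTable,
    gene: str,
    reference: str,
    groups: list[str] | None = None,
    test: str = "auto",
    variable: str | None = None,
) -> pd.DataFrame:
    """All pairwise group comparisons for one gene.

    With ``test="auto"`` the routing rule is applied to the per-group
    normality p-values across the selected groups. In pairs containing
    the reference group, the reference is listed as ``group_b``.
    """
    labels = norm.labels(variable)
    if groups is None:
        groups = sorted(labels.dropna().unique())
    if reference not in groups:
        raise ValueError(f"reference {reference!r} not among groups {groups}")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if test == "auto":
        normality = normality_by_group(norm, gene, groups, variable)
        chosen = route_test(normality)
    else:
        chosen = test
    records = []
    for ga, gb in combinations(groups, 2):
        if ga == reference:
            ga, gb = gb, ga
        records.append(
            compare_groups(norm, gene, ga, gb, chosen, variable).as_dict()
        )
    return pd.DataFrame.from_records(records)


def stars(p: float | None) -> str | None:
    """Significance label for a p-value.

    ``p ≥ 0.05`` → ``ns``; ``p < 0.05`` → ``*``; ``p ≤ 0.01`` → ``**``;
    ``p ≤ 0.001`` → ``***``; ``p ≤ 0.0001`` → ``****`` (strongest
    applicable label wins at the overlapping boundaries).
    """
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return None
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
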