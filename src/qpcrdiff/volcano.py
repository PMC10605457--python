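"""Genome-wide two-group screening with BH adjustment and classification.

Every target gene is compared between two groups with a single,
caller-chosen test; p-values are adjusted across the run with the
Benjamini–Hochberg step-up rule. Genes are classified against strict
fold-change and p thresholds into ``ns`` / ``fc_only`` / ``p_only`` /
``significant`` for volcano-plot labeling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .compare import MANN_WHITNEY, STUDENT_T, mann_whitney_p
from scipy import stats

from .tables import NormalizedTable

__all__ = ["adjust_bh", "volcano_table", "classify_genes"]


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment.

    Missing p-values are excluded from the adjustment and returned
    missing; the output is order-preserving and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if mask.sum() > 0:
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def volcano_table(
    norm: NormalizedTable,
    group_a: str,
    group_b: str,
    test: str = MANN_WHITNEY,
    variable: str | None = None,
    fc_threshold: float = 2.0,
    p_threshold: float = 1e-4,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Screen all target genes between two groups.

    Genes with fewer than 2 usable values in either group get missing
    p (flagged ``untestable``) and class ``ns``. Returns one row per
    gene with medians, fold change, raw and BH-adjusted p, and class.
    """
    if group_a == group_b:
        raise ValueError("group_a and group_b must differ")
    if test not in (MANN_WHITNEY, STUDENT_T):
        raise ValueError(f"unknown test: {test!r}")
    labels = norm.labels(variable)
    for grp in (group_a, group_b):
        if grp not in set(labels):
            raise KeyError(f"unknown group: {grp!r}")

    rows = []
    for gene in norm.genes:
        a = norm.neg_delta_ct.loc[labels == group_a, gene].dropna().to_numpy()
        b = norm.neg_delta_ct.loc[labels == group_b, gene].dropna().to_numpy()
        untestable = a.size < 2 or b.size < 2
        if untestable:
            med_a = float(np.median(a)) if a.size else np.nan
            med_b = float(np.median(b)) if b.size else np.nan
            p = np.nan
        else:
            med_a, med_b = float(np.median(a)), float(np.median(b))
            if test == MANN_WHITNEY:
                p = mann_whitney_p(a, b)
            else:
                p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
                if np.isnan(p):
                    p = 1.0
        fc = float(2.0 ** (med_a - med_b)) if not untestable else np.nan
        rows.append(
            {
                "gene": gene,
                "test": test,
                "n_a": int(a.size),
                "n_b": int(b.size),
                "median_a": med_a,
                "median_b": med_b,
                "fold_change": fc,
                "log2_fold_change": np.log2(fc) if fc == fc else np.nan,
                "p_value": p,
                "untestable": untestable,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = adjust_bh(table["p_value"].to_numpy())
    return classify_genes(table, fc_threshold, p_threshold, use_adjusted)


def classify_genes(
    table: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 1e-4,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Classify genes by strict fold-change and p thresholds.

    ``significant`` needs |log2FC| > log2(fc_threshold) AND the chosen
    p < p_threshold; one-sided exceedances give ``fc_only`` /
    ``p_only``; otherwise ``ns``. Missing p counts as not passing.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    table = table.copy()
    pcol = table["p_adjusted"] if use_adjusted else table["p_value"]
    fc_pass = table["log2_fold_change"].abs() > np.log2(fc_threshold)
    p_pass = pcol < p_threshold
    fc_pass = fc_pass.fillna(False)
    p_pass = p_pass.fillna(False)
    cls = np.where(
        fc_pass & p_pass, "significant",
        np.where(fc_pass, "fc_only", np.where(p_pass, "p_only", "ns")),
    )
    table["class"] = cls
    table["label"] = table["class"] == "significant"
    return table
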