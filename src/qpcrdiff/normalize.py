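"""Livak normalization: −ΔCt per sample and target, and 2^(−ΔΔCt).

The housekeeping summary per sample is the arithmetic mean of the
normalizer Ct values (equivalent to the geometric mean of the linear
quantities, as the Livak method assumes ~100% PCR efficiency);
−ΔCt = HKmean − Ct_target. Relative expression against a reference
group is 2 raised to the difference between a sample's −ΔCt and the
reference group's median −ΔCt, so the reference median maps to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .stability import NormFinderSelector
from .tables import CtTable, NormalizedTable

__all__ = ["LivakNormalizer", "delta_ct", "relative_expression", "RelativeExpression"]


class LivakNormalizer(BaseEstimator, TransformerMixin):
    """Transform raw Ct values into −ΔCt via housekeeping genes.

    Parameters
    ----------
    housekeeping
        Normalizer gene names. ``None`` selects the best stable pair
        with :class:`~qpcrdiff.stability.NormFinderSelector` at fit time
        (``candidates`` restricts the search).
    candidates
        Candidate housekeeping genes for automatic selection.

    Attributes
    ----------
    housekeeping_ : tuple of str
        Normalizers actually used.
    selector_ : NormFinderSelector or None
        The fitted stability selector when selection was automatic.
    """

    def __init__(
        self,
        housekeeping: list[str] | None = None,
        candidates: list[str] | None = None,
    ):
        self.housekeeping = housekeeping
        self.candidates = candidates

    def fit(self, X: pd.DataFrame, y=None) -> "LivakNormalizer":
        X = pd.DataFrame(X)
        if self.housekeeping is not None:
            if len(self.housekeeping) == 0:
                raise ValueError("empty normalizer set")
            unknown = [g for g in self.housekeeping if g not in X.columns]
            if unknown:
                raise KeyError(f"unknown housekeeping gene(s): {unknown}")
            self.housekeeping_ = tuple(self.housekeeping)
            self.selector_ = None
        else:
            if y is None:
                raise ValueError("automatic selection needs group labels y")
            sel = NormFinderSelector(candidates=self.candidates)
            sel.fit(X, y)
            self.housekeeping_ = tuple(sel.best_pair_)
            self.selector_ = sel
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """−ΔCt for every non-normalizer column of ``X``.

        A sample's −ΔCt is missing when its target Ct or any normalizer
        Ct is missing (no imputation).
        """
        X = pd.DataFrame(X).astype(float)
        hk = list(self.housekeeping_)
        hk_block = X[hk]
        hk_mean = hk_block.mean(axis=1)
        hk_mean[hk_block.isna().any(axis=1)] = np.nan
        targets = [g for g in X.columns if g not in set(hk)]
        return X[targets].rsub(hk_mean, axis=0)


def delta_ct(
    table: CtTable,
    normalizers: list[str] | tuple[str, ...],
    exclude: list[str] | tuple[str, ...] | None = None,
) -> NormalizedTable:
    """Normalize a collapsed :class:`CtTable` to −ΔCt target values.

    ``exclude`` lists further housekeeping candidates to drop from the
    target matrix (unchosen candidates are reference material, not
    targets).
    """
    if not table.is_collapsed:
        raise ValueError("collapse technical replicates before normalizing")
    norm = LivakNormalizer(housekeeping=list(normalizers)).fit(table.ct)
    values = norm.transform(table.ct)
    if exclude:
        drop = [g for g in exclude if g in values.columns]
        values = values.drop(columns=drop)
    return NormalizedTable(
        neg_delta_ct=values,
        group=table.group,
        secondary=table.secondary,
        housekeeping=norm.housekeeping_,
        provenance={"method": "livak_neg_delta_ct"},
    )


@dataclass
class RelativeExpression:
    """Per-sample 2^(−ΔΔCt) fold units for one gene."""

    values: pd.Series
    gene: str
    reference_group: str

    def median_reference(self, labels: pd.Series) -> float:
        return float(self.values[labels == self.reference_group].median())


def relative_expression(
    norm: NormalizedTable,
    gene: str,
    reference_group: str,
    variable: str | None = None,
) -> RelativeExpression:
    """2^(−ΔΔCt) per sample, anchored so the reference median is 1."""
    labels = norm.labels(variable)
    if gene not in norm.genes:
        raise KeyError(f"unknown gene: {gene!r}")
    if reference_group not in set(labels):
        raise KeyError(f"unknown reference group: {reference_group!r}")
    ref_vals = norm.neg_delta_ct.loc[labels == reference_group, gene].dropna()
    if ref_vals.empty:
        raise ValueError(
            f"reference group {reference_group!r} has no usable values "
            f"for {gene!r}"
        )
    fold = np.power(2.0, norm.neg_delta_ct[gene])
    # anchor on the fold scale so the reference median is exactly 1
    # (with an even reference group, 2^median(−ΔCt) and median(2^−ΔCt)
    # differ slightly; the displayed quantity is the fold value)
    vals = fold / float(np.power(2.0, ref_vals).median())
    return RelativeExpression(values=vals, gene=gene, reference_group=reference_group)
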