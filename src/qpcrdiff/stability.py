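"""Model-based reference-gene stability scoring (NormFinder approach).

Candidate housekeeping genes are scored — singly and in pairs — by the
variance-decomposition model of Andersen et al. (2004), applied directly
to Ct values (already a log2-scale quantity) from samples that carry an
experimental-group label. Lower stability values mean more stable genes.

The model for gene *i*, group *g*, sample *j* is

    y_igj = alpha_ig + beta_gj + eps_igj,   eps ~ N(0, sigma2_ig)

where ``beta_gj`` is a sample effect shared by all genes (pipetting,
input amount) and ``alpha_ig`` carries the gene-by-group interaction
``d_ig`` (intergroup deviation). The stability value combines the
magnitude of the empirically shrunken ``d_ig`` with the standard-error
contribution of the intragroup variance:

    rho_i = mean_g ( |d~_ig| + sqrt( (s2_ig/n_g) * g2 / (g2 + s2_ig/n_g) ) )

with ``d~_ig = d_ig * g2 / (g2 + s2_ig/n_g)`` and ``g2`` the
between-gene variance of the intergroup deviations after subtracting
their average sampling variance. With a single group the score reduces
to the intragroup standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .tables import CtTable

__all__ = [
    "StabilityReport",
    "NormFinderSelector",
    "stability_single",
    "stability_pairs",
    "select_housekeeping",
]


@dataclass
class StabilityReport:
    """Per-candidate and per-pair stability values."""

    single: pd.Series  # index: gene, values: stability (>=0)
    pairs: pd.Series  # index: frozenset-like tuple (a, b) sorted
    best_single: str
    best_pair: tuple[str, str]
    groups_used: list[str] = field(default_factory=list)
    n_per_group: dict[str, int] = field(default_factory=dict)

    def single_frame(self) -> pd.DataFrame:
        return self.single.rename("stability").rename_axis("gene").reset_index()

    def pair_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [(a, b, v) for (a, b), v in self.pairs.items()],
            columns=["gene_a", "gene_b", "stability"],
        )
        return df.sort_values("stability", kind="stable").reset_index(drop=True)


def _complete_blocks(
    X: pd.DataFrame, labels: pd.Series
) -> dict[str, np.ndarray]:
    """Per-group candidate blocks restricted to complete-case samples.

    Groups where any candidate has fewer than 2 complete observations
    are dropped entirely (keeps the candidate set comparable), with a
    warning.
    """
    blocks: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for grp in sorted(labels.dropna().unique()):
        sub = X.loc[labels == grp].dropna(axis=0, how="any")
        if sub.shape[0] < 2:
            dropped.append(grp)
            continue
        blocks[grp] = sub.to_numpy(dtype=float)
    if dropped:
        warnings.warn(
            f"group(s) with <2 complete samples excluded from stability "
            f"computation: {dropped}"
        )
    if not blocks:
        raise ValueError("no group provides >=2 complete samples")
    return blocks


def _normfinder_components(blocks: dict[str, np.ndarray]):
    """Intragroup variances, intergroup deviations and shrinkage variance.

    Returns ``(genes_axis_len k, groups, sig2 (G,k), d (G,k), n_g (G,),
    gamma2)``; single-group input yields ``d = 0`` and ``gamma2 = 0``.
    """
    groups = list(blocks)
    k = next(iter(blocks.values())).shape[1]
    G = len(groups)

    sig2 = np.zeros((G, k))
    means = np.zeros((G, k))
    n_g = np.zeros(G, dtype=int)
    for gi, grp in enumerate(groups):
        Z = blocks[grp]
        n = Z.shape[0]
        n_g[gi] = n
        gene_mean = Z.mean(axis=0)
        sample_mean = Z.mean(axis=1)
        grand = Z.mean()
        resid = Z - gene_mean[None, :] - sample_mean[:, None] + grand
        m = (resid**2).sum(axis=0) / (n - 1)
        if k > 2:
            # unbiased under gene-specific variances: the two-way
            # residual mixes all genes' noise through the sample mean
            s_hat = m.sum() * k / (k - 1)
            sig2[gi] = np.maximum((m - s_hat / k**2) * k / (k - 2), 0.0)
        else:
            sig2[gi] = m  # decomposition unidentifiable for k = 2
        means[gi] = gene_mean

    if G == 1:
        return k, groups, sig2, np.zeros((1, k)), n_g, 0.0

    # gene-by-group interaction of the cell means (unweighted over groups)
    d = means - means.mean(axis=0)[None, :] - means.mean(axis=1)[:, None] + means.mean()
    samp_var = sig2 / n_g[:, None]
    gamma2 = max(
        float((d**2).sum() / ((k - 1) * (G - 1)) - samp_var.mean()), 0.0
    )
    return k, groups, sig2, d, n_g, gamma2


def _combine(d_row: np.ndarray, var_row: np.ndarray, n_g: np.ndarray,
             gamma2: float, single_group: bool) -> float:
    """Stability value from per-group deviations and variances.

    ``var_row`` holds the intragroup variance of the (single or
    pair-averaged) quantity; its sampling variance is ``var_row / n_g``.
    """
    if single_group:
        return float(np.sqrt(var_row).mean())
    samp = var_row / n_g
    if gamma2 <= 0.0:
        # no detectable intergroup signal: rank by the standard error of
        # the group means (the large-gamma limit of the se term)
        return float(np.sqrt(samp).mean())
    shrink = gamma2 / (gamma2 + samp)
    d_shrunk = d_row * shrink
    se = np.sqrt(samp * shrink)
    return float((np.abs(d_shrunk) + se).mean())


class NormFinderSelector(BaseEstimator):
    """Select the most stable housekeeping genes from Ct data.

    Scikit-learn style estimator: ``fit(X, y)`` takes a samples × genes
    DataFrame of Ct values (``X``) and group labels (``y``) and exposes
    fitted stability attributes.

    Parameters
    ----------
    candidates
        Gene names to evaluate; ``None`` means every column of ``X``.

    Attributes
    ----------
    single_ : pandas.Series
        Stability value per candidate (lower = more stable).
    pairs_ : pandas.Series
        Stability value per unordered candidate pair.
    best_single_ : str
    best_pair_ : tuple of str
    report_ : StabilityReport
    """

    def __init__(self, candidates: list[str] | None = None):
        self.candidates = candidates

    def fit(self, X: pd.DataFrame, y) -> "NormFinderSelector":
        X = pd.DataFrame(X)
        labels = pd.Series(y, index=X.index).astype(str).str.strip()
        labels = labels.mask(labels == "")
        kept = labels.notna()
        X, labels = X.loc[kept], labels[kept]
        if not kept.any():
            raise ValueError("all samples are ungrouped")

        cand = list(self.candidates) if self.candidates is not None else list(X.columns)
        missing = [c for c in cand if c not in X.columns]
        if missing:
            raise KeyError(f"candidate gene(s) absent from table: {missing}")
        if len(cand) < 2:
            raise ValueError("need at least 2 candidate genes")

        blocks = _complete_blocks(X[cand], labels)
        k, groups, sig2, d, n_g, gamma2 = _normfinder_components(blocks)
        single_group = len(groups) == 1

        single = pd.Series(
            [
                _combine(d[:, i], sig2[:, i], n_g, gamma2, single_group)
                for i in range(k)
            ],
            index=cand,
            name="stability",
        )
        pair_vals: dict[tuple[str, str], float] = {}
        for i, j in combinations(range(k), 2):
            d_pair = (d[:, i] + d[:, j]) / 2.0
            var_pair = (sig2[:, i] + sig2[:, j]) / 4.0
            key = tuple(sorted((cand[i], cand[j])))
            pair_vals[key] = _combine(d_pair, var_pair, n_g, gamma2, single_group)
        pairs = pd.Series(pair_vals, name="stability")

        # ties resolved lexicographically (stable sort on sorted index)
        best_single = single.sort_index().idxmin()
        best_pair = pairs.sort_index().idxmin()

        self.single_ = single
        self.pairs_ = pairs
        self.best_single_ = str(best_single)
        self.best_pair_ = tuple(best_pair)
        self.report_ = StabilityReport(
            single=single,
            pairs=pairs,
            best_single=self.best_single_,
            best_pair=self.best_pair_,
            groups_used=groups,
            n_per_group={g: int(n) for g, n in zip(groups, n_g)},
        )
        return self

    def get_support(self) -> list[str]:
        """The selected normalizer genes (the best pair)."""
        return list(self.best_pair_)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Restrict ``X`` to the selected housekeeping genes."""
        return pd.DataFrame(X)[list(self.best_pair_)]


# ---------------------------------------------------------------- wrappers


def _fit_selector(
    table: CtTable, candidates: list[str] | None, group_var: str | None
) -> NormFinderSelector:
    sel = NormFinderSelector(candidates=candidates)
    return sel.fit(table.ct, table.labels(group_var))


def stability_single(
    table: CtTable,
    candidates: list[str],
    group_var: str | None = None,
) -> StabilityReport:
    """Single-gene stability values for ``candidates``."""
    return _fit_selector(table, candidates, group_var).report_


def stability_pairs(
    table: CtTable,
    candidates: list[str],
    group_var: str | None = None,
) -> StabilityReport:
    """Pairwise stability values (the report also carries the singles)."""
    return _fit_selector(table, candidates, group_var).report_


def select_housekeeping(
    table: CtTable,
    user_list: list[str] | None = None,
    group_var: str | None = None,
) -> tuple[str, ...]:
    """Choose the normalizer gene set.

    A one-gene user list is used as-is (single-housekeeping designs);
    two or more genes select the most stable pair among them; with no
    list every gene is a candidate (discouraged — warns).
    """
    if user_list is not None:
        unknown = [g for g in user_list if g not in table.genes]
        if unknown:
            raise KeyError(f"unknown housekeeping gene(s): {unknown}")
        if len(user_list) == 0:
            raise ValueError("empty housekeeping list")
        if len(user_list) == 1:
            return (user_list[0],)
        return _fit_selector(table, list(user_list), group_var).best_pair_
    warnings.warn(
        "no housekeeping list given: evaluating every gene as a candidate "
        "(a curated list is recommended)"
    )
    return _fit_selector(table, None, group_var).best_pair_
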