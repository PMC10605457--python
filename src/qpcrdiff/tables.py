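"""In-memory containers for Ct and normalized expression tables.

A :class:`CtTable` holds raw cycle-threshold (Ct) values as a
samples × genes :class:`pandas.DataFrame` together with a primary group
label per sample and any number of secondary categorical variables.
Before technical-replicate collapsing the sample index may contain
repeated identifiers (one row per replicate measurement); after
collapsing it is unique.

A :class:`NormalizedTable` holds −ΔCt values (log2 relative-expression
units) for target genes only, plus the housekeeping genes that were used
to produce them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["CtTable", "MetadataTable", "NormalizedTable", "InputFormatError"]


class InputFormatError(ValueError):
    """Raised when an input file does not match the declared layout."""


def _clean_labels(values: Iterable) -> list[str]:
    return [str(v).strip() for v in values]


@dataclass
class CtTable:
    """Raw Ct measurements with per-sample group labels.

    Parameters
    ----------
    ct
        Samples × genes matrix of Ct values (PCR cycles). Missing values
        are NaN. The index holds sample identifiers; duplicates denote
        technical replicates of the same sample.
    group
        Primary group label per row, aligned with ``ct``.
    secondary
        Optional additional categorical variables, one column each,
        aligned with ``ct``. May have zero columns.
    """

    ct: pd.DataFrame
    group: pd.Series
    secondary: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ct = self.ct.copy()
        ct.index = pd.Index(_clean_labels(ct.index), name="sample")
        ct.columns = pd.Index(_clean_labels(ct.columns), name="gene")
        if ct.columns.has_duplicates:
            dups = ct.columns[ct.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene names: {dups}")
        if any(c == "" for c in ct.columns):
            raise ValueError("empty gene name")
        ct = ct.astype(float)
        values = ct.to_numpy()
        if np.isinf(values).any():
            raise ValueError("Ct values must be finite or missing")
        if np.nanmin(values, initial=np.inf) < 0:
            raise ValueError("Ct values must be nonnegative")
        self.ct = ct

        group = pd.Series(_clean_labels(self.group), index=ct.index, name="group")
        if (group == "").any() or group.isna().any():
            bad = ct.index[(group == "") | group.isna()].tolist()
            raise ValueError(f"samples with empty primary group: {bad[:5]}")
        self.group = group

        if self.secondary is None:
            self.secondary = pd.DataFrame(index=ct.index)
        else:
            sec = self.secondary.copy()
            sec.index = ct.index
            self.secondary = sec

    # -- convenience -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def n_samples(self) -> int:
        return self.ct.shape[0]

    @property
    def group_levels(self) -> list[str]:
        return sorted(self.group.unique())

    @property
    def is_collapsed(self) -> bool:
        return self.ct.index.is_unique

    def labels(self, variable: str | None = None) -> pd.Series:
        """Group labels for ``variable`` (primary group when ``None``)."""
        if variable in (None, "group", "primary", "primary_group"):
            return self.group
        if variable in self.secondary.columns:
            return self.secondary[variable]
        raise KeyError(f"unknown grouping variable: {variable!r}")

    def summary(self) -> dict:
        """Load summary: counts shown to the user after reading a file."""
        return {
            "n_rows": self.n_samples,
            "n_samples": self.ct.index.nunique(),
            "n_genes": len(self.genes),
            "groups": self.group_levels,
        }

    def __eq__(self, other: object) -> bool:  # value semantics for tests
        if not isinstance(other, CtTable):
            return NotImplemented
        return (
            self.ct.equals(other.ct)
            and self.group.equals(other.group)
            and self.secondary.equals(other.secondary)
        )


@dataclass
class MetadataTable:
    """Per-sample categorical metadata (one identifier per sample)."""

    variables: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.variables.copy()
        df.index = pd.Index(_clean_labels(df.index), name="sample")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers in metadata: {dups}")
        if df.shape[1] < 1:
            raise ValueError("metadata needs at least one variable column")
        self.variables = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.variables.index)


@dataclass
class NormalizedTable:
    """−ΔCt values for target genes, with normalization provenance."""

    neg_delta_ct: pd.DataFrame
    group: pd.Series
    secondary: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    housekeeping: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.neg_delta_ct.copy()
        df.index = pd.Index(_clean_labels(df.index), name="sample")
        df.columns = pd.Index(_clean_labels(df.columns), name="gene")
        if not df.index.is_unique:
            raise ValueError("normalized table requires unique sample identifiers")
        self.neg_delta_ct = df.astype(float)
        self.group = pd.Series(
            _clean_labels(self.group), index=df.index, name="group"
        )
        if self.secondary is None:
            self.secondary = pd.DataFrame(index=df.index)
        else:
            sec = self.secondary.copy()
            sec.index = df.index
            self.secondary = sec
        self.housekeeping = tuple(self.housekeeping)

    @property
    def genes(self) -> list[str]:
        return list(self.neg_delta_ct.columns)

    @property
    def group_levels(self) -> list[str]:
        return sorted(self.group.unique())

    def labels(self, variable: str | None = None) -> pd.Series:
        if variable in (None, "group", "primary", "primary_group"):
            return self.group
        if variable in self.secondary.columns:
            return self.secondary[variable]
        raise KeyError(f"unknown grouping variable: {variable!r}")

    def values_for(
        self,
        gene: str,
        group: str,
        variable: str | None = None,
        dropna: bool = True,
    ) -> pd.Series:
        """−ΔCt values of ``gene`` for the samples in ``group``."""
        if gene not in self.neg_delta_ct.columns:
            raise KeyError(f"unknown gene: {gene!r}")
        labels = self.labels(variable)
        if group not in set(labels):
            raise KeyError(f"unknown group: {group!r}")
        vals = self.neg_delta_ct.loc[labels == group, gene]
        return vals.dropna() if dropna else vals

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NormalizedTable):
            return NotImplemented
        return (
            self.neg_delta_ct.equals(other.neg_delta_ct)
            and self.group.equals(other.group)
            and self.housekeeping == other.housekeeping
        )


def geometric_mean_ct(values: Sequence[float]) -> float:
    """Geometric mean of the non-missing Ct values in ``values``.

    Returns NaN when every value is missing. A zero Ct yields zero.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return float("nan")
    if (arr == 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(arr))))
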