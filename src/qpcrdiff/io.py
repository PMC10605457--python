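"""Reading and writing Ct tables in the four accepted tabular layouts.

Two layouts are supported in each of CSV, TSV (``.txt``) and Excel:

* ``wide`` — first column sample name, second column group label, one
  further column per gene;
* ``long`` — exactly four columns: sample name, group label, gene name,
  Ct value.

Non-numeric Ct cells (blank, ``Undetermined``, ``>40`` …) become missing
values with a warning; data imputation is deliberately not performed.
Excel files may carry a second sheet of per-sample categorical metadata.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import CtTable, InputFormatError, MetadataTable, NormalizedTable, geometric_mean_ct

__all__ = [
    "read_ct_table",
    "read_metadata",
    "collapse_replicates",
    "rename_genes",
    "join_metadata",
    "write_normalized",
    "read_normalized",
]

logger = logging.getLogger(__name__)

_SUFFIX_TO_FILETYPE = {
    ".csv": "csv",
    ".txt": "tsv",
    ".tsv": "tsv",
    ".xls": "xlsx",
    ".xlsx": "xlsx",
}


def _infer_filetype(path: Path, filetype: str | None) -> str:
    if filetype is not None:
        if filetype not in {"csv", "tsv", "xlsx"}:
            raise ValueError(f"unsupported filetype: {filetype!r}")
        return filetype
    try:
        return _SUFFIX_TO_FILETYPE[path.suffix.lower()]
    except KeyError:
        raise InputFormatError(
            "Please, verify the format of the input file."
        ) from None


def _read_raw(path: Path, filetype: str) -> pd.DataFrame:
    # header=None keeps duplicate column names visible (pandas would
    # otherwise mangle them to "A.1"), so duplicates can be rejected
    try:
        if filetype == "csv":
            raw = pd.read_csv(path, dtype=str, header=None)
        elif filetype == "tsv":
            raw = pd.read_csv(path, sep="\t", dtype=str, header=None)
        else:
            raw = pd.read_excel(path, sheet_name=0, dtype=str, header=None)
    except Exception as exc:  # malformed file
        raise InputFormatError(
            "Please, verify the format of the input file."
        ) from exc
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise InputFormatError(
            "Please, verify the format of the input file: "
            "need a header row plus sample and group columns."
        )
    header = raw.iloc[0].astype(str).str.strip()
    data = raw.iloc[1:].reset_index(drop=True)
    data.columns = list(header)
    return data


def _coerce_ct(values: pd.DataFrame | pd.Series, context: str):
    """Numeric coercion: non-numeric tokens and negatives become missing."""
    numeric = pd.to_numeric(
        values.stack() if isinstance(values, pd.DataFrame) else values,
        errors="coerce",
    )
    raw = values.stack() if isinstance(values, pd.DataFrame) else values
    nonblank = raw.notna() & (raw.astype(str).str.strip() != "")
    bad_token = nonblank & numeric.isna()
    if bad_token.any():
        warnings.warn(
            f"{int(bad_token.sum())} non-numeric Ct cell(s) in {context} "
            "treated as missing",
            stacklevel=3,
        )
    negative = numeric.notna() & (numeric < 0)
    if negative.any():
        warnings.warn(
            f"{int(negative.sum())} negative Ct value(s) in {context} "
            "treated as missing",
            stacklevel=3,
        )
        numeric[negative] = np.nan
    if isinstance(values, pd.DataFrame):
        return numeric.unstack().reindex(index=values.index, columns=values.columns)
    return numeric


def _from_wide(raw: pd.DataFrame) -> CtTable:
    if raw.shape[1] < 3:
        raise InputFormatError(
            "Please, verify the format of the input file: "
            "wide layout needs at least one gene column."
        )
    samples = raw.iloc[:, 0].astype(str).str.strip()
    groups = raw.iloc[:, 1]
    genes = raw.iloc[:, 2:].copy()
    gene_names = [str(c).strip() for c in genes.columns]
    if len(set(gene_names)) != len(gene_names):
        seen: set[str] = set()
        dup = sorted({n for n in gene_names if n in seen or seen.add(n)})  # type: ignore[func-returns-value]
        raise InputFormatError(f"duplicate gene column(s): {dup}")
    genes.columns = gene_names
    ct = _coerce_ct(genes, "wide table")
    ct.index = samples
    return CtTable(ct=ct, group=pd.Series(groups.values, index=samples))


def _from_long(raw: pd.DataFrame) -> CtTable:
    if raw.shape[1] != 4:
        raise InputFormatError(
            "Please, verify the format of the input file: "
            "long layout needs exactly four columns "
            "(sample, group, gene, Ct)."
        )
    df = raw.copy()
    df.columns = ["sample", "group", "gene", "ct"]
    for col in ("sample", "group", "gene"):
        df[col] = df[col].astype(str).str.strip()
    df["ct"] = _coerce_ct(df["ct"], "long table")
    # replicate measurements of the same (sample, gene) stay separate rows
    df["_rep"] = df.groupby(["sample", "gene"]).cumcount()
    wide = df.pivot_table(
        index=["sample", "_rep"], columns="gene", values="ct", aggfunc="first",
        dropna=False,
    )
    group_map = df.drop_duplicates(["sample", "group"]).set_index("sample")["group"]
    conflicting = df.groupby("sample")["group"].nunique()
    bad = conflicting[conflicting > 1].index.tolist()
    if bad:
        raise InputFormatError(
            f"sample(s) with conflicting group labels: {bad[:5]}"
        )
    samples = wide.index.get_level_values("sample")
    ct = wide.copy()
    ct.index = samples
    # preserve first-appearance gene order from the file
    order = df["gene"].drop_duplicates().tolist()
    ct = ct[order]
    return CtTable(ct=ct, group=group_map.reindex(samples).set_axis(samples))


def read_ct_table(
    path: str | Path,
    layout: str = "wide",
    filetype: str | None = None,
) -> CtTable:
    """Read a Ct table from ``path``.

    Parameters
    ----------
    path
        Input file (``.csv``, ``.txt``/``.tsv``, ``.xls``/``.xlsx``).
    layout
        ``"wide"``, ``"long"`` or ``"auto"``. Auto-detection tries wide
        then long and raises on ambiguity (a four-column file can be
        either layout).
    filetype
        ``"csv"``, ``"tsv"`` or ``"xlsx"``; inferred from the suffix
        when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ftype = _infer_filetype(path, filetype)
    raw = _read_raw(path, ftype)

    if layout == "wide":
        table = _from_wide(raw)
    elif layout == "long":
        table = _from_long(raw)
    elif layout == "auto":
        if raw.shape[1] == 4:
            raise InputFormatError(
                "ambiguous layout: a four-column file can be wide or long; "
                "pass layout='wide' or layout='long'"
            )
        table = _from_wide(raw) if raw.shape[1] != 4 else _from_long(raw)
    else:
        raise ValueError(f"unknown layout: {layout!r}")

    s = table.summary()
    logger.info(
        "loaded %s: %d rows, %d samples, %d genes, groups=%s",
        path.name, s["n_rows"], s["n_samples"], s["n_genes"], s["groups"],
    )
    return table


def read_metadata(path: str | Path, sheet: int | str = 1) -> MetadataTable:
    """Read per-sample metadata.

    For Excel files this is the second sheet by default (first column =
    sample identifier, one variable per further column); CSV/TSV files
    are read whole.
    """
    path = Path(path)
    ftype = _infer_filetype(path, None)
    if ftype == "xlsx":
        try:
            raw = pd.read_excel(path, sheet_name=sheet, dtype=str)
        except Exception as exc:
            raise InputFormatError(
                "Please, verify the format of the input file: "
                "no readable metadata sheet."
            ) from exc
    elif ftype == "csv":
        raw = pd.read_csv(path, dtype=str)
    else:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise InputFormatError("metadata needs an identifier plus one variable")
    df = raw.set_index(raw.columns[0])
    df.index = df.index.astype(str).str.strip()
    return MetadataTable(variables=df)


def collapse_replicates(table: CtTable) -> CtTable:
    """Collapse technical replicates by the geometric mean of their Cts.

    Rows sharing a sample identifier are replicate measurements; each
    gene's collapsed Ct is the geometric mean of its non-missing
    replicate values (all-missing stays missing). Rows with the same
    identifier but different primary groups are an error.
    """
    groups_per_sample = table.group.groupby(level=0).nunique()
    conflicting = groups_per_sample[groups_per_sample > 1].index.tolist()
    if conflicting:
        raise ValueError(
            f"replicates with conflicting primary group for sample(s): "
            f"{conflicting[:5]}"
        )
    if table.is_collapsed:
        return table

    collapsed = table.ct.groupby(level=0, sort=False).agg(geometric_mean_ct)
    group = table.group.groupby(level=0, sort=False).first()
    sec = table.secondary.groupby(level=0, sort=False).first()
    collapsed = collapsed[table.genes]
    return CtTable(
        ct=collapsed,
        group=group.reindex(collapsed.index),
        secondary=sec.reindex(collapsed.index),
    )


def rename_genes(table: CtTable, mapping: dict[str, str]) -> CtTable:
    """Rename gene columns (e.g. ``{"A": "ACTB"}``); values untouched."""
    unknown = [g for g in mapping if g not in table.genes]
    if unknown:
        raise KeyError(f"unknown gene(s) in rename mapping: {unknown}")
    new_names = [mapping.get(g, g) for g in table.genes]
    if len(set(new_names)) != len(new_names):
        seen: set[str] = set()
        dup = [n for n in new_names if n in seen or seen.add(n)]  # type: ignore[func-returns-value]
        raise ValueError(f"rename would create duplicate gene name(s): {dup}")
    ct = table.ct.copy()
    ct.columns = new_names
    return CtTable(ct=ct, group=table.group, secondary=table.secondary)


def join_metadata(table: CtTable, meta: MetadataTable) -> CtTable:
    """Attach metadata columns as secondary grouping variables.

    Samples absent from the metadata get missing values (warning);
    metadata rows for unknown samples are ignored (warning).
    """
    sample_ids = table.ct.index
    known = set(sample_ids)
    extra = [s for s in meta.sample_ids if s not in known]
    if extra:
        warnings.warn(
            f"{len(extra)} metadata row(s) for unknown sample(s) ignored: "
            f"{extra[:5]}"
        )
    missing = [s for s in sample_ids if s not in set(meta.sample_ids)]
    if missing:
        warnings.warn(
            f"{len(missing)} sample(s) absent from metadata get missing "
            f"values: {missing[:5]}"
        )
    joined = meta.variables.reindex(sample_ids)
    sec = pd.concat([table.secondary, joined], axis=1)
    return CtTable(ct=table.ct, group=table.group, secondary=sec)


def write_normalized(table: NormalizedTable, path: str | Path) -> None:
    """Write −ΔCt values as CSV: sample, group, one column per target.

    A ``#``-prefixed provenance header records the housekeeping genes;
    :func:`read_normalized` reproduces the table.
    """
    if table.neg_delta_ct.shape[1] == 0:
        raise ValueError("empty normalized table")
    path = Path(path)
    out = pd.concat([table.group.rename("group"), table.neg_delta_ct], axis=1)
    out.index.name = "sample"
    with open(path, "w", newline="") as fh:
        fh.write(f"# housekeeping: {','.join(table.housekeeping)}\n")
        for key, val in table.provenance.items():
            fh.write(f"# {key}: {val}\n")
        out.to_csv(fh)


def read_normalized(path: str | Path) -> NormalizedTable:
    """Read a CSV written by :func:`write_normalized`."""
    path = Path(path)
    housekeeping: tuple[str, ...] = ()
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# housekeeping:"):
                names = line.split(":", 1)[1].strip()
                housekeeping = tuple(n for n in names.split(",") if n)
    df = pd.read_csv(path, comment="#", index_col=0)
    return NormalizedTable(
        neg_delta_ct=df.drop(columns="group"),
        group=df["group"],
        housekeeping=housekeeping,
    )
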