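"""Publication-grade static figure export (600 dpi PNG)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .compare import pairwise_table, stars
from .normalize import relative_expression
from .tables import NormalizedTable

__all__ = [
    "export_boxplot",
    "export_volcano",
    "export_dotplot",
    "export_scatter",
    "DPI",
]

DPI = 600


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    fig.savefig(path, dpi=DPI, bbox_inches="tight")
    plt.close(fig)
    return path


def export_boxplot(
    norm: NormalizedTable,
    gene: str,
    reference: str,
    path: str | Path,
    groups: list[str] | None = None,
    relative: bool = False,
    test: str = "auto",
    variable: str | None = None,
) -> Path:
    """Boxplot of −ΔCt (or 2^(−ΔΔCt)) per group with significance stars
    versus the reference group."""
    labels = norm.labels(variable)
    if groups is None:
        groups = sorted(labels.dropna().unique())
    comp = pairwise_table(norm, gene, reference, groups, test, variable)
    if relative:
        rel = relative_expression(norm, gene, reference, variable)
        series = rel.values
        ylabel = r"$2^{-\Delta\Delta Ct}$"
    else:
        series = norm.neg_delta_ct[gene]
        ylabel = r"$-\Delta Ct$"
    data = [series[labels == g].dropna().to_numpy() for g in groups]
    if all(len(d) == 0 for d in data):
        raise ValueError("no data to plot")

    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 1, 4))
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel(ylabel)
    ax.set_title(gene)
    if relative:
        ax.set_yscale("log", base=2)
    top = max(np.nanmax(d) if len(d) else 0.0 for d in data)
    step = 0.08 * (abs(top) + 1)
    level = 0
    ref_pos = groups.index(reference) + 1
    for _, row in comp.iterrows():
        if reference not in (row["group_a"], row["group_b"]):
            continue
        other = row["group_a"] if row["group_b"] == reference else row["group_b"]
        label = stars(row["p_value"]) or ""
        pos = groups.index(other) + 1
        y = top + step * (1.5 + level)
        ax.plot([ref_pos, pos], [y, y], lw=0.8, c="black")
        ax.text((ref_pos + pos) / 2, y, label, ha="center", va="bottom", fontsize=8)
        level += 1
    return _save(fig, path)


def export_volcano(table: pd.DataFrame, path: str | Path,
                   fc_threshold: float = 2.0, p_threshold: float = 1e-4,
                   use_adjusted: bool = False) -> Path:
    """Volcano plot; significant genes are labeled."""
    pcol = "p_adjusted" if use_adjusted else "p_value"
    sub = table.dropna(subset=["log2_fold_change", pcol])
    colors = {
        "ns": "lightgray",
        "fc_only": "seagreen",
        "p_only": "steelblue",
        "significant": "firebrick",
    }
    fig, ax = plt.subplots(figsize=(5, 4.5))
    with np.errstate(divide="ignore"):
        ylog = -np.log10(sub[pcol].to_numpy())
    for cls, color in colors.items():
        m = (sub["class"] == cls).to_numpy()
        ax.scatter(
            sub["log2_fold_change"].to_numpy()[m], ylog[m],
            s=10, c=color, label=cls, alpha=0.8,
        )
    for _, row in sub[sub["class"] == "significant"].iterrows():
        y = -np.log10(row[pcol]) if row[pcol] > 0 else ylog.max()
        ax.annotate(row["gene"], (row["log2_fold_change"], y), fontsize=6)
    ax.axvline(np.log2(fc_threshold), ls="--", lw=0.6, c="gray")
    ax.axvline(-np.log2(fc_threshold), ls="--", lw=0.6, c="gray")
    ax.axhline(-np.log10(p_threshold), ls="--", lw=0.6, c="gray")
    ax.set_xlabel(r"$\log_2$ fold change")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.legend(fontsize=7)
    return _save(fig, path)


def export_dotplot(drtable: pd.DataFrame, path: str | Path) -> Path:
    """Dot plot of dR-val for each gene pair per group comparison."""
    sub = drtable.dropna(subset=["dr_val"]).copy()
    if sub.empty:
        raise ValueError("no dR values to plot")
    sub["comparison"] = sub["group_a"] + " vs " + sub["group_b"]
    comps = sub["comparison"].unique().tolist()
    fig, ax = plt.subplots(figsize=(1.6 * len(comps) + 1.5, 4))
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for i, comp in enumerate(comps):
        vals = sub.loc[sub["comparison"] == comp, "dr_val"].to_numpy()
        x = i + rng.uniform(-0.18, 0.18, size=len(vals))
        ax.scatter(x, vals, s=8, alpha=0.6)
    ax.set_xticks(range(len(comps)), comps, rotation=20, ha="right")
    ax.set_ylabel("dR-val")
    ax.set_ylim(-0.05, 2.05)
    return _save(fig, path)


def export_scatter(
    norm: NormalizedTable,
    gene_x: str,
    gene_y: str,
    groups: list[str],
    stats_table: pd.DataFrame,
    path: str | Path,
    variable: str | None = None,
) -> Path:
    """Two-panel XY plot (one per group) with trend line and r/p."""
    labels = norm.labels(variable)
    fig, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 3.6),
                             sharex=True, sharey=True)
    axes = np.atleast_1d(axes)
    for ax, grp in zip(axes, groups):
        sub = norm.neg_delta_ct.loc[labels == grp, [gene_x, gene_y]].dropna()
        ax.scatter(sub[gene_x], sub[gene_y], s=10, alpha=0.7)
        row = stats_table.set_index("group").loc[grp]
        xs = np.linspace(sub[gene_x].min(), sub[gene_x].max(), 50)
        ax.plot(xs, row["slope"] * xs + row["intercept"], c="firebrick", lw=1)
        ax.set_title(f"{grp}  r={row['r']:.2f}, p={row['p']:.2g}", fontsize=9)
        ax.set_xlabel(f"{gene_x} " + r"$-\Delta Ct$")
    axes[0].set_ylabel(f"{gene_y} " + r"$-\Delta Ct$")
    return _save(fig, path)
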