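"""Seeded synthetic Ct datasets with known ground truth.

Signals are planted on the −ΔCt (log2 expression) scale and mapped to
Ct values through simulated housekeeping genes plus a shared per-sample
loading effect, so Livak normalization inverts the construction exactly
in the noise-free limit. Planted features: group-shifted target genes
(differential expression), stable and unstable housekeeping candidates,
group-dependent pairwise correlations (bivariate normal blocks),
completely-at-random missing cells, and optional technical replicates.

:func:`example_dataset` builds a synthetic replica of a published
68-gene × 328-sample, four-group single-cell qPCR experiment with five
housekeeping candidates named A–E; it is synthetic data, not the
original measurement set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import CtTable

__all__ = ["SyntheticTruth", "generate_dataset", "example_dataset"]

_LOG2 = float(np.log(2.0))


@dataclass
class SyntheticTruth:
    """Planted parameters of a generated dataset."""

    group_names: list[str]
    target_means: pd.DataFrame  # genes × groups, −ΔCt units
    housekeeping: dict[str, dict]  # name -> {base_ct, sd, shifts}
    noise_sd: pd.Series  # per target gene
    noise_dist: dict[str, dict[str, str]]  # gene -> group -> normal|skewed
    corr_pairs: list[tuple[str, str, dict[str, float]]]
    de_genes: dict[str, dict[str, float]]  # gene -> group -> planted shift
    missing_rate: float
    replicate_fraction: float
    seed: int
    sample_loading_sd: float = 0.3
    technical_sd: float = 0.1
    target_base_ct: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for _, _, targets in self.corr_pairs:
            for rho in targets.values():
                if not -1.0 <= rho <= 1.0:
                    raise ValueError(f"planted correlation {rho} outside [-1, 1]")
        for spec in self.housekeeping.values():
            if spec["sd"] <= 0:
                raise ValueError("housekeeping SD must be positive")


def _skewed_noise(rng: np.random.Generator, size: int) -> np.ndarray:
    """Right-skewed noise with unit SD and median zero (exponential)."""
    return rng.exponential(1.0, size=size) - _LOG2


def generate_dataset(
    n_groups: int = 4,
    n_per_group: int = 82,
    n_targets: int = 10,
    n_housekeeping: int = 4,
    *,
    seed: int = 0,
    group_names: list[str] | None = None,
    target_names: list[str] | None = None,
    hk_names: list[str] | None = None,
    de_effects: dict[str, dict[str, float]] | None = None,
    corr_pairs: list[tuple[str, str, dict[str, float]]] | None = None,
    hk_specs: dict[str, dict] | None = None,
    noise_sd: float | dict[str, float] = 1.0,
    noise_dist: dict[str, dict[str, str]] | None = None,
    missing_rate: float = 0.0,
    replicate_fraction: float = 0.0,
    sample_loading_sd: float = 0.3,
    technical_sd: float = 0.1,
) -> tuple[CtTable, SyntheticTruth]:
    """Generate a seeded CtTable with planted ground truth.

    Parameters
    ----------
    n_groups, n_per_group, n_targets, n_housekeeping
        Design dimensions. Housekeeping candidates default to zero
        group shift with per-gene SDs from ``hk_specs``.
    de_effects
        Per-gene, per-group planted −ΔCt mean shifts (log2 fold units
        relative to the zero baseline).
    corr_pairs
        ``(gene_x, gene_y, {group: rho})`` planted Pearson correlation
        targets, induced by bivariate normal noise within each group.
        A gene may appear in at most one pair.
    noise_dist
        Per-gene, per-group noise family: ``"normal"`` (default) or
        ``"skewed"`` (median-centred exponential, breaks normality).
    """
    if min(n_groups, n_per_group, n_targets, n_housekeeping) < 1:
        raise ValueError("design counts must be positive")
    rng = np.random.default_rng(seed)

    groups = group_names or [f"Group{i + 1}" for i in range(n_groups)]
    if len(groups) != n_groups:
        raise ValueError("group_names length mismatch")
    targets = target_names or [f"T{i + 1:02d}" for i in range(n_targets)]
    hks = hk_names or [f"HK{i + 1}" for i in range(n_housekeeping)]
    if set(targets) & set(hks):
        raise ValueError("target and housekeeping names overlap")

    de_effects = de_effects or {}
    corr_pairs = corr_pairs or []
    noise_dist = noise_dist or {}
    seen: set[str] = set()
    for gx, gy, _ in corr_pairs:
        if gx == gy or gx not in targets or gy not in targets:
            raise ValueError(f"infeasible correlation pair ({gx}, {gy})")
        if gx in seen or gy in seen:
            raise ValueError(
                "infeasible correlation structure: gene in more than one pair"
            )
        seen.update((gx, gy))

    means = pd.DataFrame(0.0, index=targets, columns=groups)
    for gene, shifts in de_effects.items():
        for grp, delta in shifts.items():
            means.at[gene, grp] = delta

    if isinstance(noise_sd, dict):
        sd_series = pd.Series({g: noise_sd.get(g, 1.0) for g in targets})
    else:
        sd_series = pd.Series(float(noise_sd), index=targets)

    default_hk = {"base_ct": 20.0, "sd": 0.3, "shifts": {}}
    hk_specs = hk_specs or {}
    hk_full: dict[str, dict] = {}
    for name in hks:
        spec = dict(default_hk, **hk_specs.get(name, {}))
        spec["shifts"] = dict(spec.get("shifts", {}))
        hk_full[name] = spec

    base_ct = {g: float(b) for g, b in zip(targets, rng.uniform(22.0, 28.0, len(targets)))}

    truth = SyntheticTruth(
        group_names=groups,
        target_means=means,
        housekeeping=hk_full,
        noise_sd=sd_series,
        noise_dist=noise_dist,
        corr_pairs=list(corr_pairs),
        de_genes={g: dict(s) for g, s in de_effects.items()},
        missing_rate=missing_rate,
        replicate_fraction=replicate_fraction,
        seed=seed,
        sample_loading_sd=sample_loading_sd,
        technical_sd=technical_sd,
        target_base_ct=base_ct,
    )

    paired = {g for gx, gy, _ in corr_pairs for g in (gx, gy)}
    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    labels: list[str] = []
    genes_order = targets + hks

    for grp in groups:
        n = n_per_group
        expr = pd.DataFrame(0.0, index=range(n), columns=targets)
        # independent genes
        for gene in targets:
            if gene in paired:
                continue
            dist = noise_dist.get(gene, {}).get(grp, "normal")
            eps = (
                _skewed_noise(rng, n)
                if dist == "skewed"
                else rng.standard_normal(n)
            )
            expr[gene] = means.at[gene, grp] + sd_series[gene] * eps
        # correlated pairs via bivariate normal blocks
        for gx, gy, rho_by_group in corr_pairs:
            rho = float(rho_by_group.get(grp, 0.0))
            cov = np.array([[1.0, rho], [rho, 1.0]])
            z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
            expr[gx] = means.at[gx, grp] + sd_series[gx] * z[:, 0]
            expr[gy] = means.at[gy, grp] + sd_series[gy] * z[:, 1]

        loading = rng.normal(0.0, sample_loading_sd, size=n)
        ct = pd.DataFrame(index=range(n), columns=genes_order, dtype=float)
        for gene in targets:
            ct[gene] = base_ct[gene] + loading - expr[gene].to_numpy()
        for name, spec in hk_full.items():
            shift = float(spec["shifts"].get(grp, 0.0))
            ct[name] = (
                spec["base_ct"]
                + shift
                + loading
                + rng.normal(0.0, spec["sd"], size=n)
            )

        base_rows = ct.to_numpy()
        ids = [f"{grp}_S{j + 1:03d}" for j in range(n)]
        n_rep = int(round(replicate_fraction * n))
        rep_idx = set(rng.choice(n, size=n_rep, replace=False)) if n_rep else set()
        for j in range(n):
            if j in rep_idx:
                for _ in range(2):
                    rows.append(
                        base_rows[j]
                        + rng.normal(0.0, technical_sd, size=len(genes_order))
                    )
                    sample_ids.append(ids[j])
                    labels.append(grp)
            else:
                rows.append(base_rows[j])
                sample_ids.append(ids[j])
                labels.append(grp)

    data = np.array(rows)
    data = np.clip(data, 0.0, None)  # Ct values are nonnegative cycles
    if missing_rate > 0:
        mask = rng.random(data.shape) < missing_rate
        data[mask] = np.nan

    ct_df = pd.DataFrame(data, index=sample_ids, columns=genes_order)
    table = CtTable(ct=ct_df, group=pd.Series(labels, index=sample_ids))
    return table, truth


# ---------------------------------------------------------- example replica

_EXAMPLE_DE = {
    # up in Group1 (G1 − G2 median shift > 2 log2 units)
    "TP53": {"Group1": 2.4},
    "CDH2": {"Group1": 2.6},
    "FOS": {"Group1": 3.0},
    "SESN2": {"Group1": 2.2},
    # up in Group2
    "SOD2": {"Group2": 2.4},
    "SRC": {"Group2": 2.2},
    "HIF1A": {"Group2": 2.6},
    "CMBL": {"Group2": 3.0},
    "PCNA": {"Group2": 2.3},
    "SERPINE2": {"Group2": 2.5},
    "ALDH3A1": {"Group2": 2.8},
    "SNAI1": {"Group2": 2.1},
    # AKT1 raised in Group3 (strongly) and Group4 (moderately)
    "AKT1": {"Group3": 2.0, "Group4": 0.6},
}

_EXAMPLE_CORR = [
    # planted Pearson targets chosen so the Spearman coefficients land
    # near +0.43 (Group1) and −0.48 (Group3) for the PCNA–KDM5B pair
    ("PCNA", "KDM5B", {"Group1": 0.45, "Group2": 0.10, "Group3": -0.50, "Group4": 0.0}),
]

_EXAMPLE_HK = {
    "A": {"base_ct": 19.0, "sd": 0.50, "shifts": {"Group2": 0.3, "Group4": -0.3}},
    "B": {"base_ct": 21.0, "sd": 0.15, "shifts": {}},
    "C": {"base_ct": 18.5, "sd": 0.40, "shifts": {"Group3": 0.25}},
    "D": {"base_ct": 23.0, "sd": 0.60, "shifts": {"Group1": 0.4, "Group3": -0.2}},
    "E": {"base_ct": 22.0, "sd": 0.15, "shifts": {}},
}


def example_dataset(seed: int = 0, missing_rate: float = 0.02):
    """Synthetic replica of the published example experiment's structure.

    68 genes (5 housekeeping candidates A–E, 63 targets) × 328 samples
    in four groups. B and E are planted as the stable pair; 12 genes
    are differentially expressed between Group1 and Group2 (4 up in
    Group1, 8 up in Group2); AKT1 is raised in Group3 and Group4; the
    PCNA–KDM5B pair flips correlation between Group1 and Group3. AKT1
    noise is skewed outside Group1 so normality-based routing selects
    the nonparametric path. This is generated data — a stand-in for the
    original supplementary spreadsheet, not a copy of it.
    """
    named = [
        "AKT1", "TP53", "CDH2", "FOS", "SESN2", "SOD2", "SRC", "HIF1A",
        "CMBL", "PCNA", "SERPINE2", "ALDH3A1", "SNAI1", "KDM5B",
    ]
    fillers = [f"T{i:02d}" for i in range(1, 50)]  # 49 fillers -> 63 targets
    targets = named + fillers
    # modest group structure in fillers outside the Group1/Group2 contrast
    de = {g: dict(s) for g, s in _EXAMPLE_DE.items()}
    rng = np.random.default_rng(seed + 104729)
    for i, gene in enumerate(fillers):
        if i % 3 == 0:
            de.setdefault(gene, {})["Group3"] = float(rng.uniform(-1.5, 1.5))
        if i % 4 == 0:
            de.setdefault(gene, {})["Group4"] = float(rng.uniform(-1.2, 1.2))

    table, truth = generate_dataset(
        n_groups=4,
        n_per_group=82,
        n_targets=len(targets),
        n_housekeeping=5,
        seed=seed,
        target_names=targets,
        hk_names=list(_EXAMPLE_HK),
        de_effects=de,
        corr_pairs=_EXAMPLE_CORR,
        hk_specs=_EXAMPLE_HK,
        noise_sd=1.0,
        noise_dist={
            "AKT1": {"Group2": "skewed", "Group3": "skewed", "Group4": "skewed"}
        },
        missing_rate=missing_rate,
    )
    return table, truth
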