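"""Per-gene expression profiles across cell-type groups and a restriction score.

An immunotherapy target is attractive when its expression is restricted to
the hematopoietic compartment (or to the malignant lineage) and stays low in
the non-hematopoietic tissues attacked in graft-versus-host disease -- also
under inflammation, which is why IFN-treated non-hematopoietic samples count
on the non-target side by default.  The restriction score operationalizes
the visual triage of per-cell-type profiles:

    score = min(mean over target groups) - max(mean over non-target groups)

in log2 fluorescence units; higher means more restricted.  The score has no
built-in decision threshold -- it ranks candidates, the cut is the user's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AtlasDataset
from .crossplatform import RELIABILITY_TAU, classify_reliability

logger = logging.getLogger("hematlas")

HEMATOPOIETIC = ("malignant_hematopoietic", "healthy_hematopoietic")


@dataclass
class TargetProfile:
    gene_symbol: str
    probes: list[str]
    groups: pd.DataFrame  # index: group label; mean, sd, n, lineage_group, treatment
    reliability: str  # "quantitative" | "qualitative_only"
    max_fluorescence: float
    ifn_modulation: float | None  # max fold increase across IFN-treated cell types


def _group_key(row: pd.Series) -> str:
    if row["treatment"] == "ifn_gamma":
        return f"{row['cell_type']}+IFN"
    if row["treatment"] == "t_cell_supernatant":
        return f"{row['cell_type']}+Tsup"
    return str(row["cell_type"])


def profile_gene(
    dataset: AtlasDataset,
    gene_symbol: str,
    tau: float = RELIABILITY_TAU,
) -> TargetProfile:
    """Group mean/SD profile of one gene across annotated cell-type groups.

    Treated samples form their own groups (``<cell_type>+IFN``); groups are
    ordered hematopoietic first, then alphabetically, so output is
    deterministic.  The reliability class from the cross-platform gate is
    attached.
    """
    probes = dataset.probes_for_gene(gene_symbol)
    if not probes:
        raise KeyError(f"gene {gene_symbol!r} resolves to no probe in the matrix")
    signal = dataset.matrix.data.loc[probes].mean(axis=0)
    meta = dataset.samples.copy()
    meta["group"] = [_group_key(row) for _, row in meta.iterrows()]
    records = []
    for group, block in meta.groupby("group"):
        vals = signal.loc[block.index]
        records.append({
            "group": group,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "n": int(len(vals)),
            "lineage_group": block["lineage_group"].iloc[0],
            "treatment": block["treatment"].iloc[0],
        })
    groups = pd.DataFrame(records).set_index("group")
    groups = groups.sort_values(
        by=["lineage_group", "group"],
        key=lambda col: col.map(lambda v: (v not in HEMATOPOIETIC, v))
        if col.name == "lineage_group" else col,
    )
    reliability = classify_reliability(dataset.matrix, {gene_symbol: probes}, tau)[0]
    ifn_mod = None
    treated = meta[meta["treatment"] == "ifn_gamma"]
    if len(treated):
        folds = []
        for sid, row in treated.iterrows():
            pair = row["paired_sample_id"]
            if pair in signal.index:
                folds.append(float(np.exp2(signal[sid] - signal[pair])))
        if folds:
            ifn_mod = max(folds)
    return TargetProfile(
        gene_symbol=gene_symbol,
        probes=probes,
        groups=groups,
        reliability=reliability.label,
        max_fluorescence=reliability.max_probe_fluorescence,
        ifn_modulation=ifn_mod,
    )


def restriction_score(
    profile: TargetProfile,
    target_groups: list[str] | None = None,
    include_treated_nontargets: bool = True,
) -> float:
    """min(target group means) - max(non-target group means), log2 units.

    By default the target side is every hematopoietic group and the
    non-target side every non-hematopoietic group including IFN-treated
    ones (inflammation-driven toxicity is the concern).  ``target_groups``
    restricts the target side to a named lineage subset (e.g. the B lineage
    for B-cell surface antigens); the remaining hematopoietic groups then
    count on neither side.
    """
    groups = profile.groups
    hema = groups[groups["lineage_group"].isin(HEMATOPOIETIC)]
    non_hema = groups[groups["lineage_group"] == "non_hematopoietic"]
    if not include_treated_nontargets:
        non_hema = non_hema[non_hema["treatment"] == "none"]
    if target_groups is not None:
        missing = set(target_groups) - set(groups.index)
        if missing:
            raise KeyError(f"unknown target groups: {sorted(missing)}")
        target = groups.loc[list(target_groups)]
    else:
        target = hema
    if target.empty or non_hema.empty:
        raise ValueError("need at least one group on each side of the score")
    return float(target["mean"].min() - non_hema["mean"].max())


def profile_table(
    dataset: AtlasDataset,
    gene_symbols: list[str],
    target_groups: list[str] | None = None,
) -> pd.DataFrame:
    """Tidy per-(gene, group) table with scores and classes for a gene list."""
    rows = []
    for gene in gene_symbols:
        prof = profile_gene(dataset, gene)
        score = restriction_score(prof, target_groups=target_groups)
        for group, g in prof.groups.iterrows():
            rows.append({
                "gene": gene, "group": group, "mean": g["mean"], "sd": g["sd"],
                "n": g["n"], "lineage_group": g["lineage_group"],
                "reliability": prof.reliability, "restriction_score": score,
                "ifn_modulation": prof.ifn_modulation,
            })
    return pd.DataFrame(rows)


def plot_profile(profile: TargetProfile, ax=None):
    """Horizontal mean +/- SD profile per group, hematopoietic groups on top."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.3 * len(profile.groups) + 1.5))
    groups = profile.groups.iloc[::-1]
    y = np.arange(len(groups))
    colors = [
        "tab:red" if lg in HEMATOPOIETIC else "tab:blue"
        for lg in groups["lineage_group"]
    ]
    ax.errorbar(groups["mean"], y, xerr=groups["sd"], fmt="none", ecolor="gray", capsize=2)
    ax.scatter(groups["mean"], y, c=colors, zorder=3)
    ax.set_yticks(y, groups.index)
    ax.set_xlabel("probe fluorescence (log2)")
    ax.set_title(f"{profile.gene_symbol} ({profile.reliability})")
    return ax
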