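"""Fold-induction computation and threshold screens.

Group comparisons are made on the transformed (log2) scale: the treated and
untreated group means are subtracted and the fold increase is

    FC = 2 ** (avg1 - avg2),

equivalently the ratio of geometric-mean linear intensities.  Reported
linear group averages are 2 ** mean-log (geometric means); reported linear
SDs are standard deviations of the linear values.  The screen itself is a
pure fold filter, deliberately without moderated statistics or p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AtlasDataset

logger = logging.getLogger("hematlas")


def fold_increase(avg1: float | np.ndarray, avg2: float | np.ndarray) -> float | np.ndarray:
    """Fold increase 2 ** (avg1 - avg2) from transformed-scale group means."""
    return np.exp2(np.asarray(avg1, dtype=float) - np.asarray(avg2, dtype=float))


def _pairs_by_cell_type(dataset: AtlasDataset, condition: str) -> dict[str, list[tuple[str, str]]]:
    """cell_type -> [(treated_sample, untreated_pair), ...] for a condition."""
    treated = dataset.samples[dataset.samples["treatment"] == condition]
    out: dict[str, list[tuple[str, str]]] = {}
    for sid, row in treated.iterrows():
        pair = row["paired_sample_id"]
        if pair is None or pair not in dataset.samples.index:
            logger.warning("treated sample %s has no resolvable pair; excluded", sid)
            continue
        out.setdefault(row["cell_type"], []).append((sid, pair))
    return out


def group_comparisons(dataset: AtlasDataset, condition: str = "ifn_gamma") -> pd.DataFrame:
    """Per-probe, per-cell-type treated/untreated comparison.

    Returns one row per (probe_id, cell_type) with group means on the
    transformed scale (avg_treated, avg_untreated), geometric-mean linear
    averages, linear-scale SDs, and the fold increase.
    """
    pairs = _pairs_by_cell_type(dataset, condition)
    if not pairs:
        raise ValueError(f"no paired samples for condition {condition!r}")
    frames = []
    data = dataset.matrix.data
    for cell_type in sorted(pairs):
        treated_ids = [t for t, _ in pairs[cell_type]]
        untreated_ids = [u for _, u in pairs[cell_type]]
        avg1 = data[treated_ids].mean(axis=1)
        avg2 = data[untreated_ids].mean(axis=1)
        linear_t = np.exp2(data[treated_ids])
        linear_u = np.exp2(data[untreated_ids])
        frames.append(pd.DataFrame({
            "probe_id": data.index,
            "cell_type": cell_type,
            "condition": condition,
            "avg_treated": avg1.to_numpy(),
            "avg_untreated": avg2.to_numpy(),
            "avg_treated_linear": np.exp2(avg1).to_numpy(),
            "avg_untreated_linear": np.exp2(avg2).to_numpy(),
            "sd_treated_linear": linear_t.std(axis=1, ddof=1).to_numpy(),
            "sd_untreated_linear": linear_u.std(axis=1, ddof=1).to_numpy(),
            "fold_increase": fold_increase(avg1.to_numpy(), avg2.to_numpy()),
            "n_pairs": len(pairs[cell_type]),
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class ScreenResult:
    """Summary of the induction screen for the retained probes."""

    table: pd.DataFrame  # probe_id x cell_type fold-increase matrix (retained probes)
    fold_threshold: float
    min_celltypes: int
    n_celltypes_screened: int

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_over_threshold(self) -> pd.Series:
        return (self.table > self.fold_threshold).sum(axis=1)


def screen_induced(
    dataset: AtlasDataset,
    condition: str = "ifn_gamma",
    fold_threshold: float = 10.0,
    min_celltypes: int = 1,
    comparisons: pd.DataFrame | None = None,
) -> ScreenResult:
    """Probes whose fold increase exceeds ``fold_threshold`` (strict ``>``)
    in at least ``min_celltypes`` screened cell types, sorted by probe ID."""
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    comp = comparisons if comparisons is not None else group_comparisons(dataset, condition)
    fc = comp.pivot(index="probe_id", columns="cell_type", values="fold_increase")
    n_over = (fc > fold_threshold).sum(axis=1)
    keep = sorted(fc.index[n_over >= min_celltypes])
    logger.info(
        "screen %s: %d/%d probes > %g-fold in >= %d of %d cell types",
        condition, len(keep), fc.shape[0], fold_threshold, min_celltypes, fc.shape[1],
    )
    return ScreenResult(fc.loc[keep], fold_threshold, min_celltypes, fc.shape[1])


def cross_condition_concordance(
    fc_a: pd.Series,
    fc_b: pd.Series,
    fold_floor: float = 5.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Compare per-probe folds between two conditions over a shared universe.

    ``fc_a``/``fc_b`` are fold increases indexed by probe ID (e.g. the
    fibroblast column of two screens).  Returns the per-probe table and
    summary counts of probes at or above ``fold_floor`` in each and both
    conditions.
    """
    shared = fc_a.index.intersection(fc_b.index)
    if shared.empty:
        raise ValueError("conditions share no probes")
    table = pd.DataFrame({
        "fold_a": fc_a.loc[shared],
        "fold_b": fc_b.loc[shared],
    })
    table["pass_a"] = table["fold_a"] >= fold_floor
    table["pass_b"] = table["fold_b"] >= fold_floor
    table["both"] = table["pass_a"] & table["pass_b"]
    summary = {
        "n_probes": int(len(table)),
        "n_pass_a": int(table["pass_a"].sum()),
        "n_pass_b": int(table["pass_b"].sum()),
        "n_both": int(table["both"].sum()),
    }
    return table, summary
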