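"""qPCR cross-platform validation of the array signal.

qPCR crossing points (Cp) are corrected by subtracting a weighted average of
reference-gene Cp values measured in the same sample and batch (a multi-gene
delta-Ct).  Per gene, the array signal is regressed on the corrected Cp with
an ordinary quadratic model

    array = b0 + b1 * Cp' + b2 * Cp'^2,

and the per-gene coefficient of determination R2 summarizes how well the two
platforms agree.  A reliability gate classifies genes by their maximum
probe-averaged fluorescence: above the gate the array is trusted
quantitatively; below it, only qualitative statements are supported and qPCR
is the recommended quantitative assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AtlasDataset, ExpressionMatrix

logger = logging.getLogger("hematlas")

#: Fluorescence gate (transformed scale, strict >) separating genes whose
#: array signal supports quantitative interpretation from those needing qPCR.
RELIABILITY_TAU = 11.0

#: R2 level read as "more than two thirds of the variability fits".
R2_CUT = 0.667

REFERENCE_GENES = ("HMBS", "GAPDH", "ACTB")


@dataclass
class ReferenceCorrection:
    reference_genes: tuple[str, ...] = REFERENCE_GENES
    weights: tuple[float, ...] | None = None  # None -> equal weights

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = tuple(1.0 / len(self.reference_genes) for _ in self.reference_genes)
        if len(self.weights) != len(self.reference_genes):
            raise ValueError("one weight per reference gene required")
        if any(w < 0 for w in self.weights):
            raise ValueError("reference weights must be non-negative")
        total = sum(self.weights)
        if not np.isclose(total, 1.0):
            raise ValueError(f"reference weights must sum to 1, got {total}")


def average_replicates(qpcr: pd.DataFrame) -> pd.DataFrame:
    """Mean Cp per (gene, sample, batch); NaN only if all replicates missing."""
    grouped = (
        qpcr.groupby(["gene", "sample_id", "batch"], sort=False)["cp"]
        .mean()
        .reset_index()
    )
    return grouped


def impute_missing_cp(qpcr: pd.DataFrame, policy: str = "censor_max") -> pd.DataFrame:
    """Fill missing Cp values; imputed rows are flagged.

    ``censor_max`` (default): missing <- max observed Cp for that gene in
    that batch + 1 cycle, reflecting detection censoring of late cycles.
    ``batch_gene_mean``: missing <- mean observed Cp for (gene, batch).
    """
    out = qpcr.copy()
    out["imputed"] = out["cp"].isna()
    if not out["imputed"].any():
        return out
    for (gene, batch), idx in out.groupby(["gene", "batch"]).groups.items():
        block = out.loc[idx, "cp"]
        if block.isna().all():
            raise ValueError(f"no observed Cp for gene {gene!r} in batch {batch!r}")
        if policy == "censor_max":
            fill = block.max() + 1.0
        elif policy == "batch_gene_mean":
            fill = block.mean()
        else:
            raise ValueError(f"unknown imputation policy {policy!r}")
        out.loc[idx, "cp"] = block.fillna(fill)
    if "is_missing" in out.columns:
        out["is_missing"] = False
    return out


def correct_cp(
    qpcr: pd.DataFrame, correction: ReferenceCorrection | None = None
) -> pd.DataFrame:
    """Reference-corrected Cp per (gene, sample): Cp' = Cp - sum_r w_r Cp_r.

    Replicates are averaged first.  Reference values are taken from the same
    sample and the same batch as the target measurement; a missing reference
    raises, naming the (sample, batch).
    """
    corr = correction or ReferenceCorrection()
    if qpcr["cp"].isna().any():
        raise ValueError("missing Cp values present; impute before correction")
    means = average_replicates(qpcr)
    refs = means[means["gene"].isin(corr.reference_genes)]
    ref_wide = refs.pivot_table(index=["sample_id", "batch"], columns="gene", values="cp")
    targets = means[~means["gene"].isin(corr.reference_genes)].copy()
    weights = pd.Series(dict(zip(corr.reference_genes, corr.weights)))
    rows = []
    for (sample, batch), block in targets.groupby(["sample_id", "batch"], sort=False):
        if (sample, batch) not in ref_wide.index:
            raise ValueError(f"no reference genes measured for sample {sample!r}, batch {batch!r}")
        ref_row = ref_wide.loc[(sample, batch)]
        missing = [g for g in corr.reference_genes if pd.isna(ref_row.get(g))]
        if missing:
            raise ValueError(
                f"reference gene(s) {missing} missing for sample {sample!r}, batch {batch!r}"
            )
        offset = float((ref_row[list(corr.reference_genes)] * weights).sum())
        block = block.copy()
        block["cp_corrected"] = block["cp"] - offset
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def gene_signal(matrix: ExpressionMatrix, probes: list[str]) -> pd.Series:
    """Probe-averaged transformed signal per sample for one gene."""
    return matrix.data.loc[probes].mean(axis=0)


@dataclass
class ValidationFit:
    """Per-gene quadratic fits plus pooled summaries."""

    per_gene: pd.DataFrame  # gene, b0, b1, b2, r2, n_samples
    pooled_r2: float
    pooled_adjusted_r2: float
    mean_gene_r2: float
    n_samples_total: int

    def __post_init__(self) -> None:
        if self.pooled_adjusted_r2 > self.pooled_r2 + 1e-12:
            raise ValueError("adjusted R2 cannot exceed R2")


def _quadratic_ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    design = np.column_stack([np.ones_like(x), x, x**2])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return beta, ss_res, ss_tot


def fit_quadratic_model(
    corrected_qpcr: pd.DataFrame,
    matrix: ExpressionMatrix,
    gene_probe_map: dict[str, list[str]],
    min_samples: int = 4,
) -> ValidationFit:
    """Per-gene OLS of array signal on (1, Cp', Cp'^2) and pooled R2.

    Multi-probe genes use the probe-averaged transformed signal.  The pooled
    R2 stacks residuals across genes against per-gene means (each gene its
    own intercept); the adjusted version penalizes the 3 parameters per gene.
    A gene with constant array signal has undefined R2 and is reported as
    missing with a warning.
    """
    records = []
    ss_res_total = 0.0
    ss_tot_total = 0.0
    n_total = 0
    n_params = 0
    for gene in sorted(gene_probe_map):
        probes = [p for p in gene_probe_map[gene] if p in matrix.data.index]
        if not probes:
            logger.warning("gene %s has no probe in the matrix; skipped", gene)
            continue
        block = corrected_qpcr[corrected_qpcr["gene"] == gene]
        signal = gene_signal(matrix, probes)
        shared = [s for s in block["sample_id"] if s in signal.index]
        block = block[block["sample_id"].isin(shared)]
        if len(block) < min_samples:
            logger.warning("gene %s: only %d samples on both platforms; skipped", gene, len(block))
            continue
        x = block["cp_corrected"].to_numpy(dtype=float)
        y = signal.loc[block["sample_id"]].to_numpy(dtype=float)
        beta, ss_res, ss_tot = _quadratic_ols(x, y)
        if ss_tot == 0:
            logger.warning("gene %s: constant array signal, R2 undefined", gene)
            r2 = np.nan
        else:
            r2 = 1.0 - ss_res / ss_tot
            ss_res_total += ss_res
            ss_tot_total += ss_tot
            n_total += len(block)
            n_params += 3
        records.append({
            "gene": gene, "b0": beta[0], "b1": beta[1], "b2": beta[2],
            "r2": r2, "n_samples": len(block),
        })
    if not records:
        raise ValueError("no gene had enough samples on both platforms")
    per_gene = pd.DataFrame(records)
    n_genes = int(np.isfinite(per_gene["r2"]).sum())
    pooled_r2 = 1.0 - ss_res_total / ss_tot_total if ss_tot_total > 0 else np.nan
    # null model already spends one mean per gene: N - G vs N - 3G dof
    df_tot = n_total - n_genes
    df_res = n_total - n_params
    if df_res > 0 and ss_tot_total > 0:
        pooled_adj = 1.0 - (ss_res_total / df_res) / (ss_tot_total / df_tot)
    else:
        pooled_adj = np.nan
    return ValidationFit(
        per_gene=per_gene,
        pooled_r2=pooled_r2,
        pooled_adjusted_r2=pooled_adj,
        mean_gene_r2=float(per_gene["r2"].mean(skipna=True)),
        n_samples_total=n_total,
    )


@dataclass
class ReliabilityClass:
    gene_symbol: str
    max_probe_fluorescence: float
    quantitative: bool
    tau: float = RELIABILITY_TAU

    @property
    def label(self) -> str:
        return "quantitative" if self.quantitative else "qualitative_only"


def classify_reliability(
    matrix: ExpressionMatrix,
    gene_probe_map: dict[str, list[str]],
    tau: float = RELIABILITY_TAU,
) -> list[ReliabilityClass]:
    """Gate genes on the sample maximum of their probe-averaged signal (strict >)."""
    out = []
    for gene in sorted(gene_probe_map):
        probes = [p for p in gene_probe_map[gene] if p in matrix.data.index]
        if not probes:
            raise KeyError(f"gene {gene!r} resolves to no probe in the matrix")
        max_fluor = float(gene_signal(matrix, probes).max())
        out.append(ReliabilityClass(gene, max_fluor, max_fluor > tau, tau))
    return out


def classify_from_maxima(
    per_probe_maxima: dict[str, list[float]] | pd.DataFrame,
    tau: float = RELIABILITY_TAU,
) -> list[ReliabilityClass]:
    """Gate genes given per-probe maximum fluorescence values.

    Accepts ``{gene: [max per probe, ...]}`` or a frame with ``gene`` and
    ``max_1``/``max_2`` columns; multi-probe genes use the average of the
    per-probe maxima (the convention of published validation summaries).
    """
    if isinstance(per_probe_maxima, pd.DataFrame):
        mapping = {
            row["gene"]: [v for v in (row.get("max_1"), row.get("max_2")) if pd.notna(v)]
            for _, row in per_probe_maxima.iterrows()
        }
    else:
        mapping = per_probe_maxima
    out = []
    for gene, maxima in mapping.items():
        if not maxima:
            raise ValueError(f"gene {gene!r} has no probe maxima")
        avg = float(np.mean(maxima))
        out.append(ReliabilityClass(gene, avg, avg > tau, tau))
    return out
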