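"""Variance-stabilizing transformation and quantile normalization.

Bead arrays report, per probe and sample, the mean and standard deviation of
bead-level fluorescence.  The technical variance is well described by a
quadratic function of the mean,

    sd^2 = c1 + c2 * mean + c3 * mean^2,

mixing additive background noise (c1), shot-type noise (c2) and
multiplicative noise (c3).  The matching variance-stabilizing transform is a
generalized log.  With a = c2 / (2 c3) the fitted variance factors as
v(x) = c3 * ((x + a)^2 + b2), b2 = c1/c3 - a^2, and we use

    h(x) = log2( x + a + sqrt((x + a)^2 + b2) ),

which is monotone on x >= 0 and satisfies h(x) -> log2(x) + 1 as x -> inf,
so the transformed scale is a base-2 log scale at high intensity.  In the
purely multiplicative limit (c1 = c2 = 0) it is exactly log2(x) + 1.

Quantile normalization then forces every sample column onto the common
distribution given by the across-sample mean of order statistics; ties
within a column receive the mean of the order-statistic values they span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core import ExpressionMatrix

logger = logging.getLogger("hematlas")


@dataclass
class VarianceModel:
    """Quadratic variance-mean fit and the derived transform parameters."""

    c1: float
    c2: float
    c3: float
    mean_range: tuple[float, float] = (0.0, np.inf)
    epsilon: float = 1.0  # shifted-log offset used when c3 == 0

    def __post_init__(self) -> None:
        if self.c3 < 0:
            raise ValueError("c3 must be non-negative")

    def variance(self, mean: np.ndarray | float) -> np.ndarray | float:
        return self.c1 + self.c2 * np.asarray(mean, dtype=float) + self.c3 * np.square(mean)

    @property
    def offset(self) -> float:
        """Shift a of the generalized log; 0 in the multiplicative limit."""
        return self.c2 / (2.0 * self.c3) if self.c3 > 0 else np.inf

    @property
    def curvature(self) -> float:
        """b2 term of the generalized log: c1/c3 - a^2."""
        if self.c3 <= 0:
            return np.inf
        return self.c1 / self.c3 - self.offset**2


def fit_variance_function(bead_summaries: pd.DataFrame, min_pairs: int = 50) -> VarianceModel:
    """Fit sd^2 = c1 + c2*mean + c3*mean^2 over (probe, sample) pairs.

    Non-negative least squares keeps every coefficient >= 0, so the fitted
    variance is positive over the whole observed range and the derived
    generalized-log argument never goes negative.  Requires ``mean`` and
    ``sd`` columns; rows with missing sd are dropped.
    """
    df = bead_summaries.dropna(subset=["mean", "sd"])
    if len(df) < min_pairs:
        raise ValueError(f"need >= {min_pairs} (probe, sample) pairs, got {len(df)}")
    m = df["mean"].to_numpy(dtype=float)
    if np.ptp(m) == 0:
        raise ValueError("degenerate design: all bead means are equal")
    y = np.square(df["sd"].to_numpy(dtype=float))
    # column scaling keeps NNLS well-conditioned across the intensity range
    scales = np.array([1.0, m.mean(), np.square(m).mean()])
    design = np.column_stack([np.ones_like(m), m, np.square(m)]) / scales
    coef, _ = nnls(design, y)
    # the sampling noise of sd^2 scales with the variance itself, so one
    # reweighting pass (weights 1/v_hat^2) recovers the low-intensity
    # coefficients that plain least squares drowns out
    fitted = np.maximum(design @ coef, np.percentile(y, 1) + 1e-12)
    w = 1.0 / fitted
    coef, _ = nnls(design * w[:, None], y * w)
    c1, c2, c3 = coef / scales
    logger.info("variance fit: c1=%.4g c2=%.4g c3=%.4g on %d pairs", c1, c2, c3, len(df))
    return VarianceModel(c1, c2, c3, mean_range=(float(m.min()), float(m.max())))


def vst_values(x: np.ndarray, model: VarianceModel) -> np.ndarray:
    """Generalized-log transform of linear values under a fitted model."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("negative linear fluorescence cannot be transformed")
    if model.c3 > 0:
        a = model.offset
        arg = x + a + np.sqrt(np.square(x + a) + model.curvature)
        return np.log2(arg)
    # no multiplicative component fitted: shifted log keeps the log2 asymptote
    return np.log2(x + model.epsilon)


def vst_transform(matrix_linear: ExpressionMatrix, model: VarianceModel) -> ExpressionMatrix:
    """Apply the variance-stabilizing transform to a linear-scale matrix."""
    if matrix_linear.scale != "linear":
        raise ValueError("vst_transform expects a linear-scale matrix")
    values = vst_values(matrix_linear.data.to_numpy(), model)
    out = pd.DataFrame(values, index=matrix_linear.data.index, columns=matrix_linear.data.columns)
    return ExpressionMatrix(out, scale="transformed")


def log2_fallback(matrix_linear: ExpressionMatrix, epsilon: float = 1.0) -> ExpressionMatrix:
    """log2(x + epsilon) transform for matrices without bead-level SDs."""
    if matrix_linear.scale != "linear":
        raise ValueError("expects a linear-scale matrix")
    return ExpressionMatrix(np.log2(matrix_linear.data + epsilon), scale="transformed")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the mean order-statistic distribution.

    Within-column ranks are preserved; tied values receive the mean of the
    order-statistic values their rank positions span.  Idempotent.
    """
    if matrix.scale != "transformed":
        raise ValueError("quantile normalization expects a transformed-scale matrix")
    df = matrix.data
    if df.shape[1] < 2:
        raise ValueError("need >= 2 samples to quantile-normalize")
    values = df.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        if len(np.unique(col)) == len(col):
            out[:, j] = assigned
        else:
            # average assigned reference values across tied input values
            series = pd.Series(assigned)
            out[:, j] = series.groupby(col).transform("mean").to_numpy()
    result = pd.DataFrame(out, index=df.index, columns=df.columns)
    return ExpressionMatrix(result, scale="transformed")


def normalize(
    matrix_linear: ExpressionMatrix,
    bead_summaries: pd.DataFrame | None = None,
    epsilon: float = 1.0,
) -> tuple[ExpressionMatrix, VarianceModel | None]:
    """Full normalization: VST (or shifted-log fallback) + quantile normalization.

    Returns the normalized matrix and the fitted variance model (None when
    bead-level SDs were unavailable and the fallback was used).
    """
    if bead_summaries is not None:
        model = fit_variance_function(bead_summaries)
        transformed = vst_transform(matrix_linear, model)
    else:
        model = None
        transformed = log2_fallback(matrix_linear, epsilon=epsilon)
    return quantile_normalize(transformed), model
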