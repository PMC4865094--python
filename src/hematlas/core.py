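"""Core domain types for the expression atlas.

The atlas is a probe x sample matrix of bead-array fluorescence together
with sample and probe annotation tables.  Values live on one of two scales:

* ``linear`` -- raw fluorescence as summarized from beads (positive reals);
* ``transformed`` -- a base-2 logarithmic scale (the output of the
  variance-stabilizing transformation, calibrated to a log2 asymptote).

The two scales are linked by ``linear = 2 ** transformed``; group fold
changes downstream are ratios of geometric means, i.e. ``2 ** (avg1 - avg2)``
of group-mean transformed values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger("hematlas")

Scale = Literal["linear", "transformed"]

LINEAGE_GROUPS = ("malignant_hematopoietic", "healthy_hematopoietic", "non_hematopoietic")
TREATMENTS = ("none", "ifn_gamma", "t_cell_supernatant")

SAMPLE_COLUMNS = ("cell_type", "lineage_group", "treatment", "paired_sample_id", "batch")


@dataclass
class ExpressionMatrix:
    """Probe x sample expression values with a declared scale.

    ``data`` is indexed by probe ID with sample IDs as columns.  Transformed
    values must be finite; linear values must be positive wherever finite.
    """

    data: pd.DataFrame
    scale: Scale = "transformed"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate probe ID: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        if self.scale not in ("linear", "transformed"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "transformed" and not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("transformed matrix contains non-finite values")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.scale)


def to_linear(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise ``2 ** x`` view of a transformed matrix."""
    if matrix.scale != "transformed":
        raise ValueError("to_linear expects a transformed-scale matrix")
    return ExpressionMatrix(np.exp2(matrix.data), scale="linear")


def to_log(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise ``log2(x)`` view of a linear matrix; inverse of to_linear."""
    if matrix.scale != "linear":
        raise ValueError("to_log expects a linear-scale matrix")
    vals = matrix.data.to_numpy()
    if (vals <= 0).any():
        bad = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"non-positive value at probe {matrix.data.index[bad[0]]!r}, "
            f"sample {matrix.data.columns[bad[1]]!r}"
        )
    return ExpressionMatrix(np.log2(matrix.data), scale="transformed")


def make_sample_annotations(records: Iterable[dict] | pd.DataFrame) -> pd.DataFrame:
    """Build and validate a sample annotation table.

    Required fields: sample_id, cell_type, lineage_group, treatment.
    Optional: paired_sample_id (required when treatment != none), batch.
    """
    df = pd.DataFrame(records)
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    for col in SAMPLE_COLUMNS:
        if col not in df.columns:
            df[col] = "none" if col == "treatment" else None
    df = df[list(SAMPLE_COLUMNS) + [c for c in df.columns if c not in SAMPLE_COLUMNS]]
    validate_sample_annotations(df)
    return df


def validate_sample_annotations(samples: pd.DataFrame) -> None:
    if samples.index.has_duplicates:
        dup = samples.index[samples.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID: {dup!r}")
    bad_lineage = set(samples["lineage_group"].dropna()) - set(LINEAGE_GROUPS)
    if bad_lineage:
        raise ValueError(f"unknown lineage_group values: {sorted(bad_lineage)}")
    bad_treat = set(samples["treatment"].dropna()) - set(TREATMENTS)
    if bad_treat:
        raise ValueError(f"unknown treatment values: {sorted(bad_treat)}")
    treated = samples[samples["treatment"] != "none"]
    for sid, row in treated.iterrows():
        pid = row["paired_sample_id"]
        if pid is None or (isinstance(pid, float) and np.isnan(pid)):
            raise ValueError(f"treated sample {sid!r} has no paired_sample_id")
        if pid not in samples.index:
            raise ValueError(f"paired sample {pid!r} of {sid!r} not found")
        pair = samples.loc[pid]
        if pair["treatment"] != "none":
            raise ValueError(f"pair {pid!r} of {sid!r} is not an untreated sample")
        if pair["cell_type"] != row["cell_type"]:
            raise ValueError(
                f"pair {pid!r} of {sid!r} has different cell_type "
                f"({pair['cell_type']!r} vs {row['cell_type']!r})"
            )


def make_probe_annotations(records: Iterable[dict] | pd.DataFrame) -> pd.DataFrame:
    """Build a probe annotation table: probe_id -> gene_symbol, chip versions.

    ``present_on_versions`` is a comma-joined label set, e.g. ``"v3,v4"``.
    """
    df = pd.DataFrame(records)
    if "probe_id" in df.columns:
        df = df.set_index("probe_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate probe ID: {dup!r}")
    if "gene_symbol" not in df.columns:
        raise ValueError("probe annotations need a gene_symbol column")
    if "present_on_versions" not in df.columns:
        df["present_on_versions"] = ""
    return df


@dataclass
class AtlasDataset:
    """Expression matrix plus sample and probe annotations, axes-consistent."""

    matrix: ExpressionMatrix
    samples: pd.DataFrame
    probes: pd.DataFrame
    excluded_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.matrix.sample_ids) != list(self.samples.index):
            missing = set(self.matrix.sample_ids) ^ set(self.samples.index)
            raise ValueError(f"matrix/sample annotation mismatch: {sorted(missing)[:5]}")
        if not set(self.matrix.probe_ids) <= set(self.probes.index):
            missing = set(self.matrix.probe_ids) - set(self.probes.index)
            raise ValueError(f"unannotated probes in matrix: {sorted(missing)[:5]}")
        validate_sample_annotations(self.samples)

    def probes_for_gene(self, gene_symbol: str) -> list[str]:
        """Probe IDs mapping to a gene symbol, restricted to the matrix."""
        hits = self.probes.index[self.probes["gene_symbol"] == gene_symbol]
        return [p for p in hits if p in self.matrix.data.index]

    def drop_samples(self, sample_ids: Iterable[str]) -> "AtlasDataset":
        """Return a dataset with the given samples removed (QC exclusion)."""
        drop = [s for s in sample_ids if s in self.samples.index]
        keep = [s for s in self.matrix.sample_ids if s not in set(drop)]
        samples = self.samples.loc[keep].copy()
        # unlink pairs pointing at dropped samples
        mask = samples["paired_sample_id"].isin(drop)
        samples.loc[mask, ["paired_sample_id", "treatment"]] = [None, "none"]
        return AtlasDataset(
            ExpressionMatrix(self.matrix.data[keep], self.matrix.scale),
            samples,
            self.probes,
            excluded_samples=self.excluded_samples + drop,
        )


def merge_chip_versions(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    probes: pd.DataFrame | None = None,
    how: Literal["intersection", "union"] = "intersection",
) -> ExpressionMatrix:
    """Merge two chip-version matrices into one dataset.

    The default keeps the probes present on both versions (only those are
    measured in every sample); ``how="union"`` keeps everything, with NaN
    where a probe is absent from one version.  Sample order is the
    concatenation of a then b.
    """
    if matrix_a.scale != matrix_b.scale:
        raise ValueError("cannot merge matrices on different scales")
    overlap = set(matrix_a.sample_ids) & set(matrix_b.sample_ids)
    if overlap:
        raise ValueError(f"sample sets overlap: {sorted(overlap)[:5]}")
    if how == "intersection":
        shared = [p for p in matrix_a.probe_ids if p in set(matrix_b.probe_ids)]
        if not shared:
            raise ValueError("chip versions share no probes")
        data = pd.concat(
            [matrix_a.data.loc[shared], matrix_b.data.loc[shared]], axis=1
        )
    elif how == "union":
        data = pd.concat([matrix_a.data, matrix_b.data], axis=1)
    else:
        raise ValueError(f"unknown merge mode {how!r}")
    logger.info(
        "merged chip versions: %d + %d samples, %d probes (%s)",
        len(matrix_a.sample_ids), len(matrix_b.sample_ids), data.shape[0], how,
    )
    merged = ExpressionMatrix.__new__(ExpressionMatrix)
    merged.data = data
    merged.scale = matrix_a.scale
    if how == "intersection":
        # re-run invariant checks; union may legitimately hold NaN
        return ExpressionMatrix(data, matrix_a.scale)
    return merged
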