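"""Readers and writers for the tab-delimited formats the pipeline consumes.

Expression tables are GenomeStudio-style exports: probe IDs in the first
column, one column per sample.  A bead-summary export additionally carries
``<sample>.AVG_Signal``, ``<sample>.BEAD_STDERR`` and ``<sample>.Avg_NBEADS``
columns; those are parsed into a long-format bead-summary frame.  European
exports with decimal commas are handled through ``decimal=","``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, make_probe_annotations, make_sample_annotations

logger = logging.getLogger("hematlas")

_BEAD_SUFFIXES = (".AVG_Signal", ".BEAD_STDERR", ".Avg_NBEADS")


def _parse_numeric(df: pd.DataFrame, decimal: str) -> pd.DataFrame:
    """Convert string cells to floats, reporting the first bad coordinate."""
    out = {}
    for col in df.columns:
        series = df[col].astype(str).str.strip()
        if decimal != ".":
            series = series.str.replace(decimal, ".", regex=False)
        converted = pd.to_numeric(series, errors="coerce")
        blank = series.isin(("", "nan", "NaN", "NA"))
        bad = converted.isna() & ~blank
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric value {df.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def read_expression_table(
    path: str | Path,
    scale: str = "transformed",
    decimal: str = ".",
) -> ExpressionMatrix:
    """Read a probe x sample TSV into an ExpressionMatrix.

    Raises on duplicate probe IDs (naming the probe) and on non-numeric
    cells (naming row and column).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate probe ID in {path}: {dup!r}")
    sample_cols = [c for c in raw.columns if not c.endswith(_BEAD_SUFFIXES)]
    avg_cols = [c for c in raw.columns if c.endswith(".AVG_Signal")]
    if avg_cols and not sample_cols:
        values = _parse_numeric(raw[avg_cols], decimal)
        values.columns = [c[: -len(".AVG_Signal")] for c in avg_cols]
    else:
        values = _parse_numeric(raw[sample_cols], decimal)
    values.index.name = "probe_id"
    logger.info("read expression table %s: %d probes x %d samples", path, *values.shape)
    return ExpressionMatrix(values, scale=scale)


def read_bead_summary_table(path: str | Path, decimal: str = ".") -> pd.DataFrame:
    """Read a GenomeStudio-style bead-summary export into long format.

    Returns columns: probe_id, sample_id, mean, sd, n_beads.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    samples = sorted({c.rsplit(".", 1)[0] for c in raw.columns if c.endswith(_BEAD_SUFFIXES)})
    if not samples:
        raise ValueError(f"{path} has no .AVG_Signal/.BEAD_STDERR/.Avg_NBEADS columns")
    frames = []
    for s in samples:
        cols = {f"{s}.AVG_Signal": "mean", f"{s}.BEAD_STDERR": "sd", f"{s}.Avg_NBEADS": "n_beads"}
        present = {c: n for c, n in cols.items() if c in raw.columns}
        block = _parse_numeric(raw[list(present)], decimal).rename(columns=present)
        block.insert(0, "sample_id", s)
        frames.append(block.reset_index(names="probe_id"))
    out = pd.concat(frames, ignore_index=True)
    if "n_beads" in out.columns:
        out["n_beads"] = out["n_beads"].round().astype("Int64")
    return out


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, decimal: str = ".", float_format: str = "%.10g"
) -> None:
    df = matrix.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format=float_format, decimal=decimal)


def write_bead_summary_table(bead: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format bead summary as a GenomeStudio-style wide TSV."""
    wide = bead.pivot(index="probe_id", columns="sample_id")
    cols = []
    suffix = {"mean": "AVG_Signal", "sd": "BEAD_STDERR", "n_beads": "Avg_NBEADS"}
    for field, sample in wide.columns:
        cols.append(f"{sample}.{suffix[field]}")
    wide.columns = cols
    wide = wide[sorted(cols, key=lambda c: (c.rsplit(".", 1)[0], c))]
    wide.to_csv(path, sep="\t", float_format="%.10g")


def read_sample_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).replace({"": None, "nan": None})
    return make_sample_annotations(df)


def write_sample_annotations(samples: pd.DataFrame, path: str | Path) -> None:
    samples.reset_index(names="sample_id").to_csv(path, sep="\t", index=False)


def read_probe_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return make_probe_annotations(df)


def write_probe_annotations(probes: pd.DataFrame, path: str | Path) -> None:
    probes.reset_index(names="probe_id").to_csv(path, sep="\t", index=False)


def read_qpcr_table(path: str | Path, decimal: str = ".") -> pd.DataFrame:
    """Read a qPCR table: gene, sample_id, batch, replicate, cp (blank = missing)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "sample_id", "batch", "replicate", "cp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    cp = df["cp"].astype(str).str.strip()
    if decimal != ".":
        cp = cp.str.replace(decimal, ".", regex=False)
    df["cp"] = pd.to_numeric(cp.replace({"": None, "nan": None}), errors="raise")
    df["replicate"] = df["replicate"].astype(int)
    df["is_missing"] = df["cp"].isna()
    return df


def write_qpcr_table(qpcr: pd.DataFrame, path: str | Path) -> None:
    out = qpcr[["gene", "sample_id", "batch", "replicate", "cp"]].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_series_matrix(path: str | Path, scale: str = "transformed") -> ExpressionMatrix:
    """Best-effort reader for a GEO series-matrix text file.

    Parses the ``!series_matrix_table_begin`` .. ``_end`` block; sample titles
    come from ``!Sample_title`` when present, otherwise GSM accessions are
    kept.  Quotes are stripped.  No guarantee beyond the plain-text layout.
    """
    lines = Path(path).read_text().splitlines()
    titles: list[str] | None = None
    table: list[str] = []
    in_table = False
    for line in lines:
        if line.startswith("!series_matrix_table_begin"):
            in_table = True
            continue
        if line.startswith("!series_matrix_table_end"):
            break
        if in_table:
            table.append(line)
        elif line.startswith("!Sample_title"):
            titles = [t.strip().strip('"') for t in line.split("\t")[1:]]
    if not table:
        raise ValueError(f"{path}: no series matrix table block found")
    rows = [l.split("\t") for l in table]
    header = [h.strip().strip('"') for h in rows[0]]
    df = pd.DataFrame(rows[1:], columns=header)
    df[header[0]] = df[header[0]].str.strip('"')
    df = df.set_index(header[0])
    values = _parse_numeric(df, ".")
    if titles and len(titles) == values.shape[1]:
        values.columns = titles
    return ExpressionMatrix(values, scale=scale)
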