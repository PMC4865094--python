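"""Bundled published summary tables and recomputation helpers.

Two small reference tables ship with the package:

* ``fibroblast_induction.tsv`` -- per-probe group averages (linear scale) and
  SDs of fibroblast fluorescence untreated vs. IFN-gamma and untreated vs.
  T-cell supernatant, with the published fold increases, for the 47 probes
  retained by the >10-fold inflammation screen (GSE76340 study design).
* ``qpcr_validation.tsv`` -- the 24-gene qPCR validation summary: per-probe
  maximum fluorescence in the validation sample set and the per-gene R2 of
  the quadratic cross-platform regression.

These printed group-level summaries are inputs here: the helpers recompute
fold increases, screen memberships and reliability classes from them, which
exercises the same code paths the pipeline applies to full datasets.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .crossplatform import R2_CUT, RELIABILITY_TAU, classify_from_maxima
from .induction import cross_condition_concordance, fold_increase


def _load(name: str) -> pd.DataFrame:
    with resources.files("hematlas.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_fibroblast_induction() -> pd.DataFrame:
    """The 47-probe fibroblast inflammation-induction summary."""
    return _load("fibroblast_induction.tsv")


def load_qpcr_validation() -> pd.DataFrame:
    """The 24-gene qPCR cross-platform validation summary."""
    return _load("qpcr_validation.tsv")


def recompute_folds(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute fold increases from the printed linear group averages.

    The fold is 2 ** (log2 avg_treated - log2 avg_untreated), i.e. the plain
    ratio of the linear averages; ``fc_*_recomputed`` columns are added next
    to the printed folds.
    """
    df = (table if table is not None else load_fibroblast_induction()).copy()
    for cond in ("ifn", "tsup"):
        df[f"fc_{cond}_recomputed"] = fold_increase(
            np.log2(df[f"avg_{cond}"]), np.log2(df[f"avg_untreated_{cond}"])
        )
    return df


def induction_filter_count(table: pd.DataFrame | None = None, fold_threshold: float = 10.0) -> int:
    """Probes whose recomputed fold exceeds the threshold in either condition."""
    df = recompute_folds(table)
    keep = (df["fc_ifn_recomputed"] > fold_threshold) | (df["fc_tsup_recomputed"] > fold_threshold)
    return int(keep.sum())


def concordance_counts(
    table: pd.DataFrame | None = None, fold_floor: float = 5.0
) -> dict[str, int]:
    """Cross-condition concordance of the recomputed folds at a fold floor."""
    df = recompute_folds(table).set_index("probe_id")
    _, summary = cross_condition_concordance(
        df["fc_ifn_recomputed"], df["fc_tsup_recomputed"], fold_floor=fold_floor
    )
    return summary


def reliability_counts(
    table: pd.DataFrame | None = None,
    tau: float = RELIABILITY_TAU,
    r2_cut: float = R2_CUT,
) -> dict[str, float]:
    """Apply the reliability gate to the printed per-probe maxima.

    Returns the number of quantitative genes, how many of them have printed
    R2 above the cut, the same count among qualitative-only genes, and the
    probe-averaged maximum of the first (highest) gene in the table.
    """
    df = table if table is not None else load_qpcr_validation()
    classes = classify_from_maxima(df, tau=tau)
    by_gene = {c.gene_symbol: c for c in classes}
    quant = df["gene"].map(lambda g: by_gene[g].quantitative)
    return {
        "n_quantitative": int(quant.sum()),
        "n_quantitative_r2_over_cut": int((df.loc[quant, "r2"] > r2_cut).sum()),
        "n_qualitative_r2_over_cut": int((df.loc[~quant, "r2"] > r2_cut).sum()),
        "n_genes": int(len(df)),
        "top_gene_probe_average": float(by_gene[df["gene"].iloc[0]].max_probe_fluorescence),
    }
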