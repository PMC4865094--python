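"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analyses assume, at test
scale: log-normal probe fluorescence (Gaussian on the log2 scale) with

* a per-probe baseline,
* cell-type marker effects and a pan-hematopoietic lineage signature,
* planted fold induction in cytokine-treated samples,
* chip-version batch shifts,
* optional peripheral-blood contamination, mixed in linear space (the
  physics of pooled cells),

plus bead-level summaries whose variance follows a quadratic variance-mean
law, and qPCR crossing points linked (anti-)linearly to log2 expression with
reference genes, two batches and censored missingness.  Every generator
returns machine-readable ground truth so downstream stages can be scored
without re-deriving it, and identical (config, seed) pairs produce
bit-identical outputs.

The default design mirrors a cell-type atlas study shape at test scale:
five non-hematopoietic cell types with paired IFN-gamma samples (fibroblasts
additionally with T-cell-supernatant pairs), four healthy and two malignant
hematopoietic groups -- 200 probes x 40 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import AtlasDataset, ExpressionMatrix, make_probe_annotations, make_sample_annotations

REFERENCE_GENES = ("HMBS", "GAPDH", "ACTB")

#: Genes induced by inflammation in the default design; the first six form
#: the default IFN-response QC panel.
DEFAULT_INDUCIBLE = (
    "GBP2", "IFITM1", "TAP1", "CD74", "PSMB9", "HLA-DRA",
    "IND07", "IND08", "IND09", "IND10", "IND11", "IND12",
)

DEFAULT_MARKERS: dict[str, tuple[str, ...]] = {
    "fibroblast": ("FBLN2", "CD248", "ITGA11", "THY1"),
    "keratinocyte": ("KRT14", "LAMA3", "KLK5", "DSG3"),
    "ptec": ("PAX8", "KCNIP1", "KCNJ16", "FXYD2"),
    "melanocyte": ("MLANA", "SILV", "TYRP1", "TYR"),
    "huvec": ("VWF", "CDH5", "ESM1", "CLEC14A"),
    "b_cell": ("CD19", "MS4A1", "CD79A", "CD79B"),
    "t_cell": ("CD3D", "CD3E", "CD2", "TRAC"),
    "monocyte": ("CD14", "CD33", "LYZ", "ITGAM"),
    "hsc": ("CD34", "KIT", "PROM1", "FLT3"),
    "aml": ("CD33", "MPO", "WT1", "FLT3"),
    "b_all": ("CD19", "CD79B", "PAX5", "EBF1"),
}

#: Pan-hematopoietic signature: high in every hematopoietic sample and in the
#: peripheral-blood profile used for contamination mixtures.
DEFAULT_SIGNATURE = ("PTPRC",) + tuple(f"HEMSIG{i:02d}" for i in range(1, 20))

#: Approximate mononuclear-cell composition of peripheral blood used for the
#: contamination profile.
PBMC_WEIGHTS = {"t_cell": 0.6, "b_cell": 0.15, "monocyte": 0.25}


@dataclass
class CellTypeSpec:
    name: str
    lineage_group: str
    n_samples: int
    n_ifn_pairs: int = 0
    n_tsup_pairs: int = 0

    def __post_init__(self) -> None:
        if max(self.n_ifn_pairs, self.n_tsup_pairs) > self.n_samples:
            raise ValueError(f"{self.name}: more treated pairs than untreated samples")


def default_cell_types() -> list[CellTypeSpec]:
    return [
        CellTypeSpec("fibroblast", "non_hematopoietic", 2, n_ifn_pairs=2, n_tsup_pairs=2),
        CellTypeSpec("keratinocyte", "non_hematopoietic", 2, n_ifn_pairs=2),
        CellTypeSpec("ptec", "non_hematopoietic", 2, n_ifn_pairs=2),
        CellTypeSpec("melanocyte", "non_hematopoietic", 2, n_ifn_pairs=2),
        CellTypeSpec("huvec", "non_hematopoietic", 2, n_ifn_pairs=2),
        CellTypeSpec("b_cell", "healthy_hematopoietic", 3),
        CellTypeSpec("t_cell", "healthy_hematopoietic", 3),
        CellTypeSpec("monocyte", "healthy_hematopoietic", 3),
        CellTypeSpec("hsc", "healthy_hematopoietic", 3),
        CellTypeSpec("aml", "malignant_hematopoietic", 3),
        CellTypeSpec("b_all", "malignant_hematopoietic", 3),
    ]


@dataclass
class SyntheticConfig:
    """Generative parameters; defaults define the study-shaped test conditions."""

    n_probes: int = 200
    cell_types: list[CellTypeSpec] = field(default_factory=default_cell_types)
    markers: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_MARKERS))
    marker_effect: float = 4.0  # log2 units
    signature_genes: tuple[str, ...] = DEFAULT_SIGNATURE
    signature_effect: float = 4.0
    induction_folds: dict[str, float | dict[str, float]] = field(
        default_factory=lambda: {g: 20.0 for g in DEFAULT_INDUCIBLE}
    )
    baseline_mean: float = 6.0  # log2 fluorescence floor
    baseline_sd: float = 0.8  # per-probe baseline spread (filler probes)
    noise_sd: float = 0.4  # residual noise at expressed levels, log2
    noise_floor_sd: float = 0.15  # residual noise at the detection floor
    batch_labels: tuple[str, ...] = ("v3", "v4")
    batch_offsets: tuple[float, ...] = (0.0, 0.3)
    contamination: dict[str, float] = field(default_factory=dict)  # sample_id -> pi
    # bead-summary variance law: sd^2 = c1 + c2*mean + c3*mean^2 (linear
    # scale); c1 is background noise (sd ~20 at the 2^6 fluorescence floor),
    # c3 the squared asymptotic CV (~14%)
    bead_c1: float = 400.0
    bead_c2: float = 1.0
    bead_c3: float = 0.02
    # qPCR link: Cp = qpcr_intercept - qpcr_slope*x + qpcr_quad*x^2 + batch + noise
    qpcr_slope: float = 1.0
    qpcr_intercept: float = 38.0
    qpcr_quad: float = 0.0
    qpcr_noise_sd: float = 0.15
    qpcr_reference_noise_sd: float = 0.05
    qpcr_batch_offsets: tuple[float, ...] = (0.0, 2.0)
    qpcr_replicates: int = 2
    cp_max: float = 40.0  # censoring limit: later cycles read as missing
    reference_level: float = 12.0  # planted log2 expression of reference genes
    seed: int = 0

    def __post_init__(self) -> None:
        for pi in self.contamination.values():
            if not 0.0 <= pi <= 1.0:
                raise ValueError("contamination fractions must lie in [0, 1]")
        if min(self.baseline_sd, self.noise_sd, self.qpcr_noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")

    def gene_fold(self, gene: str, cell_type: str) -> float:
        spec = self.induction_folds.get(gene, 1.0)
        if isinstance(spec, dict):
            return float(spec.get(cell_type, 1.0))
        return float(spec)


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline against the generator."""

    gene_to_probe: dict[str, str]
    signature_probes: list[str]
    marker_probes: dict[str, list[str]]  # cell_type -> probes
    induction: pd.DataFrame  # gene, probe, cell_type, condition, fold
    baseline: pd.Series  # per-probe baseline (log2)
    pbmc_profile: pd.Series  # contamination source profile (log2)
    contamination: dict[str, float]
    config: dict


def _special_genes(config: SyntheticConfig) -> list[str]:
    ordered: list[str] = []
    for g in config.signature_genes:
        ordered.append(g)
    for ct in config.markers.values():
        ordered.extend(ct)
    ordered.extend(config.induction_folds.keys())
    ordered.extend(REFERENCE_GENES)
    seen: set[str] = set()
    unique = [g for g in ordered if not (g in seen or seen.add(g))]
    return unique


def _probe_universe(config: SyntheticConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    special = _special_genes(config)
    if len(special) > config.n_probes:
        raise ValueError(
            f"probe universe ({config.n_probes}) smaller than the "
            f"{len(special)} marker/signature/inducible/reference genes"
        )
    genes = special + [f"GENE{i:04d}" for i in range(1, config.n_probes - len(special) + 1)]
    probe_ids = [f"SIM_{i:04d}" for i in range(1, config.n_probes + 1)]
    versions = ",".join(config.batch_labels)
    probes = make_probe_annotations(pd.DataFrame({
        "probe_id": probe_ids,
        "gene_symbol": genes,
        "present_on_versions": versions,
    }))
    return probes, dict(zip(genes, probe_ids))


def _sample_plan(config: SyntheticConfig) -> pd.DataFrame:
    records = []
    for spec in config.cell_types:
        for i in range(1, spec.n_samples + 1):
            records.append({
                "sample_id": f"{spec.name}_{i:02d}", "cell_type": spec.name,
                "lineage_group": spec.lineage_group, "treatment": "none",
                "paired_sample_id": None,
            })
        for i in range(1, spec.n_ifn_pairs + 1):
            records.append({
                "sample_id": f"{spec.name}_{i:02d}_ifn", "cell_type": spec.name,
                "lineage_group": spec.lineage_group, "treatment": "ifn_gamma",
                "paired_sample_id": f"{spec.name}_{i:02d}",
            })
        for i in range(1, spec.n_tsup_pairs + 1):
            records.append({
                "sample_id": f"{spec.name}_{i:02d}_tsup", "cell_type": spec.name,
                "lineage_group": spec.lineage_group, "treatment": "t_cell_supernatant",
                "paired_sample_id": f"{spec.name}_{i:02d}",
            })
    df = pd.DataFrame(records)
    df["batch"] = [config.batch_labels[i % len(config.batch_labels)] for i in range(len(df))]
    return make_sample_annotations(df)


def _expected_log2(
    config: SyntheticConfig,
    baseline: pd.Series,
    gene_to_probe: dict[str, str],
    cell_type: str,
    treatment: str,
) -> pd.Series:
    """Noise- and batch-free expected profile of one sample."""
    x = baseline.copy()
    lineages = {spec.name: spec.lineage_group for spec in config.cell_types}
    if lineages.get(cell_type, "non_hematopoietic") != "non_hematopoietic":
        for g in config.signature_genes:
            x[gene_to_probe[g]] += config.signature_effect
    for g in config.markers.get(cell_type, ()):
        x[gene_to_probe[g]] += config.marker_effect
    if treatment != "none":
        for g in config.induction_folds:
            x[gene_to_probe[g]] += np.log2(config.gene_fold(g, cell_type))
    return x


def _pbmc_profile(
    config: SyntheticConfig, baseline: pd.Series, gene_to_probe: dict[str, str]
) -> pd.Series:
    """Idealized peripheral-blood profile: linear mixture of blood cell types."""
    linear = None
    for ct, w in PBMC_WEIGHTS.items():
        x = baseline.copy()
        for g in config.signature_genes:
            x[gene_to_probe[g]] += config.signature_effect
        for g in config.markers.get(ct, ()):
            x[gene_to_probe[g]] += config.marker_effect
        contrib = w * np.exp2(x)
        linear = contrib if linear is None else linear + contrib
    return np.log2(linear)


def contaminate(values_log2: pd.Series, pbmc_log2: pd.Series, pi: float) -> pd.Series:
    """Mix a sample with the blood profile in linear space at fraction pi."""
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    return np.log2((1.0 - pi) * np.exp2(values_log2) + pi * np.exp2(pbmc_log2))


def generate_atlas(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[AtlasDataset, GroundTruth]:
    """Generate a transformed-scale atlas plus ground truth.

    log2 value = baseline + marker/signature effects + induction (treated
    samples) + batch offset + N(0, noise_sd); contamination is applied as a
    linear-space mixture with the generated blood profile.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    probes, gene_to_probe = _probe_universe(config)
    samples = _sample_plan(config)
    for sid in config.contamination:
        if sid not in samples.index:
            raise ValueError(f"contamination names unknown sample {sid!r}")
    baseline = pd.Series(
        config.baseline_mean + config.baseline_sd * rng.standard_normal(config.n_probes),
        index=probes.index,
    )
    # Marker, signature and inducible genes are the ones panels and screens
    # key on; in practice such genes are chosen for clean off-states, so
    # their baseline is pinned at the detection floor rather than drawn from
    # the filler-probe spread.
    for g in _special_genes(config):
        baseline[gene_to_probe[g]] = config.baseline_mean
    # reference genes are stably expressed by construction
    for g in REFERENCE_GENES:
        baseline[gene_to_probe[g]] = config.reference_level
    offsets = dict(zip(config.batch_labels, config.batch_offsets))
    pbmc = _pbmc_profile(config, baseline, gene_to_probe)
    columns = {}
    for sid, row in samples.iterrows():
        x = _expected_log2(config, baseline, gene_to_probe, row["cell_type"], row["treatment"])
        # the VST compresses technical variance at the detection floor, so
        # probes sitting at background get the smaller noise term
        at_floor = x <= config.baseline_mean + 0.5
        sd = np.where(at_floor, config.noise_floor_sd, config.noise_sd)
        x = x + offsets[row["batch"]]
        x = x + sd * rng.standard_normal(config.n_probes)
        pi = config.contamination.get(sid, 0.0)
        if pi > 0:
            x = contaminate(x, pbmc, pi)
        columns[sid] = x
    matrix = ExpressionMatrix(pd.DataFrame(columns, index=probes.index), scale="transformed")
    induction_rows = []
    treatable = [
        (spec.name, cond)
        for spec in config.cell_types
        for cond, n in (("ifn_gamma", spec.n_ifn_pairs), ("t_cell_supernatant", spec.n_tsup_pairs))
        if n > 0
    ]
    for gene in config.induction_folds:
        for ct, cond in treatable:
            induction_rows.append({
                "gene": gene, "probe_id": gene_to_probe[gene], "cell_type": ct,
                "condition": cond, "fold": config.gene_fold(gene, ct),
            })
    truth = GroundTruth(
        gene_to_probe=gene_to_probe,
        signature_probes=[gene_to_probe[g] for g in config.signature_genes],
        marker_probes={
            ct: [gene_to_probe[g] for g in genes] for ct, genes in config.markers.items()
        },
        induction=pd.DataFrame(induction_rows),
        baseline=baseline,
        pbmc_profile=pbmc,
        contamination=dict(config.contamination),
        config=asdict(config),
    )
    return AtlasDataset(matrix, samples, probes), truth


def generate_bead_summaries(
    config: SyntheticConfig,
    matrix_linear: ExpressionMatrix,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bead-level summaries consistent with sd^2 = c1 + c2*mean + c3*mean^2.

    The reported sd is a sample standard deviation over n_beads beads, so
    sd^2 is drawn from the scaled chi-square law of a variance estimate.
    n_beads ~ 15 + Poisson(15), clipped at 1.
    """
    if matrix_linear.scale != "linear":
        raise ValueError("bead summaries are generated from a linear-scale matrix")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    means = matrix_linear.data.to_numpy().ravel(order="F")
    n_probes, n_samples = matrix_linear.shape
    n_beads = np.maximum(1, 15 + rng.poisson(15.0, size=means.size))
    true_var = config.bead_c1 + config.bead_c2 * means + config.bead_c3 * means**2
    dof = np.maximum(n_beads - 1, 1)
    sd = np.sqrt(true_var * rng.chisquare(dof) / dof)
    return pd.DataFrame({
        "probe_id": np.tile(matrix_linear.data.index, n_samples),
        "sample_id": np.repeat(matrix_linear.data.columns, n_probes),
        "mean": means,
        "sd": sd,
        "n_beads": n_beads,
    })


def generate_qpcr(
    config: SyntheticConfig,
    matrix: ExpressionMatrix,
    gene_probe_map: dict[str, list[str]],
    genes: list[str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """qPCR table linked to the matrix: Cp = b - a*x + q*x^2 + batch + noise.

    ``x`` is the probe-averaged transformed signal for target genes; the
    reference genes are stably expressed by construction, so their Cp comes
    from the planted ``reference_level`` with their own (small) noise.  Cp
    above ``cp_max`` is censored to missing.  Samples are split over two
    batches alternately.
    """
    if matrix.scale != "transformed":
        raise ValueError("qPCR generation expects a transformed-scale matrix")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if genes is None:
        genes = [g for g in gene_probe_map if g not in REFERENCE_GENES]
    for g in REFERENCE_GENES:
        if g not in gene_probe_map:
            raise ValueError(f"reference gene {g} missing from gene_probe_map")
    all_genes = list(genes) + list(REFERENCE_GENES)
    sample_ids = list(matrix.sample_ids)
    batches = {
        s: f"qbatch{(i % len(config.qpcr_batch_offsets)) + 1}" for i, s in enumerate(sample_ids)
    }
    offsets = {
        f"qbatch{i + 1}": off for i, off in enumerate(config.qpcr_batch_offsets)
    }
    rows = []
    for gene in all_genes:
        is_ref = gene in REFERENCE_GENES
        if is_ref:
            signal = pd.Series(config.reference_level, index=sample_ids)
        else:
            probes = [p for p in gene_probe_map[gene] if p in matrix.data.index]
            if not probes:
                raise ValueError(f"gene {gene!r} resolves to no probe")
            signal = matrix.data.loc[probes].mean(axis=0)
        noise_sd = config.qpcr_reference_noise_sd if is_ref else config.qpcr_noise_sd
        for s in sample_ids:
            x = float(signal[s])
            base = (
                config.qpcr_intercept - config.qpcr_slope * x + config.qpcr_quad * x**2
                + offsets[batches[s]]
            )
            for rep in range(1, config.qpcr_replicates + 1):
                cp = base + noise_sd * rng.standard_normal()
                rows.append({
                    "gene": gene, "sample_id": s, "batch": batches[s],
                    "replicate": rep,
                    "cp": np.nan if cp > config.cp_max else cp,
                })
    out = pd.DataFrame(rows)
    out["is_missing"] = out["cp"].isna()
    return out
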