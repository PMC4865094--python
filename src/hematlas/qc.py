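"""Sample-identity QC: marker panels, contamination checks, response checks,
and unsupervised clustering validation.

A marker panel names genes expected above the detection threshold in a given
cell type (``expected_high``) and genes expected below it (``expected_low``).
A sample passes when at least ``min_fraction_high`` of the high genes are
detected and at most ``max_fraction_low`` of the low genes are.  The same
verdict structure drives peripheral-blood contamination detection (a panel of
pan-hematopoietic genes that must all stay below threshold in
non-hematopoietic samples) and the inflammation-response check on
IFN-gamma-treated samples (panel genes must be fold-induced versus the
paired untreated sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AtlasDataset

logger = logging.getLogger("hematlas")

#: Default detection threshold on the transformed (log2-like) scale.  The
#: observed fluorescence floor in bead-array atlases is ~5.6; 7.0 adds margin
#: so baseline noise never counts as detection.
DETECTION_THRESHOLD = 7.0


@dataclass
class MarkerPanel:
    name: str
    expected_high: tuple[str, ...] = ()
    expected_low: tuple[str, ...] = ()
    detection_threshold: float = DETECTION_THRESHOLD
    min_fraction_high: float = 0.75
    max_fraction_low: float = 0.0

    def __post_init__(self) -> None:
        overlap = set(self.expected_high) & set(self.expected_low)
        if overlap:
            raise ValueError(f"genes in both expected_high and expected_low: {sorted(overlap)}")
        for p in (self.min_fraction_high, self.max_fraction_low):
            if not 0.0 <= p <= 1.0:
                raise ValueError("panel fractions must lie in [0, 1]")


@dataclass
class QcVerdict:
    sample_id: str
    panel_name: str
    passed: bool
    fraction_high_detected: float
    fraction_low_detected: float
    reason: str = ""


#: Cell-type marker panels used to confirm sample origin.  The macrophage
#: polarization panel is a plausible default only; it is not anchored to a
#: published marker list the way the others are.
DEFAULT_PANELS: dict[str, MarkerPanel] = {
    "hepatocyte": MarkerPanel("hepatocyte", ("APOA2", "ORM1", "FGA", "ALB")),
    "melanocyte": MarkerPanel("melanocyte", ("MLANA", "SILV", "TYRP1", "TYR")),
    "fibroblast": MarkerPanel("fibroblast", ("FBLN2", "CD248", "ITGA11", "THY1")),
    "keratinocyte": MarkerPanel("keratinocyte", ("KRT14", "LAMA3", "KLK5", "DSG3")),
    "ptec": MarkerPanel("ptec", ("PAX8", "KCNIP1", "KCNJ16", "FXYD2")),
    "huvec": MarkerPanel("huvec", ("VWF", "CDH5", "ESM1", "CLEC14A")),
    "dendritic_cell": MarkerPanel(
        "dendritic_cell", ("CD86", "CD209", "CCL22"), expected_low=("CD14",)
    ),
    "dc_maturation": MarkerPanel(
        "dc_maturation",
        ("LAMP3", "HLA-DOB", "FLT3", "CD80", "CD83", "HLA-DQA1"),
        expected_low=("CCL13", "CD36"),
    ),
    "macrophage": MarkerPanel("macrophage", ("MMP9", "SPP1", "CCL2", "CD163")),
    "hematopoietic_contamination": MarkerPanel(
        "hematopoietic_contamination",
        expected_low=("PTPRC", "CD14", "CD19", "CD3D"),
        min_fraction_high=0.0,
        max_fraction_low=0.0,
    ),
    "ifn_response": MarkerPanel(
        "ifn_response", ("GBP2", "IFITM1", "TAP1", "CD74", "PSMB9", "HLA-DRA")
    ),
}


def _gene_detection(dataset: AtlasDataset, genes: tuple[str, ...], sample_id: str,
                    threshold: float) -> dict[str, bool]:
    """Per-gene detection: max probe value in the sample strictly above threshold."""
    column = dataset.matrix.data[sample_id]
    detected: dict[str, bool] = {}
    for gene in genes:
        probes = dataset.probes_for_gene(gene)
        if not probes:
            logger.warning("panel gene %s has no probe in the matrix; skipped", gene)
            continue
        detected[gene] = bool(column.loc[probes].max() > threshold)
    return detected


def evaluate_marker_panel(dataset: AtlasDataset, panel: MarkerPanel, sample_id: str) -> QcVerdict:
    """Score one sample against a marker panel.

    Fractions are computed over the genes that resolve to at least one probe;
    an empty (or fully unresolvable) side of the panel is neutral.
    """
    if sample_id not in dataset.samples.index:
        raise KeyError(f"unknown sample {sample_id!r}")
    high = _gene_detection(dataset, panel.expected_high, sample_id, panel.detection_threshold)
    low = _gene_detection(dataset, panel.expected_low, sample_id, panel.detection_threshold)
    if not high and not low:
        raise ValueError(f"no gene of panel {panel.name!r} resolves to a probe")
    frac_high = float(np.mean(list(high.values()))) if high else 1.0
    frac_low = float(np.mean(list(low.values()))) if low else 0.0
    passed = frac_high >= panel.min_fraction_high and frac_low <= panel.max_fraction_low
    reason = "" if passed else (
        f"high {frac_high:.2f} < {panel.min_fraction_high}" if frac_high < panel.min_fraction_high
        else f"low {frac_low:.2f} > {panel.max_fraction_low}"
    )
    return QcVerdict(sample_id, panel.name, passed, frac_high, frac_low, reason)


def detect_contamination(
    dataset: AtlasDataset,
    sample_id: str,
    hematopoietic_panel: MarkerPanel | None = None,
) -> QcVerdict:
    """Flag peripheral-blood contamination of a non-hematopoietic sample.

    Passes iff every pan-hematopoietic marker gene stays below the detection
    threshold.
    """
    panel = hematopoietic_panel or DEFAULT_PANELS["hematopoietic_contamination"]
    lineage = dataset.samples.loc[sample_id, "lineage_group"]
    if lineage != "non_hematopoietic":
        raise ValueError(f"sample {sample_id!r} is {lineage}, not non_hematopoietic")
    verdict = evaluate_marker_panel(dataset, panel, sample_id)
    if not verdict.passed:
        verdict.reason = "hematopoietic marker detected: possible blood contamination"
    return verdict


def check_ifn_response(
    dataset: AtlasDataset,
    treated_sample_id: str,
    response_panel: MarkerPanel | None = None,
    response_fold: float = 2.0,
) -> QcVerdict:
    """Check that a treated sample induced the inflammation response panel.

    A panel gene responds when its best probe shows a per-sample fold
    increase (2 ** (treated - untreated)) of at least ``response_fold`` over
    the paired untreated sample.  Passes when at least ``min_fraction_high``
    of resolvable panel genes respond.
    """
    panel = response_panel or DEFAULT_PANELS["ifn_response"]
    row = dataset.samples.loc[treated_sample_id]
    if row["treatment"] == "none":
        raise ValueError(f"sample {treated_sample_id!r} is untreated")
    pair = row["paired_sample_id"]
    if pair is None or pair not in dataset.samples.index:
        raise ValueError(f"treated sample {treated_sample_id!r} has no resolvable pair")
    treated = dataset.matrix.data[treated_sample_id]
    untreated = dataset.matrix.data[pair]
    responding: list[bool] = []
    for gene in panel.expected_high:
        probes = dataset.probes_for_gene(gene)
        if not probes:
            logger.warning("response gene %s has no probe; skipped", gene)
            continue
        fc = np.exp2((treated.loc[probes] - untreated.loc[probes]).max())
        responding.append(bool(fc >= response_fold))
    if not responding:
        raise ValueError(f"no gene of panel {panel.name!r} resolves to a probe")
    frac = float(np.mean(responding))
    passed = frac >= panel.min_fraction_high
    reason = "" if passed else f"only {frac:.2f} of response genes induced >= {response_fold}-fold"
    return QcVerdict(treated_sample_id, panel.name, passed, frac, 0.0, reason)


@dataclass
class SampleDendrogram:
    """Average-linkage dendrogram over samples (scipy linkage convention)."""

    linkage: np.ndarray  # (n-1, 4)
    labels: list[str]
    distances: pd.DataFrame = field(repr=False, default=None)

    def cut(self, n_clusters: int) -> dict[str, int]:
        from scipy.cluster.hierarchy import fcluster

        assignment = fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, assignment.tolist()))

    def to_newick(self) -> str:
        from scipy.cluster.hierarchy import to_tree

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            length_l = node.dist - node.left.dist
            length_r = node.dist - node.right.dist
            return (
                f"({render(node.left)}:{length_l:.6g},"
                f"{render(node.right)}:{length_r:.6g})"
            )

        return render(to_tree(self.linkage)) + ";"


def correlation_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between sample columns; errors on constant samples."""
    stds = matrix.std(axis=0, ddof=0)
    constant = stds.index[stds == 0]
    if len(constant):
        raise ValueError(f"constant sample vector, correlation undefined: {constant[0]!r}")
    return 1.0 - matrix.corr(method="pearson")


def top_variable_probes(matrix: pd.DataFrame, top_n: int) -> pd.DataFrame:
    """Deterministic selection of the top_n most variable probes."""
    variances = matrix.var(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda p: (-variances[p], p))
    return matrix.loc[order[: min(top_n, len(order))]]


def average_linkage(distances: pd.DataFrame) -> np.ndarray:
    """Deterministic UPGMA agglomeration returning a scipy-style linkage matrix.

    Average linkage on the original pairwise distances; among merge
    candidates at equal distance the lexicographically smallest pair of
    cluster label sets wins, so the output is independent of input order.
    """
    labels = list(distances.index)
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 samples to cluster")
    d = distances.to_numpy(dtype=float)
    # cluster id -> (member point indices, sorted member labels)
    clusters: dict[int, tuple[list[int], tuple[str, ...]]] = {
        i: ([i], (labels[i],)) for i in range(n)
    }
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best: tuple[float, tuple[str, ...], tuple[str, ...], int, int] | None = None
        ids = sorted(clusters)
        for ii, a in enumerate(ids):
            for b in ids[ii + 1:]:
                ma, la = clusters[a]
                mb, lb = clusters[b]
                dist = d[np.ix_(ma, mb)].mean()
                key_a, key_b = sorted((la, lb))
                cand = (dist, key_a, key_b, min(a, b), max(a, b))
                if best is None or cand < best:
                    best = cand
        dist, _, _, a, b = best
        ma, la = clusters.pop(a)
        mb, lb = clusters.pop(b)
        clusters[next_id] = (ma + mb, tuple(sorted(la + lb)))
        merges[step] = (a, b, dist, len(ma) + len(mb))
        next_id += 1
    return merges


def cluster_samples(
    dataset: AtlasDataset, top_n_probes: int = 500
) -> SampleDendrogram:
    """Average-linkage clustering of samples on correlation distance.

    Uses the ``top_n_probes`` most variable probes (all probes when fewer).
    Deterministic given the stated tie-breaking.
    """
    if dataset.matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples for clustering validation")
    sub = top_variable_probes(dataset.matrix.data, top_n_probes)
    distances = correlation_distances(sub)
    linkage = average_linkage(distances)
    return SampleDendrogram(linkage, list(distances.index), distances)


def qc_report(
    dataset: AtlasDataset,
    panels_by_cell_type: dict[str, MarkerPanel] | None = None,
    response_fold: float = 2.0,
) -> pd.DataFrame:
    """Run all applicable checks per sample; returns a tidy verdict table."""
    panels = panels_by_cell_type if panels_by_cell_type is not None else DEFAULT_PANELS
    verdicts: list[QcVerdict] = []
    for sid, row in dataset.samples.iterrows():
        if row["treatment"] == "none" and row["cell_type"] in panels:
            verdicts.append(evaluate_marker_panel(dataset, panels[row["cell_type"]], sid))
        if row["treatment"] == "none" and row["lineage_group"] == "non_hematopoietic":
            verdicts.append(detect_contamination(dataset, sid))
        if row["treatment"] != "none":
            verdicts.append(check_ifn_response(dataset, sid, response_fold=response_fold))
    return pd.DataFrame([vars(v) for v in verdicts])
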