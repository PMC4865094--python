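"""Cp correction, imputation, quadratic fits, reliability gate."""

import numpy as np
import pandas as pd
import pytest

from hematlas import (
    ReferenceCorrection,
    SyntheticConfig,
    classify_from_maxima,
    classify_reliability,
    correct_cp,
    fit_quadratic_model,
    generate_atlas,
    generate_qpcr,
    impute_missing_cp,
)
from hematlas.published import load_qpcr_validation, reliability_counts
from .conftest import make_matrix


def qpcr_frame(rows):
    df = pd.DataFrame(rows, columns=["gene", "sample_id", "batch", "replicate", "cp"])
    df["is_missing"] = df["cp"].isna()
    return df


def refs_for(sample, batch, values=(20.0, 21.0, 22.0)):
    return [
        ("HMBS", sample, batch, 1, values[0]),
        ("GAPDH", sample, batch, 1, values[1]),
        ("ACTB", sample, batch, 1, values[2]),
    ]


class TestCorrectCp:
    def test_equal_weights_arithmetic(self):
        q = qpcr_frame([("G", "s1", "b1", 1, 25.0)] + refs_for("s1", "b1"))
        out = correct_cp(q)
        assert out.loc[out["gene"] == "G", "cp_corrected"].iloc[0] == pytest.approx(4.0)

    def test_degenerate_weights_subtract_first_reference(self):
        q = qpcr_frame([("G", "s1", "b1", 1, 25.0)] + refs_for("s1", "b1"))
        corr = ReferenceCorrection(weights=(1.0, 0.0, 0.0))
        out = correct_cp(q, corr)
        assert out["cp_corrected"].iloc[0] == pytest.approx(5.0)

    def test_batch_offset_cancels_exactly(self):
        # same biology measured in two batches, +2 cycles on everything in b2
        rows = [("G", "s1", "b1", 1, 25.0)] + refs_for("s1", "b1")
        rows += [("G", "s2", "b2", 1, 27.0)] + refs_for("s2", "b2", (22.0, 23.0, 24.0))
        out = correct_cp(qpcr_frame(rows))
        vals = out.set_index("sample_id")["cp_corrected"]
        assert vals["s1"] == pytest.approx(vals["s2"])

    def test_per_sample_additive_shift_invariance(self):
        rows = [("G", "s1", "b1", 1, 25.0)] + refs_for("s1", "b1")
        base = correct_cp(qpcr_frame(rows))["cp_corrected"].iloc[0]
        shifted_rows = [(g, s, b, r, cp + 3.7) for g, s, b, r, cp in rows]
        shifted = correct_cp(qpcr_frame(shifted_rows))["cp_corrected"].iloc[0]
        assert shifted == pytest.approx(base)

    def test_replicates_averaged_before_correction(self):
        rows = [("G", "s1", "b1", 1, 24.0), ("G", "s1", "b1", 2, 26.0)] + refs_for("s1", "b1")
        out = correct_cp(qpcr_frame(rows))
        assert len(out[out["gene"] == "G"]) == 1
        assert out.loc[out["gene"] == "G", "cp_corrected"].iloc[0] == pytest.approx(4.0)

    def test_missing_reference_errors_with_sample_and_batch(self):
        rows = [("G", "s1", "b1", 1, 25.0), ("HMBS", "s1", "b1", 1, 20.0)]
        with pytest.raises(ValueError, match="s1.*b1"):
            correct_cp(qpcr_frame(rows))

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ReferenceCorrection(weights=(0.5, 0.2, 0.2))


class TestImputation:
    def test_censor_max_adds_one_cycle(self):
        q = qpcr_frame([
            ("G", "s1", "b1", 1, 30.0), ("G", "s2", "b1", 1, 32.0),
            ("G", "s3", "b1", 1, np.nan),
        ])
        out = impute_missing_cp(q)
        assert out.loc[out["sample_id"] == "s3", "cp"].iloc[0] == pytest.approx(33.0)
        assert out.loc[out["sample_id"] == "s3", "imputed"].iloc[0]

    def test_no_missing_leaves_table_unchanged(self):
        q = qpcr_frame([("G", "s1", "b1", 1, 30.0)])
        out = impute_missing_cp(q)
        assert not out["imputed"].any()
        assert out["cp"].iloc[0] == 30.0

    def test_batch_gene_mean_policy(self):
        q = qpcr_frame([
            ("G", "s1", "b1", 1, 30.0), ("G", "s2", "b1", 1, 34.0),
            ("G", "s3", "b1", 1, np.nan),
        ])
        out = impute_missing_cp(q, policy="batch_gene_mean")
        assert out.loc[out["sample_id"] == "s3", "cp"].iloc[0] == pytest.approx(32.0)

    def test_all_missing_gene_batch_errors(self):
        q = qpcr_frame([("G", "s1", "b1", 1, np.nan)])
        with pytest.raises(ValueError, match="no observed"):
            impute_missing_cp(q)


class TestQuadraticFit:
    def test_exact_quadratic_zero_noise_r2_one(self):
        rng = np.random.default_rng(7)
        cp = rng.uniform(-2, 8, 30)
        y = 14.0 - 1.2 * cp + 0.05 * cp**2
        matrix = make_matrix(y[None, :], probes=["pG"], samples=[f"s{i}" for i in range(30)])
        corrected = pd.DataFrame({
            "gene": "G", "sample_id": [f"s{i}" for i in range(30)],
            "batch": "b1", "cp_corrected": cp,
        })
        fit = fit_quadratic_model(corrected, matrix, {"G": ["pG"]})
        assert fit.per_gene["r2"].iloc[0] == pytest.approx(1.0)
        assert fit.per_gene["b1"].iloc[0] == pytest.approx(-1.2)

    def test_pure_noise_r2_below_point_one(self):
        rng = np.random.default_rng(42)
        n = 200
        cp = rng.uniform(0, 10, n)
        y = rng.normal(8, 1, n)  # independent of Cp
        matrix = make_matrix(y[None, :], probes=["pG"], samples=[f"s{i}" for i in range(n)])
        corrected = pd.DataFrame({
            "gene": "G", "sample_id": [f"s{i}" for i in range(n)],
            "batch": "b1", "cp_corrected": cp,
        })
        fit = fit_quadratic_model(corrected, matrix, {"G": ["pG"]})
        assert fit.per_gene["r2"].iloc[0] < 0.1

    def test_linear_submodel_never_beats_quadratic(self):
        # nesting: residuals of the constrained (b2 = 0) fit >= full fit
        rng = np.random.default_rng(3)
        n = 50
        cp = rng.uniform(-3, 7, n)
        y = 12 - cp + 0.2 * cp**2 + rng.normal(0, 0.5, n)
        full = np.column_stack([np.ones(n), cp, cp**2])
        lin = full[:, :2]
        for design in (full, lin):
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        r2 = []
        for design in (full, lin):
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            res = y - design @ beta
            r2.append(1 - res @ res / ((y - y.mean()) ** 2).sum())
        assert r2[0] >= r2[1]

    def test_noise_ranking_recovered_on_synthetic_panel(self, atlas, default_config):
        """Genes generated with high qPCR noise rank below low-noise genes."""
        dataset, truth = atlas
        gene_map = {g: [p] for g, p in truth.gene_to_probe.items()}
        genes = sorted(set().union(*map(set, default_config.markers.values())))[:12]
        quiet = SyntheticConfig(qpcr_noise_sd=0.05)
        loud = SyntheticConfig(qpcr_noise_sd=2.0)
        q_lo = generate_qpcr(quiet, dataset.matrix, gene_map, genes=genes[:6], seed=5)
        q_hi = generate_qpcr(loud, dataset.matrix, gene_map, genes=genes[6:], seed=5)
        qpcr = pd.concat([q_lo, q_hi[q_hi["gene"].isin(genes[6:])]], ignore_index=True)
        corrected = correct_cp(impute_missing_cp(qpcr))
        fit = fit_quadratic_model(corrected, dataset.matrix, {g: gene_map[g] for g in genes})
        r2 = fit.per_gene.set_index("gene")["r2"]
        assert r2[genes[:6]].min() > r2[genes[6:]].max()

    def test_adjusted_r2_never_exceeds_r2(self, atlas, default_config):
        dataset, truth = atlas
        gene_map = {g: [p] for g, p in truth.gene_to_probe.items()}
        genes = sorted(default_config.induction_folds)[:8]
        qpcr = generate_qpcr(default_config, dataset.matrix, gene_map, genes=genes, seed=9)
        fit = fit_quadratic_model(
            correct_cp(impute_missing_cp(qpcr)), dataset.matrix,
            {g: gene_map[g] for g in genes},
        )
        assert fit.pooled_adjusted_r2 <= fit.pooled_r2

    def test_censoring_degrades_gracefully(self, atlas, default_config):
        """A known link survives mild detection censoring: R2 > 0.9 when
        under 10% of a low-expression gene's wells are censored."""
        dataset, truth = atlas
        gene_map = {g: [p] for g, p in truth.gene_to_probe.items()}
        gene = "GENE0001"  # filler probe near the floor -> high Cp
        uncensored = generate_qpcr(
            SyntheticConfig(qpcr_noise_sd=0.1, cp_max=np.inf),
            dataset.matrix, gene_map, genes=[gene], seed=13,
        )
        cp_max = float(uncensored.loc[uncensored["gene"] == gene, "cp"].quantile(0.92))
        cfg = SyntheticConfig(qpcr_noise_sd=0.1, cp_max=cp_max)
        qpcr = generate_qpcr(cfg, dataset.matrix, gene_map, genes=[gene], seed=13)
        frac_missing = qpcr.loc[qpcr["gene"] == gene, "is_missing"].mean()
        assert 0.0 < frac_missing < 0.10
        fit = fit_quadratic_model(
            correct_cp(impute_missing_cp(qpcr)), dataset.matrix, {gene: gene_map[gene]}
        )
        assert fit.per_gene["r2"].iloc[0] > 0.9


class TestReliabilityGate:
    def test_two_probe_average_from_printed_maxima(self):
        classes = classify_from_maxima({"HLA-DRA": [15.03, 14.61]})
        assert classes[0].max_probe_fluorescence == pytest.approx(14.82)
        assert classes[0].quantitative

    def test_low_fluorescence_gene_is_qualitative_only(self):
        classes = classify_from_maxima({"HMHA1": [10.11]})
        assert not classes[0].quantitative

    def test_boundary_is_strict(self):
        at_tau, above = classify_from_maxima({"X": [11.0], "Y": [11.0 + 1e-9]})
        assert not at_tau.quantitative and above.quantitative

    def test_printed_validation_counts(self):
        counts = reliability_counts()
        assert counts["n_quantitative"] == 11
        assert counts["n_quantitative_r2_over_cut"] == 11
        assert counts["n_qualitative_r2_over_cut"] == 3
        assert counts["top_gene_probe_average"] == pytest.approx(14.82)

    def test_matrix_classification_matches_probe_average_rule(self):
        m = make_matrix([[12.0, 9.0], [10.0, 8.0]], probes=["p1", "p2"], samples=["s1", "s2"])
        cls = classify_reliability(m, {"G": ["p1", "p2"]})
        # probe-averaged signal: (12+10)/2 = 11 at s1 -> not strictly above tau
        assert cls[0].max_probe_fluorescence == pytest.approx(11.0)
        assert not cls[0].quantitative

    def test_unresolvable_gene_errors(self):
        m = make_matrix([[12.0]], probes=["p1"], samples=["s1"])
        with pytest.raises(KeyError, match="GHOST"):
            classify_reliability(m, {"GHOST": ["nope"]})


def test_printed_validation_table_shape():
    df = load_qpcr_validation()
    assert len(df) == 24
    assert df["gene"].is_unique
    assert df["r2"].between(-0.01, 1.0).all()
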