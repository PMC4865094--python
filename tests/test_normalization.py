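"""VST and quantile normalization: oracles, limits, invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hematlas import (
    ExpressionMatrix,
    SyntheticConfig,
    VarianceModel,
    fit_variance_function,
    generate_bead_summaries,
    normalize,
    quantile_normalize,
    vst_transform,
)
from hematlas.normalization import vst_values
from .conftest import make_matrix


def brute_force_quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Independent oracle: explicit rank-average construction, no ties."""
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="ordinal").astype(int) - 1
        out[:, j] = reference[ranks]
    return out


class TestQuantileNormalize:
    def test_hand_computed_two_columns(self):
        m = make_matrix([[1, 4], [2, 5], [3, 6]])
        result = quantile_normalize(m).data.to_numpy()
        np.testing.assert_allclose(result, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_identical_distributions_are_fixed_point(self):
        m = make_matrix([[1, 3], [2, 1], [3, 2]])  # same values, permuted
        np.testing.assert_allclose(quantile_normalize(m).data, m.data)

    def test_exhaustive_3x2_instances_match_oracle(self):
        # every arrangement of the distinct integers 1..6 in a 3x2 matrix
        base = np.arange(1.0, 7.0)
        for perm in itertools.permutations(range(6)):
            values = base[list(perm)].reshape((3, 2), order="F")
            got = quantile_normalize(make_matrix(values)).data.to_numpy()
            np.testing.assert_allclose(got, brute_force_quantile_normalize(values))

    def test_exhaustive_4x3_column_orderings_match_oracle(self):
        # quantile normalization depends on values only through within-column
        # order, so enumerating all (4!)^3 column orderings of a fixed
        # distinct-entry fill is exhaustive for the 4x3 case
        cols = [np.array([1.0, 2, 3, 4]), np.array([5.0, 6, 7, 8]), np.array([9.0, 10, 11, 12])]
        perms = list(itertools.permutations(range(4)))
        for pa in perms:
            for pb in perms:
                for pc in perms:
                    values = np.column_stack([cols[0][list(pa)], cols[1][list(pb)], cols[2][list(pc)]])
                    got = quantile_normalize(make_matrix(values)).data.to_numpy()
                    np.testing.assert_allclose(got, brute_force_quantile_normalize(values))

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(8, 2, (50, 5)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-9)

    def test_ties_get_mean_of_spanned_order_statistics(self):
        m = make_matrix([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        got = quantile_normalize(m).data.to_numpy()
        ref = np.sort(m.data.to_numpy(), axis=0).mean(axis=1)  # (5.5, 10.5, 17.5)
        np.testing.assert_allclose(got[:, 0], [(ref[0] + ref[1]) / 2] * 2 + [ref[2]])
        np.testing.assert_allclose(got[:, 1], ref)

    def test_all_identical_column_handled_not_error(self):
        m = make_matrix([[1.0, 1.0], [1.0, 2.0], [1.0, 3.0]])
        got = quantile_normalize(m).data.to_numpy()
        assert np.isfinite(got).all()
        assert np.allclose(got[:, 0], got[:, 0].mean())  # ties averaged

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_column_means_equal_after_normalization(self, seed):
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.normal(0, 3, (20, 4)))
        means = quantile_normalize(m).data.mean(axis=0).to_numpy()
        assert np.ptp(means) < 1e-9

    def test_within_column_ranks_preserved(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(30, 3))
        got = quantile_normalize(make_matrix(values)).data.to_numpy()
        for j in range(3):
            assert (np.argsort(got[:, j]) == np.argsort(values[:, j])).all()


class TestVarianceFit:
    def test_recovers_planted_quadratic_within_10_percent(self):
        rng = np.random.default_rng(11)
        n = 10_000
        means = np.exp(rng.uniform(np.log(10), np.log(10_000), n))
        true_var = 4 + 0.1 * means + 0.0004 * means**2
        dof = 29
        sd = np.sqrt(true_var * rng.chisquare(dof, n) / dof)
        model = fit_variance_function(pd.DataFrame({"mean": means, "sd": sd}))
        assert model.c1 == pytest.approx(4.0, rel=0.10)
        assert model.c2 == pytest.approx(0.1, rel=0.10)
        assert model.c3 == pytest.approx(0.0004, rel=0.10)

    def test_pure_additive_noise_pins_c3_at_zero(self):
        rng = np.random.default_rng(3)
        means = rng.uniform(10, 1000, 500)
        sd = np.full_like(means, 2.0)  # sd^2 = 4, no mean dependence
        model = fit_variance_function(pd.DataFrame({"mean": means, "sd": sd}))
        assert model.c3 == 0.0
        assert model.c1 == pytest.approx(4.0, rel=0.05)

    def test_degenerate_design_errors(self):
        df = pd.DataFrame({"mean": np.full(100, 5.0), "sd": np.ones(100)})
        with pytest.raises(ValueError, match="degenerate"):
            fit_variance_function(df)

    def test_too_few_pairs_errors(self):
        df = pd.DataFrame({"mean": [1.0, 2.0], "sd": [0.1, 0.2]})
        with pytest.raises(ValueError, match=">= 50"):
            fit_variance_function(df)


class TestVstTransform:
    def test_multiplicative_limit_is_exact_log2_plus_constant(self):
        model = VarianceModel(0.0, 0.0, 0.04)
        x = np.linspace(0.5, 1e5, 201)
        np.testing.assert_allclose(vst_values(x, model), np.log2(x) + 1.0, rtol=1e-12)

    def test_pure_multiplicative_fit_matches_log2_over_top_decade(self):
        rng = np.random.default_rng(5)
        means = np.exp(rng.uniform(np.log(10), np.log(1e5), 5000))
        sd = 0.2 * means  # c1 = c2 = 0, c3 = 0.04
        model = fit_variance_function(pd.DataFrame({"mean": means, "sd": sd}))
        top = np.linspace(1e4, 1e5, 50)
        delta = vst_values(top, model) - np.log2(top)
        assert np.ptp(delta) < 1e-3  # constant shift only

    @given(st.floats(0.1, 1e5), st.floats(0.1, 1e5))
    @settings(max_examples=50, deadline=None)
    def test_monotone(self, x1, x2):
        model = VarianceModel(400.0, 1.0, 0.02)
        lo, hi = sorted((x1, x2))
        if hi - lo > 1e-9:
            assert vst_values(np.array([lo]), model) < vst_values(np.array([hi]), model)

    def test_negative_input_errors(self):
        model = VarianceModel(1.0, 0.0, 0.01)
        m = make_matrix([[-1.0]], scale="linear")
        with pytest.raises(ValueError, match="negative"):
            vst_transform(m, model)

    def test_scaling_input_shifts_output_by_constant_in_multiplicative_limit(self):
        model = VarianceModel(0.0, 0.0, 0.01)
        x = np.linspace(1, 1e4, 100)
        shifted = vst_values(8.0 * x, model) - vst_values(x, model)
        np.testing.assert_allclose(shifted, 3.0, rtol=1e-12)

    def test_variance_flattening_vs_log2(self, default_config):
        """Post-VST SD-vs-mean slope shrinks >= 5-fold relative to plain log2."""
        rng = np.random.default_rng(4)
        n_probes, n_samples = 300, 30
        mu = np.exp2(rng.uniform(5, 14, n_probes))
        c = default_config
        var = c.bead_c1 + c.bead_c2 * mu + c.bead_c3 * mu**2
        vals = np.maximum(
            mu[:, None] + np.sqrt(var)[:, None] * rng.standard_normal((n_probes, n_samples)),
            1.0,
        )
        lin = make_matrix(vals, scale="linear")
        bead = pd.DataFrame({"mean": vals.ravel(), "sd": np.sqrt(np.repeat(var, n_samples))})
        model = fit_variance_function(bead)
        h = vst_transform(lin, model).data.to_numpy()
        l2 = np.log2(vals)

        def sd_vs_mean_slope(mat):
            return stats.linregress(mat.mean(axis=1), mat.std(axis=1, ddof=1)).slope

        assert abs(sd_vs_mean_slope(l2)) >= 5.0 * abs(sd_vs_mean_slope(h))


class TestFullNormalization:
    def test_planted_expressed_difference_preserved(self, default_config):
        """A 4-log2 between-group difference at expressed intensities survives
        VST + quantile normalization within +/-0.2 at default noise."""
        rng = np.random.default_rng(8)
        c = default_config
        n_null, n_diff, n_per_group = 400, 5, 10
        # null probes span intensities identically in both groups
        base = np.exp2(rng.uniform(6, 14, n_null))
        group_a = np.tile(np.exp2(9.0), n_diff)  # expressed low
        group_b = np.tile(np.exp2(13.0), n_diff)  # expressed high, Delta = 4
        mu = np.concatenate([base, group_a]), np.concatenate([base, group_b])
        cols = {}
        for g, label in ((0, "a"), (1, "b")):
            for i in range(n_per_group):
                m = mu[g]
                var = c.bead_c1 + c.bead_c2 * m + c.bead_c3 * m**2
                cols[f"{label}{i}"] = np.maximum(m + np.sqrt(var) * rng.standard_normal(m.size), 1.0)
        probes = [f"p{i}" for i in range(n_null + n_diff)]
        lin = ExpressionMatrix(pd.DataFrame(cols, index=probes), scale="linear")
        beads = pd.DataFrame({
            "mean": lin.data.to_numpy().ravel(),
            "sd": np.sqrt(c.bead_c1 + c.bead_c2 * lin.data.to_numpy().ravel()
                          + c.bead_c3 * lin.data.to_numpy().ravel() ** 2),
        })
        norm, model = normalize(lin, beads)
        assert model is not None
        a_cols = [f"a{i}" for i in range(n_per_group)]
        b_cols = [f"b{i}" for i in range(n_per_group)]
        diff_probes = probes[n_null:]
        delta = (norm.data.loc[diff_probes, b_cols].mean(axis=1)
                 - norm.data.loc[diff_probes, a_cols].mean(axis=1))
        assert np.all(np.abs(delta - 4.0) <= 0.2)

    def test_fallback_without_bead_sds(self):
        rng = np.random.default_rng(9)
        lin = make_matrix(np.exp2(rng.uniform(6, 12, (40, 4))), scale="linear")
        norm, model = normalize(lin, bead_summaries=None, epsilon=1.0)
        assert model is None
        assert norm.scale == "transformed"
        assert np.ptp(norm.data.mean(axis=0).to_numpy()) < 1e-9
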