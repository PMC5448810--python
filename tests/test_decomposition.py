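import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiwalk import (
    EpistasisRemover,
    MapSpec,
    build_design_matrix,
    decompose,
    generate_map,
    phi_from_linear,
    phi_profile,
    recompose,
    truncate,
    truncated_map,
)
from scipy.special import comb


class TestDesignMatrix:
    def test_one_site_global_matrix(self):
        dm = build_design_matrix(1, "global")
        # columns: empty set, {0}; rows: "0" (ancestral, encoded -1), "1" (+1)
        np.testing.assert_array_equal(dm.matrix, [[1, -1], [1, 1]])

    @pytest.mark.parametrize("L", range(1, 9))
    def test_global_orthogonality(self, L):
        X = build_design_matrix(L, "global").matrix
        np.testing.assert_allclose(X.T @ X, 2**L * np.eye(2**L), atol=1e-12)

    def test_local_entries_are_indicator_products(self):
        dm = build_design_matrix(2, "local")
        col = dm.subsets.index((0, 1))
        assert dm.matrix[3, col] == 1.0  # genotype "11"
        assert dm.matrix[1, col] == 0.0  # genotype "01"

    @pytest.mark.parametrize("basis", ["global", "local"])
    def test_columns_per_order(self, basis):
        dm = build_design_matrix(5, basis)
        for k in range(6):
            assert np.sum(dm.orders == k) == comb(5, k)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            build_design_matrix(0)
        with pytest.raises(ValueError):
            build_design_matrix(13)
        with pytest.raises(ValueError):
            build_design_matrix(3, "sideways")


class TestDecomposeRecompose:
    def test_constant_vector_is_pure_zeroth_order(self):
        dm = build_design_matrix(3, "global")
        beta = decompose(np.full(8, 2.2), dm)
        assert beta.beta[0] == pytest.approx(2.2)
        np.testing.assert_allclose(beta.beta[1:], 0.0, atol=1e-12)

    @pytest.mark.parametrize("basis", ["global", "local"])
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_injected_coefficients_recovered(self, basis, seed):
        rng = np.random.default_rng(seed)
        dm = build_design_matrix(4, basis)
        beta_true = rng.normal(size=16)
        f = dm.matrix @ beta_true
        np.testing.assert_allclose(decompose(f, dm).beta, beta_true, atol=1e-10)
        np.testing.assert_allclose(recompose(decompose(f, dm), dm), f, atol=1e-10)

    def test_basis_mismatch_raises(self):
        dm_g = build_design_matrix(2, "global")
        dm_l = build_design_matrix(2, "local")
        beta = decompose(np.ones(4), dm_g)
        with pytest.raises(ValueError, match="match"):
            recompose(beta, dm_l)

    def test_full_order_recomposition_identical_across_bases(self):
        rng = np.random.default_rng(9)
        f = rng.normal(1.0, 0.2, size=16)
        for basis in ("global", "local"):
            dm = build_design_matrix(4, basis)
            np.testing.assert_allclose(
                recompose(truncate(decompose(f, dm), 4), dm), f, atol=1e-10
            )


class TestTruncate:
    def test_truncation_rules(self):
        dm = build_design_matrix(3, "global")
        beta = decompose(np.random.default_rng(1).normal(size=8), dm)
        assert np.array_equal(truncate(beta, 3).beta, beta.beta)  # identity at L
        t1 = truncate(beta, 1)
        assert np.all(t1.beta[t1.orders > 1] == 0)
        assert np.array_equal(t1.beta[t1.orders <= 1], beta.beta[beta.orders <= 1])
        t0 = recompose(truncate(beta, 0), dm)
        np.testing.assert_allclose(t0, beta.beta[0], atol=1e-12)  # constant map
        with pytest.raises(ValueError):
            truncate(beta, 4)
        with pytest.raises(ValueError):
            truncate(beta, -1)


class TestTruncatedMap:
    def test_full_order_is_lossless(self, noisy_map_4s):
        tm = truncated_map(noisy_map_4s, 4)
        np.testing.assert_allclose(tm.fitness_mean, noisy_map_4s.fitness_mean, atol=1e-8)
        np.testing.assert_array_equal(tm.fitness_std, noisy_map_4s.fitness_std)

    def test_additive_map_with_scale_survives_order_one_truncation(self):
        spec = MapSpec(n_sites=5, beta_spec={1: 1.0}, scale=(2.5, 1.0, 0.0), seed=7)
        gmap, _, _ = generate_map(spec)
        tm = truncated_map(gmap, 1)
        # the additive model is regressed on the nonlinear observed scale, so
        # the two-stage refit reproduces the source map approximately
        rel = np.abs(tm.fitness_mean - gmap.fitness_mean) / np.abs(gmap.fitness_mean)
        assert rel.max() < 0.01


class TestPhi:
    def test_purely_additive_map_is_all_first_order(self, staircase_map):
        prof = phi_profile(staircase_map)
        assert prof[0] == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(prof[1:], 0.0, atol=1e-9)

    def test_phi_sums_to_one_on_noiseless_map(self, epistatic_map_5s):
        gmap, _, _ = epistatic_map_5s
        prof = phi_profile(gmap)
        # telescoping sum ends at the exact full model: rho_L^2 = 1
        assert prof.sum() == pytest.approx(1.0, abs=1e-8)

    def test_phi_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(3)
        f = rng.normal(1.0, 0.2, size=32)
        np.testing.assert_allclose(
            phi_from_linear(3.0 * f - 1.0), phi_from_linear(f), atol=1e-10
        )

    def test_order_out_of_range(self, staircase_map):
        rem = EpistasisRemover().fit(staircase_map)
        with pytest.raises(ValueError):
            rem.phi(0)
        with pytest.raises(ValueError):
            rem.phi(4)


class TestEpistasisRemover:
    def test_exposes_fitted_attributes(self, noisy_map_4s):
        rem = EpistasisRemover(basis="global").fit(noisy_map_4s)
        assert rem.coefficients_.beta.shape == (16,)
        assert rem.f_linear_.shape == (16,)
        assert rem.scale_.rss_ >= 0
        # sklearn-style parameter plumbing
        assert rem.get_params()["basis"] == "global"
        rem2 = EpistasisRemover().set_params(basis="local").fit(noisy_map_4s)
        assert rem2.design_.basis == "local"
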