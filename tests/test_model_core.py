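import numpy as np
import pytest

from hpcfill.model_core import (
    HPCNetwork,
    NetworkParams,
    coding_length,
    level2_rf_in_image_space,
    perceptual_image,
    perceptual_image_from_states,
    relax_to_steady_state,
    solve_states,
    sparse_prior,
    sparse_prior_deriv,
    state_derivative,
)
from hpcfill.preprocessing import TilingGeometry, tile_patch, untile


class TestSparsePrior:
    def test_zero(self):
        assert sparse_prior(np.zeros(5), 0.05) == 0.0
        np.testing.assert_array_equal(sparse_prior_deriv(np.zeros(5), 0.05), 0.0)

    def test_printed_value(self):
        assert sparse_prior_deriv(np.array([1.0]), 0.05)[0] == pytest.approx(0.05)

    def test_odd_symmetry(self):
        r = np.linspace(-3, 3, 13)
        np.testing.assert_allclose(
            sparse_prior_deriv(-r, 0.1), -sparse_prior_deriv(r, 0.1), atol=1e-14
        )

    def test_linear_in_alpha(self):
        r = np.array([0.5, -1.5, 2.0])
        assert sparse_prior(r, 0.2) == pytest.approx(2 * sparse_prior(r, 0.1))

    def test_gradient_matches_deriv(self):
        rng = np.random.default_rng(0)
        r = rng.normal(size=6)
        eps = 1e-6
        num = np.array([
            (sparse_prior(r + eps * e, 0.05) - sparse_prior(r - eps * e, 0.05)) / (2 * eps)
            for e in np.eye(6)
        ])
        np.testing.assert_allclose(num, sparse_prior_deriv(r, 0.05), rtol=1e-6)


class TestCodingLength:
    def test_zero_everything(self, small_geometry):
        params = NetworkParams(lam=1e-12)  # lam must be > 0; weight prior excluded below
        rng = np.random.default_rng(0)
        net = HPCNetwork(
            U1=rng.normal(size=(16, 8)), U2=rng.normal(size=(32, 5)),
            geometry=small_geometry, params=params,
        )
        E = coding_length(
            np.zeros((6, 6)), np.zeros((4, 8)), np.zeros(5), net,
            include_weight_prior=False,
        )
        assert E == 0.0

    def test_perfect_reconstruction_zero_priors(self, small_geometry):
        # invertible square U1, single level, alpha ~ 0: solve r1 exactly
        rng = np.random.default_rng(1)
        U1 = rng.normal(size=(16, 16)) + 4 * np.eye(16)
        src = rng.normal(size=(6, 6))
        tiles = tile_patch(src, small_geometry)
        r1 = np.stack([np.linalg.solve(U1, t.ravel()) for t in tiles])
        params = NetworkParams(alpha1=1e-300, alpha2=1e-300)
        net = HPCNetwork(U1=U1, U2=None, geometry=small_geometry, params=params)
        E = coding_length(src, r1, None, net, include_weight_prior=False)
        assert E == pytest.approx(0.0, abs=1e-18)

    def test_mask_all_ones_matches_direct(self, small_geometry, small_instance):
        patch, r1, r2 = small_instance
        rng = np.random.default_rng(3)
        U1 = rng.normal(size=(16, 8))
        U2 = rng.normal(size=(32, 5))
        p = NetworkParams()
        net = HPCNetwork(U1=U1, U2=U2, geometry=small_geometry, params=p)
        E = coding_length(patch, r1, r2, net, include_weight_prior=False)
        # independent direct evaluation
        direct = 0.0
        for m, (r, c) in enumerate(small_geometry.windows):
            I_m = patch[r : r + 4, c : c + 4].ravel()
            err = I_m - U1 @ r1[m]
            direct += err @ err / p.sigma2
            direct += p.alpha1 * np.log1p(r1[m] ** 2).sum()
        td = r1.reshape(-1) - U2 @ r2
        direct += td @ td / p.sigma2_td + p.alpha2 * np.log1p(r2**2).sum()
        assert E == pytest.approx(direct, rel=1e-12)


class TestStateDerivative:
    def test_gradient_oracle(self, small_network, small_instance):
        patch, r1, r2 = small_instance
        dr1, dr2 = state_derivative(patch, r1, r2, small_network)
        p = small_network.params
        eps = 1e-6

        def E(r1_, r2_):
            return coding_length(patch, r1_, r2_, small_network)

        num1 = np.zeros_like(r1)
        for m in range(r1.shape[0]):
            for i in range(r1.shape[1]):
                up, dn = r1.copy(), r1.copy()
                up[m, i] += eps
                dn[m, i] -= eps
                num1[m, i] = (E(up, r2) - E(dn, r2)) / (2 * eps)
        num2 = np.array([
            (E(r1, r2 + eps * e) - E(r1, r2 - eps * e)) / (2 * eps) for e in np.eye(5)
        ])
        np.testing.assert_allclose(dr1, -0.5 * p.k1 * num1, rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(dr2, -0.5 * p.k1 * num2, rtol=1e-5, atol=1e-8)

    def test_consistent_fixed_point(self, small_geometry):
        net = HPCNetwork(
            U1=np.random.default_rng(5).normal(size=(16, 8)),
            U2=None, geometry=small_geometry,
        )
        dr1, dr2 = state_derivative(np.zeros((6, 6)), np.zeros((4, 8)), None, net)
        np.testing.assert_array_equal(dr1, 0.0)
        assert dr2 is None

    def test_all_zero_mask_kills_bottom_up(self, small_geometry):
        rng = np.random.default_rng(6)
        U1 = rng.normal(size=(16, 8))
        net_masked = HPCNetwork(
            U1=U1, U2=None, geometry=small_geometry, ff_mask=np.zeros((6, 6))
        )
        patch = rng.normal(size=(6, 6))
        r1 = rng.normal(size=(4, 8))
        dr1, _ = state_derivative(patch, r1, None, net_masked)
        p = net_masked.params
        expected = -0.5 * p.k1 * sparse_prior_deriv(r1, p.alpha1)
        np.testing.assert_allclose(dr1, expected, atol=1e-12)


class TestRelaxation:
    def test_zero_input_immediate_convergence(self, small_network):
        res = relax_to_steady_state(np.zeros((6, 6)), small_network)
        assert res.converged
        assert res.iterations == 0
        np.testing.assert_array_equal(res.r1, 0.0)

    @pytest.mark.parametrize("method", ["euler", "lbfgs"])
    def test_energy_descent(self, small_network, small_instance, method):
        patch, _, _ = small_instance
        res = relax_to_steady_state(
            patch, small_network, tol=1e-5, max_iter=5000, method=method
        )
        assert res.converged
        diffs = np.diff(res.E_trace)
        assert np.all(diffs <= 1e-10)
        assert res.final_grad_norm <= 1e-5

    def test_reconverge_idempotent(self, small_network, small_instance):
        patch, _, _ = small_instance
        res = relax_to_steady_state(patch, small_network, tol=1e-5, max_iter=5000)
        res2 = relax_to_steady_state(
            patch, small_network, init_r1=res.r1, init_r2=res.r2,
            tol=1e-5, max_iter=5000,
        )
        assert res2.iterations <= 1

    def test_invertible_limit(self, small_geometry):
        # alpha ~ 0, square invertible U1, single level, all-ones mask:
        # steady state reconstructs the input exactly
        rng = np.random.default_rng(7)
        U1 = rng.normal(size=(16, 16)) + 4 * np.eye(16)
        params = NetworkParams(alpha1=1e-300, alpha2=1e-300)
        net = HPCNetwork(U1=U1, U2=None, geometry=small_geometry, params=params)
        patch = rng.normal(size=(6, 6))
        res = relax_to_steady_state(patch, net, tol=1e-6, max_iter=20000)
        assert res.converged
        tiles = tile_patch(patch, small_geometry)
        for m in range(4):
            np.testing.assert_allclose(
                U1 @ res.r1[m], tiles[m].ravel(), atol=1e-4
            )

    def test_invalid_args(self, small_network):
        with pytest.raises(ValueError):
            relax_to_steady_state(np.zeros((6, 6)), small_network, step=0.0)
        with pytest.raises(ValueError):
            relax_to_steady_state(np.zeros((6, 6)), small_network, tol=-1.0)
        with pytest.raises(ValueError):
            relax_to_steady_state(np.zeros((6, 6)), small_network, method="rk4")

    def test_lbfgs_matches_gradient_flow(self, small_network, small_instance):
        patch, _, _ = small_instance
        res = relax_to_steady_state(
            patch, small_network, tol=1e-7, max_iter=20000, method="euler"
        )
        from hpcfill.model_core import _patch_tiles

        X = _patch_tiles(patch, small_network.geometry)
        r1, r2, _, gmax = solve_states(
            X, small_network.U1, small_network.U2,
            small_network.module_masks(), small_network.params,
            tol=1e-7, max_iter=20000,
        )
        np.testing.assert_allclose(r1[:, :, 0], res.r1, atol=1e-4)
        np.testing.assert_allclose(r2[:, 0], res.r2, atol=1e-4)


class TestPerceptualImage:
    def test_zero_states(self, small_network):
        img = perceptual_image_from_states(small_network, np.zeros((4, 8)))
        np.testing.assert_array_equal(img, 0.0)

    def test_linearity(self, small_network):
        rng = np.random.default_rng(8)
        r1 = rng.normal(size=(4, 8))
        a = perceptual_image_from_states(small_network, 2.0 * r1)
        b = 2.0 * perceptual_image_from_states(small_network, r1)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_from_inference_result(self, small_network, small_instance):
        patch, _, _ = small_instance
        res = relax_to_steady_state(patch, small_network)
        img = perceptual_image(small_network, res)
        assert img.shape == (6, 6)
        np.testing.assert_allclose(
            img, perceptual_image_from_states(small_network, res.r1), atol=1e-12
        )


class TestLevel2RF:
    def test_one_hot_composition(self, small_geometry):
        rng = np.random.default_rng(9)
        U1 = rng.normal(size=(16, 8))
        U2 = np.zeros((32, 5))
        U2[2 * 8 + 3, 1] = 1.0  # neuron 3 of module 2
        net = HPCNetwork(U1=U1, U2=U2, geometry=small_geometry)
        img = level2_rf_in_image_space(net, 1)
        subs = np.zeros((4, 4, 4))
        subs[2] = U1[:, 3].reshape(4, 4)
        np.testing.assert_allclose(img, untile(subs, small_geometry), atol=1e-12)

    def test_linear_in_column(self, small_network):
        net = small_network
        j = 2
        img = level2_rf_in_image_space(net, j)
        net2 = HPCNetwork(
            U1=net.U1, U2=net.U2 * 3.0, geometry=net.geometry, params=net.params
        )
        np.testing.assert_allclose(
            level2_rf_in_image_space(net2, j), 3.0 * img, atol=1e-12
        )

    def test_index_out_of_range(self, small_network):
        with pytest.raises(ValueError):
            level2_rf_in_image_space(small_network, 99)


class TestNetworkParams:
    def test_defaults_are_printed_values(self):
        p = NetworkParams()
        assert (p.k1, p.k2, p.sigma2, p.sigma2_td) == (1.0, 3.0, 3.0, 10.0)
        assert (p.alpha1, p.alpha2) == (0.05, 0.1)
        assert (p.lam, p.sigma2_goal, p.gamma) == (0.0025, 0.05, 0.02)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            NetworkParams(k1=-1.0)
        with pytest.raises(ValueError):
            NetworkParams(sigma2=0.0)


class TestHPCNetworkValidation:
    def test_u2_row_mismatch(self, small_geometry):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError):
            HPCNetwork(
                U1=rng.normal(size=(16, 8)),
                U2=rng.normal(size=(30, 5)),
                geometry=small_geometry,
            )

    def test_u1_dim_mismatch(self, small_geometry):
        with pytest.raises(ValueError):
            HPCNetwork(U1=np.zeros((15, 8)), geometry=small_geometry)
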