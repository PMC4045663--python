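import numpy as np
import pytest

from mwfmap.core_model import N_PARAMS, ParamBounds, build_grid, field_signals
from mwfmap.spatial_solver import (
    FitConfig,
    RegState,
    assemble_residual,
    build_graph,
    default_scales,
    fit_spatial,
    jacobian_sparsity,
    prior_residual,
    rescale_regularization,
    spatial_residual,
)
from mwfmap.volume import EchoVolume

from conftest import GM_THETA, WM_THETA


class TestGraph:
    def test_single_voxel_no_edges(self):
        g = build_graph(np.ones((1, 1, 1), bool))
        assert g.n_voxels == 1 and g.n_edges == 0

    def test_two_voxel_line(self):
        g = build_graph(np.ones((1, 1, 2), bool))
        assert g.n_edges == 1

    def test_full_3x3_grid_edge_count(self):
        # enumeration: 2D 3x3 4-neighborhood has 2*3*2 = 12 adjacencies
        g = build_graph(np.ones((3, 3), bool))
        assert g.n_voxels == 9 and g.n_edges == 12

    def test_edges_respect_mask(self):
        mask = np.zeros((3, 3, 1), bool)
        mask[0, 0] = mask[2, 2] = True  # diagonal: not face-adjacent
        g = build_graph(mask)
        assert g.n_voxels == 2 and g.n_edges == 0

    def test_no_self_or_duplicate_edges(self):
        g = build_graph(np.ones((4, 4, 2), bool))
        assert np.all(g.edges[:, 0] != g.edges[:, 1])
        pairs = {tuple(sorted(e)) for e in g.edges.tolist()}
        assert len(pairs) == g.n_edges
        assert g.n_edges <= 3 * g.n_voxels

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            build_graph(np.zeros((2, 2), bool))


class TestResidualBlocks:
    def test_constant_field_zero_spatial(self):
        g = build_graph(np.ones((2, 2), bool))
        theta = np.tile(ParamBounds.defaults().initial, (4, 1))
        r = spatial_residual(theta, g.edges, 0.01, default_scales())
        assert np.all(r == 0)

    def test_hand_evaluated_spatial_entry(self):
        g = build_graph(np.ones((1, 1, 2), bool))
        theta = np.tile(ParamBounds.defaults().initial, (2, 1))
        theta[1, 4] += 10.0  # mu_ie differs by 10 ms
        scales = default_scales()
        r = spatial_residual(theta, g.edges, 0.01, scales)
        nonzero = r[r != 0]
        assert nonzero.size == 1
        assert abs(nonzero[0]) == pytest.approx(0.01 * 10.0 / 295.0)

    def test_zero_mu_s_zero_vector(self):
        g = build_graph(np.ones((1, 1, 2), bool))
        theta = np.random.default_rng(0).random((2, N_PARAMS))
        assert np.all(spatial_residual(theta, g.edges, 0.0, default_scales()) == 0)

    def test_prior_zero_cases_and_hand_value(self):
        theta0 = ParamBounds.defaults().initial
        theta = np.tile(theta0, (3, 1))
        scales = default_scales()
        assert np.all(prior_residual(theta, theta0, 0.013, scales) == 0)
        theta[1, 0] = 0.3  # c_my deviates by 0.2, scale 1
        assert np.all(prior_residual(theta, theta0, 0.0, scales) == 0)
        r = prior_residual(theta, theta0, 0.013, scales)
        nonzero = r[r != 0]
        assert nonzero.size == 1
        assert nonzero[0] == pytest.approx(0.013 * 0.2)


class TestObjectiveConsistency:
    """||assemble_residual||^2 equals an independently summed 3-term objective."""

    @pytest.mark.parametrize("lam,mu", [(0.0, 0.0), (0.013, 0.01), (0.5, 0.2)])
    def test_matches_scalar_oracle(self, grid, mese, lam, mu):
        rng = np.random.default_rng(42)
        mask = np.ones((2, 2, 1), bool)
        g = build_graph(mask)
        nv = g.n_voxels
        theta0 = ParamBounds.defaults().initial
        theta = np.tile(theta0, (nv, 1)) * rng.uniform(0.8, 1.2, (nv, N_PARAMS))
        y = rng.random((nv, mese.count))
        scales = default_scales(grid)
        from mwfmap.core_model import decay_basis

        basis = decay_basis(grid, mese)
        q = assemble_residual(
            theta.ravel(), y, basis, mese.times, theta0, g.edges, lam, mu, scales, grid
        )

        # independent scalar oracle: plain python loops, no stacking
        fidelity = 0.0
        for v in range(nv):
            pred = field_signals(theta[v][None, :], grid, mese)[0]
            fidelity += float(np.sum((y[v] - pred) ** 2))
        prior = 0.0
        for v in range(nv):
            for p in range(N_PARAMS):
                prior += (lam * (theta[v, p] - theta0[p]) / scales[p]) ** 2
        spatial = 0.0
        for u, v in g.edges:
            for p in range(N_PARAMS):
                spatial += (mu * (theta[u, p] - theta[v, p]) / scales[p]) ** 2

        assert q @ q == pytest.approx(fidelity + prior + spatial, rel=1e-10)

    def test_noiseless_constant_field_zero_residual(self, grid, mese):
        mask = np.ones((2, 1, 1), bool)
        g = build_graph(mask)
        theta = np.tile(np.array(WM_THETA), (2, 1))
        y = field_signals(theta, grid, mese)
        from mwfmap.core_model import decay_basis

        q = assemble_residual(
            theta.ravel(), y, decay_basis(grid, mese), mese.times,
            np.array(WM_THETA), g.edges, 0.0, 0.01, default_scales(grid), grid,
        )
        assert np.linalg.norm(q) == pytest.approx(0.0, abs=1e-14)


class TestSparsityPattern:
    def test_single_voxel_pattern(self, mese):
        g = build_graph(np.ones((1, 1, 1), bool))
        P = jacobian_sparsity(g, mese.count).toarray()
        assert P.shape == (mese.count + 8, 8)
        assert np.all(P[: mese.count])  # dense fidelity block
        assert np.array_equal(P[mese.count :], np.eye(8, dtype=bool))

    def test_disconnected_voxels_block_diagonal(self):
        mask = np.zeros((3, 1, 1), bool)
        mask[0] = mask[2] = True
        g = build_graph(mask)
        K = 4
        P = jacobian_sparsity(g, K).toarray()
        assert P.shape == (2 * K + 16, 16)
        assert not P[:K, 8:].any() and not P[K : 2 * K, :8].any()

    def test_neighbor_spatial_rows(self):
        g = build_graph(np.ones((1, 1, 2), bool))
        K = 4
        P = jacobian_sparsity(g, K).toarray()
        spatial = P[2 * K + 16 :]
        assert spatial.shape == (8, 16)
        for p in range(8):
            cols = np.flatnonzero(spatial[p])
            assert np.array_equal(cols, [p, 8 + p])

    def test_pattern_covers_finite_difference_jacobian(self, grid, mese):
        """Every numerically nonzero Jacobian entry is inside the pattern."""
        rng = np.random.default_rng(0)
        g = build_graph(np.ones((1, 2, 1), bool))
        theta0 = ParamBounds.defaults().initial
        theta = np.tile(theta0, (2, 1)) * rng.uniform(0.9, 1.1, (2, 8))
        y = rng.random((2, mese.count))
        from mwfmap.core_model import decay_basis

        basis = decay_basis(grid, mese)
        scales = default_scales(grid)

        def fun(x):
            return assemble_residual(
                x, y, basis, mese.times, theta0, g.edges, 0.013, 0.01, scales, grid
            )

        x = theta.ravel()
        f0 = fun(x)
        J = np.zeros((f0.size, x.size))
        for j in range(x.size):
            h = 1e-6 * max(1.0, abs(x[j]))
            xp = x.copy()
            xp[j] += h
            J[:, j] = (fun(xp) - f0) / h
        P = jacobian_sparsity(g, mese.count).toarray()
        assert not np.any((np.abs(J) > 1e-8) & ~P)


class TestRescaling:
    def test_fixed_point(self):
        s = RegState(lambda_n=0.01, mu_s=0.02, gamma_n=0.1, gamma_s=0.1, eta=0.5)
        # penalty norms exactly at target ratio: prior/fid = 0.1, spatial/fid = 0.1
        out = rescale_regularization(s, 1.0, 0.1, 0.1)
        assert out.lambda_n == pytest.approx(0.01)
        assert out.mu_s == pytest.approx(0.02)

    def test_full_jump_eta_one(self):
        s = RegState(lambda_n=0.01, mu_s=0.01, eta=1.0)
        out = rescale_regularization(s, 2.0, 0.1, 0.05)
        # lambda* = 0.1 * 2.0 / (0.1/0.01) = 0.02
        assert out.lambda_n == pytest.approx(0.02)
        assert out.mu_s == pytest.approx(0.1 * 2.0 / (0.05 / 0.01))

    def test_relaxed_update_halfway(self):
        s = RegState(lambda_n=0.01, mu_s=0.01, eta=0.5)
        # choose norms so lambda* = 0.02
        out = rescale_regularization(s, 2.0, 0.1, 0.1)
        assert out.lambda_n == pytest.approx(0.015)

    def test_zero_fidelity_leaves_state(self):
        s = RegState(lambda_n=0.01, mu_s=0.02)
        out = rescale_regularization(s, 0.0, 0.5, 0.5)
        assert out == s


class TestFitSpatial:
    def test_single_wm_voxel_recovery(self, single_voxel_volume):
        r = fit_spatial(single_voxel_volume(WM_THETA))
        assert r.mwf_map[0, 0, 0] == pytest.approx(0.145, abs=0.005)

    def test_penalty_dominated_limit_equalizes_voxels(self, grid, mese):
        theta = np.array([WM_THETA, GM_THETA])
        y = field_signals(theta, grid, mese)
        vol = EchoVolume(
            data=y.reshape(1, 1, 2, -1), schedule=mese, mask=np.ones((1, 1, 2), bool)
        )
        cfg = FitConfig(reg=RegState(lambda_n=0.0013, mu_s=50.0), rescale=False)
        r = fit_spatial(vol, cfg)
        scaled_diff = np.abs(r.theta[0] - r.theta[1]) / default_scales(grid)
        assert np.max(scaled_diff) < 1e-3

    def test_cost_non_increasing_within_iterations(self, grid, mese):
        rng = np.random.default_rng(11)
        theta = np.array([WM_THETA, GM_THETA, WM_THETA, GM_THETA])
        y = field_signals(theta, grid, mese)
        y = y + 0.01 * rng.standard_normal(y.shape)
        vol = EchoVolume(
            data=y.reshape(2, 2, 1, -1), schedule=mese, mask=np.ones((2, 2, 1), bool)
        )
        r = fit_spatial(vol, FitConfig(max_iter=15))
        for h in r.residual_history:
            assert h["cost_end"] <= h["cost_start"] * (1 + 1e-12)

    def test_bounds_respected_and_mwf_in_range(self, grid, mese):
        rng = np.random.default_rng(4)
        theta = np.tile(np.array(WM_THETA), (4, 1))
        y = field_signals(theta, grid, mese) + 0.02 * rng.standard_normal((4, mese.count))
        vol = EchoVolume(
            data=y.reshape(2, 2, 1, -1), schedule=mese, mask=np.ones((2, 2, 1), bool)
        )
        r = fit_spatial(vol, FitConfig(max_iter=20))
        b = ParamBounds.defaults()
        assert np.all(r.theta >= b.lower - 1e-9)
        assert np.all(r.theta <= b.upper + 1e-9)
        assert np.all((r.mwf_map >= 0) & (r.mwf_map <= 1))

    def test_all_zero_volume_rejected(self, mese):
        vol = EchoVolume(
            data=np.zeros((1, 1, 1, mese.count)),
            schedule=mese,
            mask=np.ones((1, 1, 1), bool),
        )
        with pytest.raises(ValueError):
            fit_spatial(vol)

    def test_non_finite_data_rejected(self, mese):
        data = np.ones((1, 1, 1, mese.count))
        data[0, 0, 0, 3] = np.nan
        with pytest.raises(ValueError):
            EchoVolume(data=data, schedule=mese, mask=np.ones((1, 1, 1), bool))

    def test_single_voxel_matches_brute_force_grid_search(self, grid, mese,
                                                          single_voxel_volume):
        """Unregularized single-voxel fit agrees with a coarse exhaustive search
        over (c_my, mu_my) with the other parameters held at truth."""
        truth = np.array(WM_THETA)
        vol = single_voxel_volume(truth)
        cfg = FitConfig(reg=RegState(lambda_n=1e-12, mu_s=1e-12), rescale=False)
        r = fit_spatial(vol, cfg)

        y = field_signals(truth[None, :], grid, mese)[0]
        best = None
        for c_my in np.linspace(0.05, 0.25, 21):
            for mu_my in np.linspace(15, 35, 21):
                cand = truth.copy()
                cand[0], cand[1] = c_my, mu_my
                pred = field_signals(cand[None, :], grid, mese)[0]
                err = np.sum((y - pred) ** 2)
                if best is None or err < best[0]:
                    best = (err, c_my, mu_my)
        _, c_best, mu_best = best
        # agreement within the lattice resolution (c step 0.01, mu step 1.0;
        # truth can fall between lattice nodes)
        assert r.theta[0, 0] == pytest.approx(c_best, abs=0.01)
        assert r.theta[0, 1] == pytest.approx(mu_best, abs=1.5)
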