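"""Mass-spring lattice: grid construction, forces, forward equilibrium,
inverse modulus estimation."""

import numpy as np
import pytest

import lungelast as le
from lungelast.biomech import YM_MAX_KPA, YM_MIN_KPA

SPACING = (2.0, 2.0, 2.0)


def chain_grid(n, end_disp, spacing=SPACING):
    """1 x 1 x n chain with only the two end nodes prescribed."""
    mask = np.ones((1, 1, n), bool)
    bmask = np.zeros_like(mask)
    bmask[0, 0, 0] = bmask[0, 0, -1] = True
    dvf = np.zeros((1, 1, n, 3))
    dvf[0, 0, -1, 2] = end_disp
    return le.build_element_grid(mask, spacing, dvf, boundary_mask=bmask)


class TestBuildElementGrid:
    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        grid = le.build_element_grid(mask, SPACING)
        assert grid.n_nodes == 1
        assert grid.n_links == 0
        assert grid.boundary_mask.all()

    def test_two_voxel_pair(self):
        mask = np.zeros((2, 1, 1), bool)
        mask[:, 0, 0] = True
        grid = le.build_element_grid(mask, SPACING)
        assert grid.n_links == 1
        assert grid.rest_length[0] == SPACING[0]
        assert not grid.link_is_shear[0]

    def test_full_cube_link_counts(self):
        grid = le.build_element_grid(np.ones((3, 3, 3), bool), SPACING)
        assert grid.n_nodes == 27
        assert (~grid.link_is_shear).sum() == 54        # 3 axes * 2*3*3
        assert grid.link_is_shear.sum() == 6 * 2 * 2 * 3  # 6 diagonal dirs
        assert grid.boundary_mask.sum() == 26
        # diagonal links have sqrt(2) rest length
        np.testing.assert_allclose(
            grid.rest_length[grid.link_is_shear],
            np.sqrt(2) * SPACING[0],
        )

    def test_every_interior_node_linked(self, small_phantom):
        grid = le.build_element_grid(small_phantom.lung_mask, SPACING)
        deg = np.bincount(grid.link_a, minlength=grid.n_nodes) + \
            np.bincount(grid.link_b, minlength=grid.n_nodes)
        assert (deg[~grid.boundary_mask] >= 1).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            le.build_element_grid(np.zeros((3, 3, 3), bool), SPACING)


class TestComputeForces:
    def test_rest_state_force_free(self):
        grid = le.build_element_grid(np.ones((4, 4, 4), bool), SPACING)
        ym = le.ElasticityMap(np.full(grid.n_nodes, 2.0))
        f = le.compute_forces(grid, ym, np.zeros((grid.n_nodes, 3)))
        assert np.abs(f).max() < 1e-10

    def test_rigid_translation_force_free(self):
        grid = le.build_element_grid(np.ones((4, 4, 4), bool), SPACING)
        ym = le.ElasticityMap(np.full(grid.n_nodes, 2.0))
        u = np.tile([1.7, -0.4, 3.1], (grid.n_nodes, 1))
        f = le.compute_forces(grid, ym, u)
        assert np.abs(f).max() < 1e-10

    def test_two_node_stretch_hand_value(self):
        mask = np.zeros((2, 1, 1), bool)
        mask[:, 0, 0] = True
        grid = le.build_element_grid(mask, SPACING)
        ym = le.ElasticityMap(np.full(2, 1.0))
        u = np.zeros((2, 3))
        u[1, 0] = 0.1 * SPACING[0]  # 10% stretch
        f = le.compute_forces(grid, ym, u)
        # f = YM * strain = 1 kPa * 0.1, attractive, equal and opposite
        assert f[0, 0] == pytest.approx(0.1, abs=1e-12)
        assert f[1, 0] == pytest.approx(-0.1, abs=1e-12)

    def test_newtons_third_law(self):
        rng = np.random.default_rng(2)
        grid = le.build_element_grid(np.ones((5, 5, 5), bool), SPACING)
        ym = le.ElasticityMap(rng.lognormal(1.0, 0.4, grid.n_nodes))
        u = 0.3 * rng.standard_normal((grid.n_nodes, 3))
        v = rng.standard_normal((grid.n_nodes, 3))
        f = le.compute_forces(grid, ym, u, velocities=v)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)


class TestForwardSolve:
    def test_zero_boundary_zero_interior(self):
        grid = le.build_element_grid(np.ones((4, 4, 4), bool), SPACING)
        ym = le.ElasticityMap(np.full(grid.n_nodes, 2.0))
        state = le.forward_solve(grid, ym)
        assert np.abs(state.displacements).max() == 0.0
        assert state.iterations == 0

    def test_uniform_translation_propagates(self):
        mask = np.ones((5, 5, 5), bool)
        t = np.array([1.0, -2.0, 0.5])
        dvf = np.tile(t, mask.shape + (1,))
        grid = le.build_element_grid(mask, SPACING, dvf)
        ym = le.ElasticityMap(np.full(grid.n_nodes, 2.0))
        state = le.forward_solve(grid, ym, tol=1e-9)
        np.testing.assert_allclose(
            state.displacements,
            np.broadcast_to(t, state.displacements.shape),
            atol=1e-3,
        )

    def test_two_spring_chain_force_balance(self):
        # series springs k1=1, k2=3, end displacements 0 and 4 mm:
        # u_mid = (k1*0 + k2*4)/(k1+k2) = 3 mm
        grid = chain_grid(3, end_disp=4.0)
        ym = le.ElasticityMap(np.array([1.0, 1.0, 5.0]))  # link means 1, 3
        state = le.forward_solve(grid, ym, tol=1e-10)
        assert state.displacements[1, 2] == pytest.approx(3.0, abs=1e-6)

    def test_five_node_chain_matches_series_spring_solution(self):
        n = 5
        node_ym = np.array([1.0, 2.0, 4.0, 1.5, 3.0])
        end = 2.0
        grid = chain_grid(n, end_disp=end)
        k = 0.5 * (node_ym[:-1] + node_ym[1:])  # link stiffnesses
        # tridiagonal force balance for interior nodes 1..3
        A = np.zeros((n - 2, n - 2))
        b = np.zeros(n - 2)
        for i in range(1, n - 1):
            r = i - 1
            A[r, r] = k[i - 1] + k[i]
            if r > 0:
                A[r, r - 1] = -k[i - 1]
            if r < n - 3:
                A[r, r + 1] = -k[i]
        b[0] += k[0] * 0.0
        b[-1] += k[-1] * end
        expected = np.linalg.solve(A, b)
        ym = le.ElasticityMap(node_ym)
        state = le.forward_solve(grid, ym, tol=1e-12)
        np.testing.assert_allclose(
            state.displacements[1:-1, 2], expected, rtol=1e-6
        )

    def test_stiffened_block_strains_less(self):
        # monotonicity: raising one block's modulus lowers its strain share
        n = 10
        mask = np.ones((n, n, n), bool)
        bmask = np.zeros_like(mask)
        bmask[:, :, 0] = bmask[:, :, -1] = True
        dvf = np.zeros((n, n, n, 3))
        dvf[:, :, -1, 2] = 2.0
        grid = le.build_element_grid(mask, SPACING, dvf, boundary_mask=bmask)
        z = grid.node_ijk[:, 2]
        strains = []
        for stiff in (5.0, 10.0):
            ym_vals = np.where(z < n // 2, 1.0, stiff)
            state = le.forward_solve(grid, le.ElasticityMap(ym_vals))
            from lungelast.biomech import _node_strain
            s = _node_strain(grid, state.displacements)
            strains.append(s[z >= n // 2].mean())
        assert strains[1] < strains[0]

    def test_nonconvergence_raises_with_residual(self):
        grid = chain_grid(5, end_disp=4.0)
        ym = le.ElasticityMap(np.full(5, 1.0))
        with pytest.raises(le.ForwardSolveError) as err:
            le.forward_solve(grid, ym, tol=1e-14, max_iter=3)
        assert err.value.residual > 0


class TestInitElasticityFromHU:
    def test_air_maps_to_floor(self):
        hu = np.full((2, 2, 2), -1000.0)
        ym = le.init_elasticity_from_hu(hu, np.ones_like(hu, bool))
        np.testing.assert_allclose(ym.ym, YM_MIN_KPA)

    def test_threshold_maps_to_upper_start(self):
        hu = np.full((2, 2, 2), -700.0)
        ym = le.init_elasticity_from_hu(hu, np.ones_like(hu, bool))
        np.testing.assert_allclose(ym.ym, 5.0)

    def test_monotone_in_hu(self):
        hu = np.linspace(-1100, 0, 64).reshape(4, 4, 4)
        ym = le.init_elasticity_from_hu(hu, np.ones_like(hu, bool))
        assert (np.diff(ym.ym) >= 0).all()
        assert ym.ym.max() <= YM_MAX_KPA


class TestEstimateElasticity:
    def test_fixed_point_exits_immediately(self):
        mask = np.ones((8, 8, 8), bool)
        bmask = np.zeros_like(mask)
        bmask[:, :, 0] = bmask[:, :, -1] = True
        dvf = np.zeros((8, 8, 8, 3))
        dvf[:, :, -1, 2] = 1.5
        gen = le.build_element_grid(mask, SPACING, dvf, boundary_mask=bmask)
        init = le.ElasticityMap(np.full(gen.n_nodes, 2.0))
        target = gen.volume_from_node_values(
            le.forward_solve(gen, init).displacements
        )
        grid = le.build_element_grid(mask, SPACING, target,
                                     boundary_mask=bmask)
        result = le.estimate_elasticity(grid, target, init, outer_tol=0.01)
        assert result.converged
        assert result.outer_iterations == 1
        np.testing.assert_array_equal(result.elasticity.ym, init.ym)

    def test_two_block_contrast_recovered(self):
        # desk-scale inverse crime at 12^3: the recovered map must separate
        # the soft and stiff halves in the right order and ratio
        n = 12
        mask = np.ones((n, n, n), bool)
        bmask = np.zeros_like(mask)
        bmask[:, :, 0] = bmask[:, :, -1] = True
        dvf = np.zeros((n, n, n, 3))
        dvf[:, :, -1, 2] = 2.0
        gen = le.build_element_grid(mask, SPACING, dvf, boundary_mask=bmask)
        z = gen.node_ijk[:, 2]
        truth = np.where(z < n // 2, 1.0, 5.0)
        target = gen.volume_from_node_values(
            le.forward_solve(gen, le.ElasticityMap(truth, "truth")).displacements
        )
        grid = le.build_element_grid(mask, SPACING, target)
        init = le.ElasticityMap(np.full(grid.n_nodes, 2.0))
        result = le.estimate_elasticity(grid, target, init,
                                        outer_tol=0.005, max_outer=40)
        interior = ~grid.boundary_mask
        soft = np.median(result.elasticity.ym[interior & (z < n // 2)])
        stiff = np.median(result.elasticity.ym[interior & (z >= n // 2)])
        assert stiff > 2.5 * soft
        assert result.error_trace[-1] < result.error_trace[0]

    def test_estimates_stay_clamped(self):
        grid = chain_grid(5, end_disp=1.0)
        init = le.ElasticityMap(np.full(5, 2.0))
        target = np.zeros((1, 1, 5, 3))
        target[0, 0, -1, 2] = 1.0
        result = le.estimate_elasticity(grid, target, init, max_outer=5,
                                        outer_tol=1e-6)
        assert (result.elasticity.ym >= YM_MIN_KPA).all()
        assert (result.elasticity.ym <= YM_MAX_KPA).all()
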