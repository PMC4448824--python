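"""Slender-body and boundary-integral operators against independent oracles."""

import numpy as np
import pytest

from elastoswim.kernels import KernelParams, ResistanceCoefficients, drag_coefficients
from elastoswim.meshes import HeadBody, make_flagellum_grid, make_head_mesh
from elastoswim.hydro import (
    grand_resistance,
    head_load,
    local_drag_velocity,
    nonlocal_sbt_velocity,
    single_layer_velocity,
    solve_hydro,
)
from elastoswim.fixtures import (
    PrescribedSwimmer,
    classical_drag,
    sbt_integral_oracle,
    single_layer_oracle,
)


def _smooth_density(mesh):
    # a smooth traction field: centroid-rule convergence is then meaningful
    c = mesh.centroids
    import numpy as _np
    return _np.stack([1 + c[:, 1], c[:, 0] * c[:, 2], _np.cos(c[:, 0])], axis=1)


@pytest.fixture(scope="module")
def coeffs():
    return drag_coefficients(KernelParams(mu=1.0, epsilon=0.01, b=0.01, q=0.1, L=1.0))


class TestLocalDrag:
    def test_perpendicular_and_parallel_limits(self, coeffs):
        t = np.array([1.0, 0.0, 0.0])
        f_perp = np.array([0.0, 2.0, 0.0])
        f_par = np.array([3.0, 0.0, 0.0])
        assert np.allclose(local_drag_velocity(f_perp, t, coeffs), -f_perp / coeffs.xi_perp)
        assert np.allclose(local_drag_velocity(f_par, t, coeffs), -f_par / coeffs.xi_par)

    def test_linearity_decomposition(self, coeffs, rng):
        t = rng.standard_normal(3)
        t /= np.linalg.norm(t)
        f = rng.standard_normal(3)
        f_par = (f @ t) * t
        f_perp = f - f_par
        v = local_drag_velocity(f, t, coeffs)
        assert np.allclose(
            v, local_drag_velocity(f_par, t, coeffs) + local_drag_velocity(f_perp, t, coeffs)
        )

    def test_non_unit_tangent_rejected(self, coeffs):
        with pytest.raises(ValueError):
            local_drag_velocity(np.ones(3), np.array([1.0, 1.0, 0.0]), coeffs)


class TestNonlocalSBT:
    def test_zero_force_zero_velocity(self, grid120):
        X = np.stack([grid120.s, 0 * grid120.s, 0 * grid120.s], axis=1)
        V = nonlocal_sbt_velocity(X, np.zeros((grid120.n_nodes, 3)), 0.1, 1.0, grid120.s)
        assert np.allclose(V, 0.0)

    def test_matches_refined_quadrature_oracle(self, grid120):
        sw = PrescribedSwimmer(0.08, 2 * np.pi)
        t0 = 0.3
        X = sw.positions(grid120.s, t0)

        def ff(s):
            return np.array([np.sin(2 * np.pi * s), np.cos(3 * s), 0.1 * s])

        f = np.array([ff(s) for s in grid120.s])
        V = nonlocal_sbt_velocity(X, f, 0.1, 1.0, grid120.s)
        scale = np.max(np.abs(V))
        for i in (0, 17, 60, 101, 120):
            Vo = sbt_integral_oracle(
                lambda s: sw.positions(np.array([s]), t0)[0], ff, grid120.s[i], 0.1, 1.0
            )
            assert np.max(np.abs(V[i] - Vo)) < 1e-3 * scale

    def test_translation_invariance(self, grid120, rng):
        sw = PrescribedSwimmer(0.05, 2 * np.pi)
        X = sw.positions(grid120.s, 0.0)
        f = rng.standard_normal((grid120.n_nodes, 3))
        V1 = nonlocal_sbt_velocity(X, f, 0.1, 1.0, grid120.s)
        V2 = nonlocal_sbt_velocity(X + np.array([5.0, -2.0, 3.0]), f, 0.1, 1.0, grid120.s)
        assert np.allclose(V1, V2, atol=1e-14)

    def test_unresolvable_cutoff_rejected(self):
        g = make_flagellum_grid(8)
        X = np.stack([g.s, 0 * g.s, 0 * g.s], axis=1)
        with pytest.raises(ValueError):
            nonlocal_sbt_velocity(X, np.zeros((9, 3)), q=0.05, mu=1.0, s=g.s)


class TestSingleLayer:
    def test_zero_density(self, unit_sphere_mesh):
        u = single_layer_velocity(unit_sphere_mesh, np.zeros((80, 3)), [[3.0, 0, 0]], 1.0)
        assert np.allclose(u, 0.0)

    def test_far_field_is_stokeslet_of_total_force(self, unit_sphere_mesh):
        from elastoswim.kernels import stokeslet

        phi = np.tile([0.0, 1.0, 0.0], (80, 1))
        target = np.array([40.0, 10.0, 0.0])
        u = single_layer_velocity(unit_sphere_mesh, phi, target[None], 1.0)[0]
        F = (phi * unit_sphere_mesh.areas[:, None]).sum(axis=0)
        u_far = stokeslet(target, np.zeros(3), 1.0) @ F
        assert np.max(np.abs(u - u_far)) < 2e-3 * np.max(np.abs(u_far))

    def test_off_surface_matches_refined_oracle(self, sphere320_mesh):
        phi = _smooth_density(sphere320_mesh)
        for target in ([2.5, 0.3, -0.4], [0.0, 1.8, 0.2]):
            u = single_layer_velocity(sphere320_mesh, phi, [target], 1.0)[0]
            uo = single_layer_oracle(sphere320_mesh, phi, target, 1.0, refine=4)
            assert np.max(np.abs(u - uo)) < 1e-3 * np.max(np.abs(uo))

    def test_on_surface_matches_adaptive_oracle(self, unit_sphere_mesh, rng):
        phi = rng.standard_normal((80, 3))
        e = 5
        target = unit_sphere_mesh.centroids[e]
        u = single_layer_velocity(unit_sphere_mesh, phi, [target], 1.0, self_map={0: e})[0]
        uo = single_layer_oracle(unit_sphere_mesh, phi, target, 1.0, refine=5)
        assert np.max(np.abs(u - uo)) < 1e-3 * np.max(np.abs(uo))

    def test_singular_kernel_on_surface_without_self_map_rejected(self, unit_sphere_mesh):
        with pytest.raises(ValueError):
            single_layer_velocity(
                unit_sphere_mesh, np.ones((80, 3)), [unit_sphere_mesh.centroids[3]], 1.0
            )


class TestSolveHydro:
    def test_rigid_transverse_rod_drag_vs_classical(self, coeffs):
        grid = make_flagellum_grid(80)
        X = np.stack([grid.s, 0 * grid.s, 0 * grid.s], axis=1)
        Xt = np.tile([0.0, 1.0, 0.0], (grid.n_nodes, 1))
        p = KernelParams(mu=1.0, epsilon=0.01, b=0.01, q=0.1, L=1.0)
        sol = solve_hydro(X, Xt, grid.s, p, coeffs)
        w = np.full(grid.n_nodes, grid.ds)
        w[0] = w[-1] = grid.ds / 2
        F = (sol.f_vis * w[:, None]).sum(axis=0)
        ref = classical_drag("straight-slender-rod", 1.0, U=1.0, L=1.0, b=0.01)
        assert abs(abs(F[1]) - ref) / ref < 0.10
        assert F[1] < 0  # drag opposes the motion

    def test_mirror_symmetry(self, coeffs, rng):
        grid = make_flagellum_grid(40)
        sw = PrescribedSwimmer(0.06, 2 * np.pi)
        X = sw.positions(grid.s, 0.2)
        Xt = rng.standard_normal((grid.n_nodes, 3))
        p = KernelParams(mu=1.0, epsilon=0.01, b=0.01, q=0.1, L=1.0)
        sol = solve_hydro(X, Xt, grid.s, p, coeffs)
        M = np.diag([1.0, 1.0, -1.0])  # reflect in z = 0
        sol_m = solve_hydro(X @ M, Xt @ M, grid.s, p, coeffs)
        assert np.allclose(sol_m.f_vis, sol.f_vis @ M, atol=1e-12)
        assert np.allclose(sol_m.V, sol.V @ M, atol=1e-12)

    def test_system_dimension(self, coeffs):
        # coupled flow problem has 3 x (flagellum nodes + head + wall elements)
        from elastoswim.meshes import make_wall
        from elastoswim.hydro import SurfaceOperator

        grid = make_flagellum_grid(16)
        head = HeadBody.ellipsoid(refinement=0)
        head.pose_from_tangent(np.array([0.0, 0.3, 0.0]), np.array([-1.0, 0.0, 0.0]))
        wall = make_wall("strip", resolution=2, extents=(1.0, 0.5))
        op = SurfaceOperator(head, wall, 1.0)
        assert op.G_ss.shape[0] == 3 * (20 + wall.mesh.n_elements)


class TestGrandResistance:
    def test_sphere_translation_block_stokes_law(self, sphere_resistance_1280):
        # >= 500 elements: icosahedral refinement 3 gives 1280
        R = sphere_resistance_1280
        stokes = classical_drag("sphere", 1.0, U=1.0, a=1.0)
        assert np.allclose(np.diag(R)[:3], stokes, rtol=0.02)
        assert np.linalg.norm(R - R.T) / np.linalg.norm(R) < 1e-3

    def test_wall_increases_parallel_drag_monotonically(self):
        from elastoswim.meshes import make_wall

        wall = make_wall("strip", resolution=6, extents=(1.0, 1.0))
        drags = []
        for gap in (0.4, 0.25, 0.15):
            head = HeadBody((0.05, 0.05, 0.05), make_head_mesh(0.05, 0.05, 0.05, refinement=1))
            head.junction = np.array([0.0, gap, 0.0])
            head.rotation = np.eye(3)
            # place centre at the junction for this pure-drag check
            head.junction = head.junction - head.rotation[:, 0] * 0.05
            drags.append(grand_resistance(head, wall, mu=1.0)[0, 0])
        assert drags[0] < drags[1] < drags[2]

    def test_wall_truncation_error_controlled(self):
        # doubling the wall extents changes the drag on a test sphere at
        # height 0.2 L above the wall by under 1%
        from elastoswim.meshes import make_wall

        def drag(extents, resolution):
            # uniform panels: doubling extents with doubled resolution keeps
            # the inner panels identical, isolating the truncation error
            wall = make_wall("strip", resolution=resolution, extents=extents, grading=0.0)
            head = HeadBody((0.05, 0.05, 0.05), make_head_mesh(0.05, 0.05, 0.05, refinement=1))
            head.junction = np.array([-0.05, 0.2, 0.0])  # centre at (0, 0.2, 0)
            return grand_resistance(head, wall, mu=1.0)[0, 0]

        d1 = drag((1.5, 1.5), 12)
        d2 = drag((3.0, 3.0), 24)
        assert abs(d2 - d1) / d1 < 0.01

    def test_head_wall_intersection_rejected(self):
        from elastoswim.meshes import make_wall

        wall = make_wall("strip", resolution=4, extents=(1.0, 1.0))
        head = HeadBody.ellipsoid(refinement=0)
        head.pose_from_tangent(np.array([0.0, 0.01, 0.0]), np.array([-1.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="intersects"):
            grand_resistance(head, wall, mu=1.0)


class TestHeadLoad:
    def test_free_space_rigid_translation_matches_resistance(self, coeffs):
        # prescribed-kinematics flagellum far away, head translating: the
        # surface-integrated load equals -R U to solver tolerance
        grid = make_flagellum_grid(16)
        head = HeadBody.ellipsoid(refinement=1)
        head.pose_from_tangent(np.zeros(3), np.array([-1.0, 0.0, 0.0]))
        X = np.stack([-grid.s, 0 * grid.s, 0 * grid.s], axis=1)
        p = KernelParams(mu=1.0, epsilon=0.01, b=0.01, q=0.1, L=1.0)
        U = np.array([0.3, -0.1, 0.0])
        sol = solve_hydro(
            X, np.tile(U, (grid.n_nodes, 1)), grid.s, p, coeffs,
            head=head, rigid_velocity=(U, np.zeros(3)),
        )
        R = grand_resistance(head, None, mu=1.0)
        (F, M), (dF, dM) = head_load(sol, R, (U, np.zeros(3)))
        # the flagellum is attached, so corrections are not zero, but the
        # decomposition must reproduce the total load exactly
        assert np.allclose(F, -(R @ np.concatenate([U, np.zeros(3)]))[:3] + dF)

    def test_zero_velocity_zero_flagellum_force_gives_zero_load(self, coeffs):
        grid = make_flagellum_grid(16)
        head = HeadBody.ellipsoid(refinement=1)
        head.pose_from_tangent(np.zeros(3), np.array([-1.0, 0.0, 0.0]))
        X = np.stack([-grid.s, 0 * grid.s, 0 * grid.s], axis=1)
        p = KernelParams(mu=1.0, epsilon=0.01, b=0.01, q=0.1, L=1.0)
        sol = solve_hydro(
            X, np.zeros((grid.n_nodes, 3)), grid.s, p, coeffs,
            head=head, rigid_velocity=(np.zeros(3), np.zeros(3)),
        )
        scale = 6 * np.pi * 0.05  # Stokes drag scale of the head at unit speed
        assert np.linalg.norm(sol.F_head) < 1e-8 * scale
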