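"""Finite-difference operators, actuation, tension solve and time stepping."""

import numpy as np
import pytest

from elastoswim.meshes import HeadBody, make_flagellum_grid
from elastoswim.stepper import (
    ActiveMoment,
    FlagellumState,
    StepperConfig,
    Swimmer,
    active_moment,
    assemble_step_system,
    fd_operators,
    fornberg_weights,
    tension_solve,
)


@pytest.fixture(scope="module")
def ops40():
    return fd_operators(make_flagellum_grid(40))


class TestFiniteDifferences:
    def test_one_sided_first_derivative_weights(self):
        # 4-point stencil at the left end, unit spacing
        w = fornberg_weights(0.0, np.arange(4.0), 1)[1]
        assert np.allclose(w, [-11.0 / 6.0, 3.0, -3.0 / 2.0, 1.0 / 3.0])

    @pytest.mark.parametrize("order,power", [(1, 2), (2, 2), (3, 3), (4, 4)])
    def test_polynomial_exactness(self, ops40, order, power):
        g = make_flagellum_grid(40)
        f = g.s**power
        import math

        exact = (
            math.factorial(power)
            / math.factorial(power - order)
            * g.s ** (power - order)
        )
        assert np.max(np.abs(ops40[order] @ f - exact)) < 1e-7

    def test_fourth_derivative_of_quartic_constant_everywhere(self, ops40):
        g = make_flagellum_grid(40)
        d4 = ops40[4] @ g.s**4
        assert np.allclose(d4, 24.0, atol=1e-6)

    def test_inextensibility_identity_on_unit_speed_curve(self):
        # 3 X_ss.X_sss + X_s.X_ssss = 0 holds for any unit-speed curve; the
        # discrete residual on an arclength-corrected sinusoid decays at
        # second order under grid refinement (a circular arc is too special:
        # its residual is at round-off for all stencils)
        from elastoswim.fixtures import PrescribedSwimmer

        def residual(ns):
            g = make_flagellum_grid(ns)
            ops = fd_operators(g)
            X = PrescribedSwimmer(0.08, 2 * np.pi).positions(g.s, 0.0)
            r = 3 * np.einsum("lc,lc->l", ops[2] @ X, ops[3] @ X) + np.einsum(
                "lc,lc->l", ops[1] @ X, ops[4] @ X
            )
            return np.max(np.abs(r[3:-3]))

        r1, r2 = residual(40), residual(80)
        assert 3.0 < r1 / r2 < 5.5  # ~second order


class TestActiveMoment:
    def test_amplitude_at_origin(self):
        mom = ActiveMoment(m0=240.0, k=6 * np.pi, tau=None)
        m, _ = active_moment(np.array([0.0]), 0.0, mom)
        assert m[0] == pytest.approx(240.0)

    def test_soft_start_99_percent_after_five_beats(self):
        mom = ActiveMoment()
        assert mom.ramp(5 * 2 * np.pi) == pytest.approx(0.99, abs=1e-9)
        ts = np.linspace(0, 40, 200)
        r = np.array([mom.ramp(t) for t in ts])
        assert np.all(np.diff(r) > 0) and np.all((0 <= r) & (r < 1))

    def test_integer_wave_count_zero_spatial_mean(self):
        mom = ActiveMoment(m0=240.0, k=6 * np.pi, tau=None)
        s = np.linspace(0, 1, 2001)
        m, _ = mom(s, 0.0)
        assert abs(np.trapezoid(m, s)) < 1e-10
        assert abs(mom.integral(0.0)) < 1e-10

    def test_analytic_derivative_matches_finite_difference(self):
        mom = ActiveMoment(m0=10.0, k=4.0, tau=None)
        s = np.array([0.3])
        _, ms = mom(s, 1.0)
        h = 1e-6
        fd = (mom(s + h, 1.0)[0] - mom(s - h, 1.0)[0]) / (2 * h)
        assert ms[0] == pytest.approx(fd[0], rel=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            active_moment(np.array([0.0]), -1.0, ActiveMoment())


class TestTensionSolve:
    def test_straight_static_filament_zero_tension(self):
        g = make_flagellum_grid(40)
        X = np.stack([g.s, 0 * g.s, 0 * g.s], axis=1)
        T = tension_solve(X, g.s, None, ActiveMoment(m0=0.0, tau=None), 0.0,
                          StepperConfig(Sp=10.0))
        assert np.max(np.abs(T)) < 1e-10

    def test_distal_tension_always_zero(self, rng):
        g = make_flagellum_grid(40)
        from elastoswim.fixtures import PrescribedSwimmer

        X = PrescribedSwimmer(0.05, 2 * np.pi).positions(g.s, 0.7)
        V = 0.01 * rng.standard_normal((g.n_nodes, 3))
        T = tension_solve(X, g.s, V, ActiveMoment(), 3.0, StepperConfig(Sp=15.0),
                          F_head=np.array([1.0, 2.0, 0.0]))
        assert T[-1] == 0.0

    def test_manufactured_solution_recovery(self):
        # insert an analytic tension into the discrete operator, solve with
        # the implied right-hand side, and recover it to high accuracy
        g = make_flagellum_grid(60)
        from elastoswim.stepper import fd_operators
        from elastoswim.fixtures import PrescribedSwimmer
        import scipy.linalg

        cfg = StepperConfig(Sp=12.0)
        X = PrescribedSwimmer(0.06, 2 * np.pi).positions(g.s, 0.2)
        ops = fd_operators(g)
        gam = cfg.coefficients().gamma
        Xss = ops[2] @ X
        Aop = gam * ops[2] - np.diag(np.einsum("lc,lc->l", Xss, Xss))
        T_star = np.sin(np.pi * g.s) * (1.0 - g.s)  # satisfies T*(1) = 0
        rhs = Aop @ T_star
        Aop[0] = 0.0
        Aop[0, 0] = 1.0
        rhs[0] = T_star[0]
        Aop[-1] = 0.0
        Aop[-1, -1] = 1.0
        rhs[-1] = 0.0
        T = scipy.linalg.solve(Aop, rhs)
        assert np.max(np.abs(T - T_star)) < 1e-8


class TestStepSystem:
    def test_system_dimension_650_at_full_resolution(self):
        g = make_flagellum_grid(160)
        from elastoswim.stepper import fd_operators

        cfg = StepperConfig(Sp=15.0)
        X = np.stack([-g.s, 0.2 + 0 * g.s, 0 * g.s], axis=1)
        st = FlagellumState(X=X, T=np.zeros(g.n_nodes))
        tilde = FlagellumState(X=X.copy(), T=np.zeros(g.n_nodes), t=cfg.dt)
        A, b = assemble_step_system(
            st, tilde, np.zeros_like(X), np.zeros(3), np.zeros(3), np.eye(6),
            ActiveMoment(), cfg, fd_operators(g), g.s,
        )
        assert A.shape == (650, 650)
        assert b.shape == (650,)


@pytest.fixture(scope="module")
def short_free_swimmer():
    """A free swimmer advanced 90 steps (1.5 beats at 60 steps/beat)."""
    cfg = StepperConfig(Sp=15.0, dt=2 * np.pi / 60)
    sw = Swimmer(cfg, ActiveMoment(), make_flagellum_grid(100),
                 HeadBody.ellipsoid(refinement=1), wall=None, x0=(0.0, 0.0, 0.0))
    infos = [sw.step() for _ in range(90)]
    return sw, infos


class TestSwimmer:
    def test_picard_converges_in_few_iterations(self, short_free_swimmer):
        _, infos = short_free_swimmer
        its = [i["iterations"] for i in infos[5:]]
        assert np.mean(its) <= 5.0
        assert max(its) < 15

    def test_inextensibility_maintained(self, short_free_swimmer):
        sw, _ = short_free_swimmer
        stretch = np.abs(np.linalg.norm(sw.ops[1] @ sw.state.X, axis=1) - 1.0)
        assert stretch.max() < 0.02

    def test_distal_tension_zero(self, short_free_swimmer):
        sw, _ = short_free_swimmer
        assert sw.state.T[-1] == pytest.approx(0.0, abs=1e-10)

    def test_planar_symmetry_without_projection(self):
        # symmetric initial data: z-components stay at round-off without
        # needing the mirror projection
        cfg = StepperConfig(Sp=15.0, dt=2 * np.pi / 60, project_z=False)
        sw = Swimmer(cfg, ActiveMoment(), make_flagellum_grid(100),
                     HeadBody.ellipsoid(refinement=1), wall=None, x0=(0.0, 0.0, 0.0))
        for _ in range(30):
            sw.step()
        assert np.max(np.abs(sw.state.X[:, 2])) < 1e-8

    def test_local_theory_mode_runs_and_conserves_length(self):
        cfg = StepperConfig(Sp=15.0, dt=2 * np.pi / 60)
        sw = Swimmer(cfg, ActiveMoment(), make_flagellum_grid(100),
                     HeadBody.ellipsoid(refinement=1), wall=None,
                     x0=(0.0, 0.0, 0.0), nonlocal_flow=False)
        for _ in range(60):
            sw.step()
        stretch = np.abs(np.linalg.norm(sw.ops[1] @ sw.state.X, axis=1) - 1.0)
        assert stretch.max() < 0.02
        assert sw.state.V is not None and np.allclose(sw.state.V, 0.0)

    def test_force_free_swimming(self, short_free_swimmer):
        # total force on the cell (flagellum integral + head surface integral)
        # vanishes relative to the force-density scale
        sw, infos = short_free_swimmer
        hydro = infos[-1]["hydro"]
        g = sw.grid
        w = np.full(g.n_nodes, g.ds)
        w[0] = w[-1] = g.ds / 2
        F_flag = (hydro.f_vis * w[:, None]).sum(axis=0)
        total = F_flag + hydro.F_head
        scale = (np.abs(hydro.f_vis) * w[:, None]).sum()
        # the residual is quadrature/operator-compatibility limited, O(ds^2)
        assert np.linalg.norm(total) < 1e-2 * scale
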