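"""Lattice Boltzmann kernel checks: stencils, equilibrium/moments, collision
and streaming conservation laws, boundary conditions, Poiseuille validation."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aneuflow import (
    ConfigurationError,
    DomainMask,
    NodeClass,
    StabilityError,
    SteadyStateCriterion,
    VesselSpec,
    build_domain,
    build_unit_system,
    d2q9,
    d3q19,
    default_scenario,
    equilibrium,
    moments,
)
from aneuflow.lbm import LBMSolver, run_to_steady

from conftest import poiseuille_2d


@pytest.fixture(params=["D2Q9", "D3Q19"], scope="module")
def model(request):
    return d2q9() if request.param == "D2Q9" else d3q19()


class TestLatticeModels:
    def test_direction_counts(self):
        assert d2q9().q == 9 and d2q9().d == 2
        assert d3q19().q == 19 and d3q19().d == 3

    def test_rest_direction_first(self, model):
        assert np.array_equal(model.e[0], np.zeros(model.d))

    def test_isotropy_constraints(self, model):
        """Brute-force summation: sum w = 1, sum w e = 0,
        sum w e_a e_b = delta_ab / 3."""
        w, e = model.w, model.e.astype(float)
        assert w.sum() == pytest.approx(1.0, abs=1e-14)
        assert np.allclose(np.einsum("q,qa->a", w, e), 0.0, atol=1e-14)
        second = np.einsum("q,qa,qb->ab", w, e, e)
        assert np.allclose(second, np.eye(model.d) / 3.0, atol=1e-14)

    def test_opposite_map_is_involution(self, model):
        assert np.array_equal(model.opp[model.opp], np.arange(model.q))
        assert np.array_equal(model.e[model.opp], -model.e)


class TestEquilibrium:
    def test_rest_state_returns_weights(self, model):
        feq = equilibrium(1.0, np.zeros(model.d), model)
        assert np.allclose(feq, model.w, atol=1e-15)

    def test_hand_evaluated_direction(self):
        """D2Q9, rho=1, u=(0.1, 0), direction e=(1,0):
        (1/9)(1 + 0.3 + 0.045 - 0.015)."""
        feq = equilibrium(1.0, np.array([0.1, 0.0]), d2q9())
        assert feq[1] == pytest.approx((1 + 0.3 + 0.045 - 0.015) / 9, rel=1e-14)

    @given(
        rho=st.floats(min_value=0.5, max_value=2.0),
        ux=st.floats(min_value=-0.2, max_value=0.2),
        uy=st.floats(min_value=-0.2, max_value=0.2),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_moment_identities(self, rho, ux, uy):
        """moments(equilibrium(rho, u)) recovers (rho, u): mass and momentum
        are exact moments of the quadratic equilibrium."""
        mdl = d2q9()
        u = np.array([ux, uy])
        feq = equilibrium(rho, u, mdl)
        assert feq.sum() == pytest.approx(rho, abs=1e-14)
        rho2, u2 = moments(feq, mdl)
        assert rho2 == pytest.approx(rho, abs=1e-13)
        assert np.allclose(u2, u, atol=1e-13)

    def test_supersonic_velocity_rejected(self, model):
        u = np.zeros(model.d)
        u[0] = 0.7
        with pytest.raises(StabilityError):
            equilibrium(1.0, u, model)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            equilibrium(1.0, np.zeros(3), d2q9())


class TestMoments:
    def test_weights_give_rest_state(self, model):
        rho, u = moments(model.w, model)
        assert rho == pytest.approx(1.0, abs=1e-15)
        assert np.allclose(u, 0.0, atol=1e-15)

    def test_zero_pdfs_rejected(self, model):
        with pytest.raises(StabilityError):
            moments(np.zeros(model.q), model)

    def test_nonfinite_rejected(self, model):
        f = model.w.copy()
        f[2] = np.nan
        with pytest.raises(StabilityError):
            moments(f, model)


def _open_box_mask(shape):
    """All-fluid periodic box (no walls, no inlet/outlet)."""
    classes = np.full(shape, NodeClass.FLUID, dtype=np.uint8)
    phi = -np.ones(shape)
    vessel = VesselSpec(width=3e-3, length=12e-3)
    return DomainMask(classes=classes, phi=phi, dx=1e-4, origin=(0.0, 0.0), vessel=vessel)


def _closed_box_mask(n=24):
    """Square cavity: solid border, fluid interior, no inlet/outlet."""
    classes = np.full((n, n), NodeClass.SOLID, dtype=np.uint8)
    classes[1:-1, 1:-1] = NodeClass.FLUID
    phi = np.where(classes == NodeClass.FLUID, -1.0, 1.0)
    vessel = VesselSpec(width=3e-3, length=12e-3)
    return DomainMask(classes=classes, phi=phi, dx=1e-4, origin=(0.0, 0.0), vessel=vessel)


def _units():
    return build_unit_system(default_scenario(2))


class TestCollide:
    def test_tau_one_projects_onto_equilibrium(self):
        mask = _open_box_mask((8, 8))
        us = dataclasses.replace(_units(), tau=1.0)
        solver = LBMSolver(mask, us)
        rng = np.random.default_rng(7)
        solver.f = solver.f * (1 + 0.01 * rng.random(solver.f.shape))
        rho, u = solver.macroscopic()
        solver.collide()
        feq = equilibrium(rho, u, solver.model, check=False)
        assert np.allclose(solver.f, feq, atol=1e-14)

    def test_collision_conserves_node_mass_and_momentum(self):
        mask = _open_box_mask((8, 8))
        solver = LBMSolver(mask, _units())
        rng = np.random.default_rng(11)
        solver.f = solver.f * (1 + 0.02 * rng.random(solver.f.shape))
        rho0, u0 = solver.macroscopic()
        solver.collide()
        rho1, u1 = solver.macroscopic()
        assert np.allclose(rho1, rho0, atol=1e-14)
        assert np.allclose(rho1 * u1, rho0 * u0, atol=1e-14)

    def test_uniform_equilibrium_is_fixed_point(self):
        """Galilean rest-frame check: a zero-velocity equilibrium state is an
        exact fixed point of collide + stream in a periodic domain."""
        mask = _open_box_mask((10, 6))
        solver = LBMSolver(mask, _units())
        solver.f = equilibrium(np.full(mask.shape, 1.3), np.zeros((2,) + mask.shape),
                               solver.model, check=False)
        f0 = solver.f.copy()
        solver.collide()
        solver.stream()
        assert np.array_equal(solver.f, f0)


class TestStreamAndBounceBack:
    def test_single_pulse_advects_one_cell(self):
        mask = _open_box_mask((9, 9))
        solver = LBMSolver(mask, _units())
        solver.f[:] = 0.0
        i = 5  # direction (1, 1) in the D2Q9 ordering
        assert tuple(solver.model.e[i]) == (1, 1)
        solver.f[i, 4, 4] = 1.0
        solver.stream()
        assert solver.f[i, 5, 5] == 1.0
        assert solver.f.sum() == 1.0

    def test_streaming_is_a_permutation(self):
        mask = _open_box_mask((7, 8))
        solver = LBMSolver(mask, _units())
        rng = np.random.default_rng(3)
        solver.f = rng.random(solver.f.shape)
        total = solver.f.sum()
        solver.stream()
        assert solver.f.sum() == pytest.approx(total, rel=1e-14)

    def test_bounce_back_conserves_mass_exactly(self):
        mask = _closed_box_mask()
        solver = LBMSolver(mask, _units())
        total = solver.total_mass()
        solver.stream()
        solver.bounce_back()
        assert solver.total_mass() == pytest.approx(total, rel=1e-15)

    def test_closed_cavity_mass_constant_over_many_steps(self):
        """Global mass in an all-solid-boundary cavity stays constant to
        1e-12 relative over thousands of collide/stream/bounce-back steps."""
        mask = _closed_box_mask()
        solver = LBMSolver(mask, _units())
        rng = np.random.default_rng(5)
        u = 0.02 * (rng.random((2,) + mask.shape) - 0.5)
        solver.f = equilibrium(np.ones(mask.shape), u, solver.model, check=False)
        total0 = solver.total_mass()
        solver.step(2000)
        assert abs(solver.total_mass() - total0) / total0 < 1e-12


class TestBoundaryConditions:
    def test_inlet_imposes_parabolic_profile(self, poiseuille_lbm, channel_mask):
        solver, _ = poiseuille_lbm
        v = solver.velocity_physical()
        y = channel_mask.axes()[1]
        expected = poiseuille_2d(0.05, 3e-3, y)
        fl = channel_mask.fluid[0]
        assert np.allclose(v[0][0][fl], expected[fl], atol=1e-6)
        # centreline node carries u ~ u_max; the wall-adjacent node carries
        # the first cell-centre value of the parabola, ~ 0.066 u_max
        assert v[0][0].max() == pytest.approx(0.05, rel=0.01)
        assert v[0][0][fl].min() < 0.07 * 0.05

    def test_outlet_reproduces_uniform_flow(self):
        mask = build_domain(VesselSpec(length=12e-3), resolution=15)
        solver = LBMSolver(mask, build_unit_system(default_scenario(2), 15))
        u = np.zeros((2,) + mask.shape)
        u[0] = 0.03
        solver.f = equilibrium(np.ones(mask.shape), u, solver.model, check=False)
        before = solver.f[:, -1].copy()
        solver.apply_outlet()
        assert np.allclose(solver.f[:, -1], before, atol=1e-15)

    def test_outlet_profile_matches_interior(self, poiseuille_lbm, channel_mask):
        solver, _ = poiseuille_lbm
        v = solver.velocity_physical()
        fl = channel_mask.fluid[-1]
        assert np.allclose(v[0][-1][fl], v[0][-4][fl], rtol=1e-3, atol=1e-6)

    def test_outlet_density_stays_positive(self, poiseuille_lbm):
        solver, _ = poiseuille_lbm
        rho, _ = solver.macroscopic()
        assert rho[solver.mask.fluid].min() > 0


class TestPoiseuilleValidation:
    def test_velocity_profile_matches_parabola(self, poiseuille_lbm, channel_mask):
        solver, report = poiseuille_lbm
        assert report.converged
        v = solver.velocity_physical()
        y = channel_mask.axes()[1]
        expected = np.broadcast_to(poiseuille_2d(0.05, 3e-3, y), v[0].shape)
        fl = channel_mask.fluid
        err = np.linalg.norm((v[0] - expected)[fl]) / np.linalg.norm(expected[fl])
        assert err < 0.01

    def test_error_decreases_under_refinement(self, poiseuille_lbm, channel_mask):
        coarse_mask = build_domain(VesselSpec(length=12e-3), resolution=15)
        us = build_unit_system(default_scenario(2), cells_across_width=15)
        coarse, rep = run_to_steady(coarse_mask, us, SteadyStateCriterion(tolerance=1e-7))
        assert rep.converged

        def l2(solver, mask):
            v = solver.velocity_physical()
            y = mask.axes()[1]
            a = np.broadcast_to(poiseuille_2d(0.05, 3e-3, y), v[0].shape)
            fl = mask.fluid
            return np.linalg.norm((v[0] - a)[fl]) / np.linalg.norm(a[fl])

        fine, _ = poiseuille_lbm
        assert l2(fine, channel_mask) < l2(coarse, coarse_mask)

    def test_field_symmetric_about_centerline(self, poiseuille_lbm, channel_mask):
        solver, _ = poiseuille_lbm
        v = solver.velocity_physical()
        fl = channel_mask.fluid
        j0 = np.nonzero(fl[5])[0]
        u_col = v[0][:, j0.min():j0.max() + 1]
        assert np.allclose(u_col, u_col[:, ::-1], atol=1e-10 * 0.05)

    def test_extrapolated_wall_velocity_is_small(self, poiseuille_lbm, channel_mask):
        """Linear extrapolation of the two wall-adjacent rows to the wall
        face gives < 1% of u_max (half-way bounce-back wall placement)."""
        solver, _ = poiseuille_lbm
        v = solver.velocity_physical()
        i = channel_mask.shape[0] // 2
        j = np.nonzero(channel_mask.fluid[i])[0].min()
        u_wall = 1.5 * v[0][i, j] - 0.5 * v[0][i, j + 1]
        assert abs(u_wall) < 0.01 * 0.05


class TestRunToSteady:
    def test_converged_state_returns_after_one_interval(self, poiseuille_lbm):
        solver, _ = poiseuille_lbm
        report = solver.run_to_steady(SteadyStateCriterion(tolerance=1e-6,
                                                           check_interval=50))
        assert report.converged
        assert report.steps == 50

    def test_zero_tolerance_never_converges(self):
        mask = build_domain(VesselSpec(length=12e-3), resolution=15)
        solver = LBMSolver(mask, build_unit_system(default_scenario(2), 15))
        report = solver.run_to_steady(
            SteadyStateCriterion(tolerance=0.0, check_interval=50, max_steps=200)
        )
        assert not report.converged
        assert report.steps == 200

    def test_criterion_validation(self):
        with pytest.raises(ConfigurationError):
            SteadyStateCriterion(tolerance=-1)
        with pytest.raises(ConfigurationError):
            SteadyStateCriterion(check_interval=100, max_steps=50)


class TestThreeDimensional:
    def test_pipe_flow_approaches_poiseuille(self):
        """D3Q19 tube flow: parabolic profile with mean ~ u_max/2; coarse
        staircase walls limit the accuracy at 12 cells across the bore."""
        mask = build_domain(VesselSpec(length=12e-3, dimensionality=3), resolution=12)
        us = build_unit_system(default_scenario(3), cells_across_width=12)
        solver, report = run_to_steady(mask, us, SteadyStateCriterion(tolerance=5e-6))
        assert report.converged
        v = solver.velocity_physical()
        Y, Z = np.meshgrid(mask.axes()[1], mask.axes()[2], indexing="ij")
        r2 = Y**2 + Z**2
        R = 1.5e-3
        expected = np.where(r2 < R**2, 0.05 * (1 - r2 / R**2), 0.0)
        i = mask.shape[0] // 2
        fl = mask.fluid[i]
        err = np.linalg.norm((v[0][i] - expected)[fl]) / np.linalg.norm(expected[fl])
        assert err < 0.08
        assert v[0][i][fl].mean() / v[0][i].max() == pytest.approx(0.5, abs=0.05)
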