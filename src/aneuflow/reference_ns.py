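"""Incompressible Navier-Stokes reference solver (2D, structured grid).

Cross-validation counterpart to the lattice Boltzmann solver: it solves

    rho (du/dt + u . grad u) = -grad p + mu lap u,   div u = 0,

on the same rasterized domain mask, using a MAC staggered grid (pressure at
cell centres, velocity components on cell faces) and Chorin pressure
projection: an explicit predictor (first-order upwind advection, central
diffusion) followed by an exact sparse-LU pressure Poisson solve, so the
discrete divergence after each projection is at machine precision.

No-slip walls sit exactly on the faces between fluid and solid cells
(normal velocity zero on the face, tangential velocity zero via ghost-cell
reflection), matching the half-way wall placement of the bounce-back LBM so
both solvers discretize bit-identical geometry.  The inlet imposes a
parabolic velocity profile; the outlet holds the pressure at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu

from .exceptions import ConfigurationError, StabilityError
from .geometry import DomainMask, NodeClass
from .lbm import ConvergenceReport, SteadyStateCriterion
from .units import FlowScenario


@dataclass
class StressModel:
    """Newtonian stress sigma = -p I + mu (grad u + grad u^T)."""

    dynamic_viscosity: float

    def __post_init__(self) -> None:
        if self.dynamic_viscosity <= 0:
            raise ConfigurationError("dynamic_viscosity must be > 0")

    def tensor(self, p: float, grad_u: np.ndarray) -> np.ndarray:
        """Evaluate sigma for a pointwise pressure and velocity gradient."""
        grad_u = np.asarray(grad_u, dtype=float)
        eye = np.eye(grad_u.shape[0])
        return -p * eye + self.dynamic_viscosity * (grad_u + grad_u.T)


@dataclass
class FlowField:
    """Velocity/pressure solution on the mask's grid.

    ``u`` is the cell-centered velocity (2, nx, ny) in m/s (zero on solid
    nodes), ``p`` the cell-centered pressure in Pa (zero on solid, defined up
    to the outlet reference), ``u_face``/``v_face`` the staggered face
    velocities the solver actually advances.
    """

    u: np.ndarray
    p: np.ndarray
    u_face: np.ndarray
    v_face: np.ndarray
    dx: float
    t: float
    mask: DomainMask


def divergence(u_face: np.ndarray, v_face: np.ndarray, dx: float,
               fluid: np.ndarray | None = None) -> np.ndarray:
    """Discrete divergence (1/s) per cell, same stencil as the projection."""
    div = (u_face[1:] - u_face[:-1] + v_face[:, 1:] - v_face[:, :-1]) / dx
    if fluid is not None:
        div = np.where(fluid, div, 0.0)
    return div


def field_divergence(field: FlowField) -> np.ndarray:
    return divergence(field.u_face, field.v_face, field.dx, field.mask.fluid)


class NSSolver2D:
    """Projection-method solver bound to a 2D domain mask.

    Parameters
    ----------
    mask : DomainMask
        Shared geometry (identical to the LBM's).
    scenario : FlowScenario
        Fluid properties and inflow peak velocity.
    dt : float, optional
        Time step [s]; default 0.9 x the explicit diffusion/advection bound.
    inlet_profile : callable, optional
        Map y [m] -> axial velocity [m/s] at the inlet; default is the
        parabolic profile peaking at ``scenario.u_max_inflow``.
    moving_wall_u : float
        Tangential velocity of walls on the +y side (plain-channel Couette
        validation option); 0 for no-slip everywhere.
    """

    def __init__(
        self,
        mask: DomainMask,
        scenario: FlowScenario,
        dt: float | None = None,
        inlet_profile: Callable[[np.ndarray], np.ndarray] | None = None,
        moving_wall_u: float = 0.0,
    ) -> None:
        if mask.ndim != 2:
            raise ConfigurationError("the NS reference solver is 2D-only")
        self.mask = mask
        self.scenario = scenario
        self.nu = scenario.fluid.kinematic_viscosity
        self.rho = scenario.fluid.density
        self.moving_wall_u = moving_wall_u
        self.dx = mask.dx
        nx, ny = mask.shape
        self.nx, self.ny = nx, ny
        F = mask.fluid
        self.F = F

        # combined explicit advection-diffusion bound:
        # 4 nu dt/dx^2 + |u| dt/dx <= 1, taken with a 0.6 safety factor
        u_ref = max(scenario.u_max_inflow, abs(moving_wall_u), 1e-12)
        dt_stable = 1.0 / (4.0 * self.nu / self.dx**2 + u_ref / self.dx)
        self.dt = dt if dt is not None else 0.6 * dt_stable
        if self.dt > dt_stable:
            raise ConfigurationError(
                f"dt={self.dt:.3e} violates the explicit stability bound "
                f"{dt_stable:.3e}"
            )

        # --- face bookkeeping -------------------------------------------
        # u faces (nx+1, ny): face i sits between cells i-1 and i
        self.u_active = np.zeros((nx + 1, ny), dtype=bool)
        self.u_active[1:nx] = F[:-1] & F[1:]
        self.u_inlet = np.zeros((nx + 1, ny), dtype=bool)
        self.u_inlet[0] = mask.classes[0] == NodeClass.INLET
        self.u_outlet = np.zeros((nx + 1, ny), dtype=bool)
        self.u_outlet[nx] = mask.classes[-1] == NodeClass.OUTLET
        # faces carrying physically meaningful u values (for ghost logic)
        self.u_in_fluid = self.u_active | self.u_inlet | self.u_outlet

        # v faces (nx, ny+1): face j sits between cells j-1 and j; v is
        # prescribed zero in the inlet/outlet columns (axial in/outflow)
        self.v_active = np.zeros((nx, ny + 1), dtype=bool)
        self.v_active[:, 1:ny] = F[:, :-1] & F[:, 1:]
        self.v_active[0] = False
        self.v_active[-1] = False
        self.v_in_fluid = np.zeros((nx, ny + 1), dtype=bool)
        self.v_in_fluid[:, 1:ny] = F[:, :-1] & F[:, 1:]

        # --- inlet profile ----------------------------------------------
        ycells = mask.axes()[1]
        if inlet_profile is None:
            D = mask.vessel.width
            s = np.clip(ycells / D, 0.0, 1.0)
            profile = scenario.u_max_inflow * 4.0 * s * (1.0 - s)
        else:
            profile = np.asarray(inlet_profile(ycells), dtype=float)
        self.inlet_values = np.where(self.u_inlet[0], profile, 0.0)

        self._assemble_poisson()

        self.u = np.zeros((nx + 1, ny))
        self.v = np.zeros((nx, ny + 1))
        self.p = np.zeros((nx, ny))
        self.t = 0.0
        self.step_count = 0
        self.max_div_scaled = 0.0
        self._apply_bcs()

    # ------------------------------------------------------------------
    def _assemble_poisson(self) -> None:
        nx, ny = self.nx, self.ny
        F = self.F
        idx = -np.ones((nx, ny), dtype=np.intp)
        n = int(F.sum())
        idx[F] = np.arange(n)
        rows, cols, vals = [], [], []
        diag = np.zeros(n)

        # x-links through active u faces
        Lx = F[:-1] & F[1:]
        a, b = idx[:-1][Lx], idx[1:][Lx]
        rows += [a, b]
        cols += [b, a]
        vals += [-np.ones(a.size), -np.ones(a.size)]
        np.add.at(diag, a, 1.0)
        np.add.at(diag, b, 1.0)

        # y-links through active v faces (inlet/outlet columns excluded)
        Ly = F[:, :-1] & F[:, 1:]
        Ly[0] = False
        Ly[-1] = False
        a, b = idx[:, :-1][Ly], idx[:, 1:][Ly]
        rows += [a, b]
        cols += [b, a]
        vals += [-np.ones(a.size), -np.ones(a.size)]
        np.add.at(diag, a, 1.0)
        np.add.at(diag, b, 1.0)

        # outlet Dirichlet p = 0 at the last axial face (ghost reflection)
        out = idx[-1][F[-1]]
        np.add.at(diag, out, 2.0)

        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        A = coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsc()
        self._idx = idx
        self._lu = splu(A / self.dx**2)

    # ------------------------------------------------------------------
    def _apply_bcs(self) -> None:
        u, v = self.u, self.v
        u[~self.u_in_fluid] = 0.0
        u[0] = self.inlet_values
        u[-1] = np.where(self.u_outlet[-1], u[-2], 0.0)
        v[~self.v_active] = 0.0

    def _ghosted_y_neighbors(self, u):
        """u at (i, j+1) and (i, j-1) with wall-reflection ghosts."""
        uN = np.zeros_like(u)
        uN[:, :-1] = u[:, 1:]
        validN = np.zeros_like(self.u_in_fluid)
        validN[:, :-1] = self.u_in_fluid[:, 1:]
        uN = np.where(validN, uN, 2.0 * self.moving_wall_u - u)
        uS = np.zeros_like(u)
        uS[:, 1:] = u[:, :-1]
        validS = np.zeros_like(self.u_in_fluid)
        validS[:, 1:] = self.u_in_fluid[:, :-1]
        uS = np.where(validS, uS, -u)
        return uS, uN

    def _ghosted_x_neighbors(self, v):
        vE = np.zeros_like(v)
        vE[:-1] = v[1:]
        validE = np.zeros_like(self.v_in_fluid)
        validE[:-1] = self.v_in_fluid[1:]
        vE = np.where(validE, vE, -v)
        vW = np.zeros_like(v)
        vW[1:] = v[:-1]
        validW = np.zeros_like(self.v_in_fluid)
        validW[1:] = self.v_in_fluid[:-1]
        vW = np.where(validW, vW, -v)
        return vW, vE

    def step(self, n: int = 1) -> None:
        for _ in range(n):
            self._step_once()

    def _step_once(self) -> None:
        dx, dt, nu = self.dx, self.dt, self.nu
        u, v = self.u, self.v
        self._apply_bcs()

        # ---- predictor for u -------------------------------------------
        uE = np.zeros_like(u)
        uE[:-1] = u[1:]
        uW = np.zeros_like(u)
        uW[1:] = u[:-1]
        uS, uN = self._ghosted_y_neighbors(u)
        vbar = np.zeros_like(u)
        vbar[1:-1] = 0.25 * (v[:-1, :-1] + v[1:, :-1] + v[:-1, 1:] + v[1:, 1:])
        dudx = np.where(u > 0, (u - uW) / dx, (uE - u) / dx)
        dudy = np.where(vbar > 0, (u - uS) / dx, (uN - u) / dx)
        lap_u = (uE + uW + uN + uS - 4.0 * u) / dx**2
        ustar = u + dt * (nu * lap_u - (u * dudx + vbar * dudy))
        ustar = np.where(self.u_active, ustar, u)

        # ---- predictor for v -------------------------------------------
        vN = np.zeros_like(v)
        vN[:, :-1] = v[:, 1:]
        vS = np.zeros_like(v)
        vS[:, 1:] = v[:, :-1]
        vW, vE = self._ghosted_x_neighbors(v)
        ubar = np.zeros_like(v)
        ubar[:, 1:-1] = 0.25 * (u[:-1, :-1] + u[1:, :-1] + u[:-1, 1:] + u[1:, 1:])
        dvdx = np.where(ubar > 0, (v - vW) / dx, (vE - v) / dx)
        dvdy = np.where(v > 0, (v - vS) / dx, (vN - v) / dx)
        lap_v = (vE + vW + vN + vS - 4.0 * v) / dx**2
        vstar = v + dt * (nu * lap_v - (ubar * dvdx + v * dvdy))
        vstar = np.where(self.v_active, vstar, v)

        # outlet zero-gradient on the predictor
        ustar[-1] = np.where(self.u_outlet[-1], ustar[-2], 0.0)

        # ---- pressure projection ---------------------------------------
        div = divergence(ustar, vstar, dx, self.F)
        rhs = -(self.rho / dt) * div[self.F]
        p = self._lu.solve(rhs)
        p_full = np.zeros((self.nx, self.ny))
        p_full[self.F] = p

        gx = (p_full[1:] - p_full[:-1]) / dx
        ustar[1:-1] = np.where(
            self.u_active[1:-1], ustar[1:-1] - (dt / self.rho) * gx, ustar[1:-1]
        )
        # outlet face: Dirichlet p = 0 half a cell beyond the last centre
        ustar[-1] = np.where(
            self.u_outlet[-1],
            ustar[-1] - (dt / self.rho) * (0.0 - p_full[-1]) * 2.0 / dx,
            0.0,
        )
        gy = (p_full[:, 1:] - p_full[:, :-1]) / dx
        vstar[:, 1:-1] = np.where(
            self.v_active[:, 1:-1], vstar[:, 1:-1] - (dt / self.rho) * gy, vstar[:, 1:-1]
        )

        # no trailing BC reset: the projected field satisfies the discrete
        # continuity equation exactly; BCs are re-applied at the next step
        self.u, self.v, self.p = ustar, vstar, p_full
        self.t += dt
        self.step_count += 1

        div_after = divergence(self.u, self.v, dx, self.F)
        scaled = float(np.abs(div_after).max()) * dx / self.scenario.u_max_inflow
        self.max_div_scaled = max(self.max_div_scaled, scaled)

    # ------------------------------------------------------------------
    def velocity_cell_centered(self) -> np.ndarray:
        uc = 0.5 * (self.u[:-1] + self.u[1:])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        out = np.stack([uc, vc])
        out[:, ~self.F] = 0.0
        return out

    def field(self) -> FlowField:
        return FlowField(
            u=self.velocity_cell_centered(),
            p=self.p.copy(),
            u_face=self.u.copy(),
            v_face=self.v.copy(),
            dx=self.dx,
            t=self.t,
            mask=self.mask,
        )

    def run_to_steady(self, criterion: SteadyStateCriterion | None = None) -> ConvergenceReport:
        crit = criterion or SteadyStateCriterion()
        u_prev = self.velocity_cell_centered()
        residual = math.inf
        history: list = []
        steps_done = 0
        while steps_done < crit.max_steps:
            n = min(crit.check_interval, crit.max_steps - steps_done)
            self.step(n)
            steps_done += n
            uc = self.velocity_cell_centered()
            if not np.all(np.isfinite(uc)):
                raise StabilityError(f"NaN/Inf after {self.step_count} NS steps")
            umax = float(np.sqrt((uc**2).sum(axis=0)).max())
            residual = float(np.abs(uc - u_prev).max() / (umax + 1e-300))
            history.append((steps_done, residual))
            u_prev = uc
            if residual < crit.tolerance:
                return ConvergenceReport(True, steps_done, residual, history)
        return ConvergenceReport(False, steps_done, residual, history)


def solve_ns(
    mask: DomainMask,
    scenario: FlowScenario,
    dt: float | None = None,
    criterion: SteadyStateCriterion | None = None,
    **kwargs,
):
    """Run the reference solver to steady state; returns (FlowField, report)."""
    solver = NSSolver2D(mask, scenario, dt=dt, **kwargs)
    report = solver.run_to_steady(criterion)
    return solver.field(), report
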