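"""Single-relaxation-time (BGK) lattice Boltzmann solver on D2Q9 / D3Q19.

Per lattice node and discrete direction e_i the particle distribution
function f_i evolves by collision and streaming,

    f_i(x + e_i, t + 1) - f_i(x, t) = -(f_i - f_i^eq) / tau,

with the low-Mach quadratic equilibrium

    f_i^eq = w_i rho (1 + 3 e_i.u + 9/2 (e_i.u)^2 - 3/2 u.u)

and macroscopic moments rho = sum_i f_i, rho u = sum_i f_i e_i.  The lattice
kinematic viscosity is nu = (tau - 1/2)/3.  No-slip walls use full-way
bounce-back (opposite-PDF swap at solid nodes; the effective wall sits half a
cell beyond the last fluid node).  The inlet imposes a parabolic velocity
Dirichlet condition via equilibrium PDFs with density extrapolated from the
first interior column; the outlet is a zero-gradient (Neumann) copy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, StabilityError
from .geometry import DomainMask, NodeClass
from .units import LATTICE_SOUND_SPEED, UnitSystem


# ---------------------------------------------------------------------------
# Lattice stencils
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatticeModel:
    """Discrete velocity set: directions e_i, weights w_i, opposite map."""

    name: str
    e: np.ndarray       # (q, d) int
    w: np.ndarray       # (q,)
    opp: np.ndarray     # (q,) index of -e_i

    @property
    def q(self) -> int:
        return self.e.shape[0]

    @property
    def d(self) -> int:
        return self.e.shape[1]


def _opposite_map(e: np.ndarray) -> np.ndarray:
    opp = np.empty(len(e), dtype=np.intp)
    for i, ei in enumerate(e):
        (j,) = np.nonzero((e == -ei).all(axis=1))[0]
        opp[i] = j
    return opp


def d2q9() -> LatticeModel:
    e = np.array(
        [[0, 0],
         [1, 0], [-1, 0], [0, 1], [0, -1],
         [1, 1], [-1, -1], [1, -1], [-1, 1]],
        dtype=np.intp,
    )
    w = np.array([4 / 9] + [1 / 9] * 4 + [1 / 36] * 4)
    return LatticeModel("D2Q9", e, w, _opposite_map(e))


def d3q19() -> LatticeModel:
    axis = [v for v in
            ([1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1])]
    diag = []
    for a in range(3):
        for b in range(a + 1, 3):
            for sa in (1, -1):
                for sb in (1, -1):
                    v = [0, 0, 0]
                    v[a], v[b] = sa, sb
                    diag.append(v)
    e = np.array([[0, 0, 0]] + axis + diag, dtype=np.intp)
    w = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12)
    return LatticeModel("D3Q19", e, w, _opposite_map(e))


_MODELS = {"D2Q9": d2q9, "D3Q19": d3q19}


def get_model(name: str) -> LatticeModel:
    try:
        return _MODELS[name]()
    except KeyError:
        raise ConfigurationError(f"unknown lattice model {name!r}") from None


# ---------------------------------------------------------------------------
# Kernel operations
# ---------------------------------------------------------------------------

def equilibrium(rho, u, model: LatticeModel, check: bool = True) -> np.ndarray:
    """Equilibrium PDFs f_i^eq for density rho and lattice velocity u.

    ``rho`` may be scalar or a field of shape S; ``u`` has shape (d,) or
    (d, *S).  Returns shape (q, *S).
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    if u.shape[0] != model.d:
        raise ConfigurationError(
            f"velocity has {u.shape[0]} components, model {model.name} needs {model.d}"
        )
    if check:
        speed = np.sqrt((u**2).sum(axis=0))
        if np.any(speed >= LATTICE_SOUND_SPEED):
            raise StabilityError(
                f"|u|={float(np.max(speed)):.4f} >= lattice sound speed "
                f"{LATTICE_SOUND_SPEED:.4f}: low-Mach violation"
            )
    eu = np.tensordot(model.e.astype(float), u, axes=(1, 0))  # (q, *S)
    usq = (u**2).sum(axis=0)
    w = model.w.reshape((model.q,) + (1,) * (eu.ndim - 1))
    return w * rho * (1.0 + 3.0 * eu + 4.5 * eu**2 - 1.5 * usq)


def moments(f: np.ndarray, model: LatticeModel, check: bool = True):
    """Macroscopic moments (rho, u) of a PDF array of shape (q, *S)."""
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise StabilityError("non-finite PDF values")
    rho = f.sum(axis=0)
    if check and np.any(rho <= 0):
        raise StabilityError("degenerate node: non-positive density")
    mom = np.einsum("q...,qd->d...", f, model.e.astype(float))
    return rho, mom / rho


# ---------------------------------------------------------------------------
# Convergence control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteadyStateCriterion:
    """Stationarity test: stop when the max-node velocity change over one
    check interval, relative to the max velocity magnitude, drops below
    ``tolerance``."""

    tolerance: float = 1.0e-6
    check_interval: int = 100
    max_steps: int = 200_000

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ConfigurationError("tolerance must be >= 0")
        if self.check_interval < 1:
            raise ConfigurationError("check_interval must be >= 1")
        if self.max_steps < self.check_interval:
            raise ConfigurationError("max_steps must be >= check_interval")


@dataclass
class ConvergenceReport:
    converged: bool
    steps: int
    residual: float
    history: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "converged": self.converged,
            "steps": self.steps,
            "residual": self.residual,
            "history": list(self.history),
        }


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

class LBMSolver:
    """BGK lattice Boltzmann solver bound to a domain mask and unit system.

    Step order: collide -> stream -> bounce-back -> inlet -> outlet.
    All state is kept in lattice units; conversions go through ``units``.
    """

    def __init__(
        self,
        mask: DomainMask,
        units: UnitSystem,
        model: LatticeModel | None = None,
    ) -> None:
        if model is None:
            model = d2q9() if mask.ndim == 2 else d3q19()
        if model.d != mask.ndim:
            raise ConfigurationError(
                f"lattice model {model.name} is {model.d}D but mask is {mask.ndim}D"
            )
        self.mask = mask
        self.units = units
        self.model = model
        self.step_count = 0

        self._fluidish = mask.fluid                       # fluid | inlet | outlet
        self._solid = ~self._fluidish
        self._inlet = mask.classes == NodeClass.INLET
        self._outlet = mask.classes == NodeClass.OUTLET
        self._axes = tuple(range(mask.ndim))
        self._inlet_profile = self._build_inlet_profile()
        self.f = self._initial_pdfs()

    # -- boundary profiles ------------------------------------------------
    def _parabolic_velocity(self, coords: list[np.ndarray]) -> np.ndarray:
        """Lattice-unit parabolic axial profile over the full grid."""
        D = self.mask.vessel.width
        u_lat = self.units.u_lattice_max
        if self.mask.ndim == 2:
            y = coords[1]
            s = np.clip(y / D, 0.0, 1.0)
            prof = 4.0 * s * (1.0 - s)
        else:
            r2 = coords[1] ** 2 + coords[2] ** 2
            prof = np.clip(1.0 - r2 / (D / 2) ** 2, 0.0, None)
        return u_lat * prof

    def _build_inlet_profile(self) -> np.ndarray:
        coords = self.mask.meshgrid()
        return self._parabolic_velocity(coords)[0][self._inlet[0]]

    def _initial_pdfs(self) -> np.ndarray:
        """Start from the parabolic channel flow (zero in the sac): a
        deterministic initial guess close to the steady lumen solution."""
        coords = self.mask.meshgrid()
        ux = np.where(self._fluidish, self._parabolic_velocity(coords), 0.0)
        if self.mask.ndim == 2:
            in_lumen = coords[1] <= self.mask.vessel.width
        else:
            in_lumen = coords[1] ** 2 + coords[2] ** 2 <= (self.mask.vessel.width / 2) ** 2
        ux = np.where(in_lumen, ux, 0.0)
        u = np.zeros((self.model.d,) + self.mask.shape)
        u[0] = ux
        return equilibrium(np.ones(self.mask.shape), u, self.model, check=False)

    # -- kernel -----------------------------------------------------------
    def collide(self) -> None:
        rho = self.f.sum(axis=0)
        mom = np.einsum("q...,qd->d...", self.f, self.model.e.astype(float))
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(rho > 0, mom / np.where(rho > 0, rho, 1.0), 0.0)
        feq = equilibrium(rho, u, self.model, check=False)
        relaxed = self.f - (self.f - feq) / self.units.tau
        self.f = np.where(self._fluidish, relaxed, self.f)

    def stream(self) -> None:
        for i in range(1, self.model.q):
            self.f[i] = np.roll(self.f[i], shift=tuple(self.model.e[i]), axis=self._axes)

    def bounce_back(self) -> None:
        solid = self._solid
        fs = self.f[:, solid]
        self.f[:, solid] = fs[self.model.opp]

    def apply_inlet(self) -> None:
        rows = self._inlet[0]
        rho_in = self.f[:, 1][:, rows].sum(axis=0)  # extrapolate from interior
        u = np.zeros((self.model.d, rows.sum()))
        u[0] = self._inlet_profile
        self.f[:, 0, ...][:, rows] = equilibrium(rho_in, u, self.model, check=False)

    def apply_outlet(self) -> None:
        # zero-gradient copy, rescaled to the lattice reference density: the
        # velocity (a PDF-scale-invariant moment) keeps its zero gradient
        # while the outlet anchors the otherwise-indeterminate pressure level
        rows = self._outlet[-1]
        upstream = self.f[:, -2, ...][:, rows]
        rho_up = upstream.sum(axis=0)
        self.f[:, -1, ...][:, rows] = upstream / np.where(rho_up > 0, rho_up, 1.0)

    def step(self, n: int = 1) -> None:
        for _ in range(n):
            self.collide()
            self.stream()
            self.bounce_back()
            self.apply_inlet()
            self.apply_outlet()
            self.step_count += 1

    # -- observables ------------------------------------------------------
    def macroscopic(self):
        """(rho, u) lattice-unit fields; zero velocity on solid nodes."""
        rho = self.f.sum(axis=0)
        mom = np.einsum("q...,qd->d...", self.f, self.model.e.astype(float))
        safe = np.where(self._fluidish & (rho > 0), rho, 1.0)
        u = mom / safe
        u = np.where(self._fluidish, u, 0.0)
        return rho, u

    def velocity_physical(self) -> np.ndarray:
        """Velocity field in m/s, shape (d, *grid), zero on solid nodes."""
        _, u = self.macroscopic()
        return self.units.velocity_to_physical(u)

    def total_mass(self) -> float:
        return float(self.f.sum())

    # -- time integration -------------------------------------------------
    def run_to_steady(self, criterion: SteadyStateCriterion | None = None) -> ConvergenceReport:
        crit = criterion or SteadyStateCriterion()
        _, u_prev = self.macroscopic()
        residual = math.inf
        history: list = []
        steps_done = 0
        while steps_done < crit.max_steps:
            n = min(crit.check_interval, crit.max_steps - steps_done)
            self.step(n)
            steps_done += n
            if not np.all(np.isfinite(self.f)):
                raise StabilityError(
                    f"NaN/Inf after {self.step_count} steps (tau={self.units.tau:.4f})"
                )
            _, u = self.macroscopic()
            umax = float(np.sqrt((u**2).sum(axis=0)).max())
            if umax >= LATTICE_SOUND_SPEED:
                raise StabilityError(
                    f"max |u|={umax:.4f} exceeds lattice sound speed "
                    f"(tau={self.units.tau:.4f}): diverging run"
                )
            residual = float(np.abs(u - u_prev).max() / (umax + 1e-300))
            history.append((steps_done, residual))
            u_prev = u
            if residual < crit.tolerance:
                return ConvergenceReport(True, steps_done, residual, history)
        return ConvergenceReport(False, steps_done, residual, history)


def run_to_steady(
    mask: DomainMask,
    units: UnitSystem,
    criterion: SteadyStateCriterion | None = None,
    model: LatticeModel | None = None,
):
    """Convenience wrapper: build a solver, iterate to steady state.

    Returns ``(solver, report)``; the steady velocity field in m/s is
    ``solver.velocity_physical()``.
    """
    solver = LBMSolver(mask, units, model=model)
    report = solver.run_to_steady(criterion)
    return solver, report
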