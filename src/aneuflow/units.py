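"""Physical <-> lattice unit conversion and nondimensional diagnostics.

The lattice Boltzmann solver works in lattice units (cell size 1, time step 1,
reference density 1).  A :class:`UnitSystem` ties those to SI units through the
cell size ``dx`` [m], the time step ``dt`` [s] and the BGK relaxation time
``tau``, which sets the lattice kinematic viscosity via

    nu_lattice = (tau - 1/2) / 3.

The default scenario is steady flow of blood (rho = 1060 kg/m^3,
mu = 0.004 Pa s) through a 3 mm vessel with a parabolic inflow peaking at
50 mm/s, i.e. Reynolds number ~ 20 (laminar).  The characteristic velocity for
the Reynolds number is the mean of the parabolic pipe profile, u_max / 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .exceptions import ConfigurationError

#: Lattice speed of sound for the standard D2Q9/D3Q19 stencils.
LATTICE_SOUND_SPEED = 1.0 / math.sqrt(3.0)


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid described by density and dynamic viscosity.

    Parameters
    ----------
    density : float
        Mass density rho in kg/m^3.
    dynamic_viscosity : float
        Dynamic viscosity mu in Pa s (kg/(m s)).
    """

    density: float
    dynamic_viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ConfigurationError(f"density must be > 0, got {self.density}")
        if self.dynamic_viscosity <= 0:
            raise ConfigurationError(
                f"dynamic_viscosity must be > 0, got {self.dynamic_viscosity}"
            )

    @property
    def kinematic_viscosity(self) -> float:
        """Kinematic viscosity nu = mu / rho in m^2/s."""
        return self.dynamic_viscosity / self.density


#: Whole blood treated as a Newtonian fluid.
BLOOD = FluidProperties(density=1060.0, dynamic_viscosity=0.004)


@dataclass(frozen=True)
class FlowScenario:
    """Steady channel/pipe inflow scenario.

    ``channel_width`` is the vessel width (2D channel) or diameter (3D tube)
    in meters; ``u_max_inflow`` the peak of the parabolic inflow in m/s.
    """

    channel_width: float
    u_max_inflow: float
    fluid: FluidProperties = BLOOD
    dimensionality: int = 2

    def __post_init__(self) -> None:
        if self.channel_width <= 0:
            raise ConfigurationError("channel_width must be > 0")
        if self.u_max_inflow <= 0:
            raise ConfigurationError("u_max_inflow must be > 0")
        if self.dimensionality not in (2, 3):
            raise ConfigurationError("dimensionality must be 2 or 3")

    @property
    def u_mean_inflow(self) -> float:
        """Mean of the parabolic inflow profile.

        2D plane channel: (2/3) u_max.  3D circular pipe: u_max / 2.
        """
        return (2.0 / 3.0 if self.dimensionality == 2 else 0.5) * self.u_max_inflow

    @property
    def u_characteristic(self) -> float:
        """Characteristic velocity used for the Reynolds number.

        Fixed to u_max / 2 (the mean of a circular-pipe parabolic profile) in
        both 2D and 3D so that the default scenario yields Re = 19.875.
        """
        return 0.5 * self.u_max_inflow


def default_scenario(dimensionality: int = 2) -> FlowScenario:
    """The default blood-in-a-3mm-vessel scenario at peak inflow 50 mm/s."""
    return FlowScenario(
        channel_width=3.0e-3,
        u_max_inflow=0.05,
        fluid=BLOOD,
        dimensionality=dimensionality,
    )


def lattice_viscosity(tau: float) -> float:
    """Lattice kinematic viscosity nu = (tau - 1/2)/3 of the BGK operator.

    Raises
    ------
    ConfigurationError
        If ``tau <= 0.5`` (non-positive viscosity).
    """
    if tau <= 0.5:
        raise ConfigurationError(
            f"relaxation time tau={tau} implies non-positive viscosity (need tau > 0.5)"
        )
    return (tau - 0.5) / 3.0


@dataclass(frozen=True)
class UnitSystem:
    """Mapping between physical (SI) and lattice units.

    Attributes
    ----------
    dx : float
        Physical size of one lattice cell [m].
    dt : float
        Physical duration of one lattice step [s].
    tau : float
        BGK relaxation time (dimensionless, > 0.5).
    u_lattice_max : float
        Peak inflow velocity in lattice units; kept < 0.1 so the low-Mach
        (weak compressibility) assumption of the LBM holds.
    """

    dx: float
    dt: float
    tau: float
    u_lattice_max: float

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dt <= 0:
            raise ConfigurationError("dx and dt must be > 0")
        if self.tau <= 0.5:
            raise ConfigurationError(f"tau={self.tau} must be > 0.5")
        if not 0 < self.u_lattice_max < 0.1:
            raise ConfigurationError(
                f"u_lattice_max={self.u_lattice_max} violates the low-Mach "
                "contract (need 0 < u < 0.1)"
            )

    @property
    def nu_lattice(self) -> float:
        return lattice_viscosity(self.tau)

    # -- conversions ------------------------------------------------------
    def velocity_to_lattice(self, u_physical):
        return u_physical * (self.dt / self.dx)

    def velocity_to_physical(self, u_lattice):
        return u_lattice * (self.dx / self.dt)

    def length_to_lattice(self, x_physical):
        return x_physical / self.dx

    def length_to_physical(self, x_lattice):
        return x_lattice * self.dx

    def time_to_lattice(self, t_physical):
        return t_physical / self.dt

    def time_to_physical(self, n_steps):
        return n_steps * self.dt

    def viscosity_to_physical(self) -> float:
        """Physical kinematic viscosity implied by tau, dx, dt [m^2/s]."""
        return self.nu_lattice * self.dx**2 / self.dt


def build_unit_system(
    scenario: FlowScenario,
    cells_across_width: int = 30,
    u_lattice_max: float = 0.05,
    max_tau: float = 2.0,
) -> UnitSystem:
    """Derive (dx, dt, tau) from a scenario and two free lattice parameters.

    dx = D / cells_across_width, dt = u_lattice_max * dx / u_max_inflow, and
    tau follows from matching the physical kinematic viscosity:
    nu_lattice = nu_phys * dt / dx^2, tau = 3 nu_lattice + 1/2.

    Raises
    ------
    ConfigurationError
        If the resulting tau falls outside (0.5, max_tau]; BGK is formally
        stable for any tau > 0.5 but accuracy degrades for large tau, so the
        default cap is 2 (raise ``max_tau`` to override).
    """
    if cells_across_width < 8:
        raise ConfigurationError(
            f"cells_across_width={cells_across_width} too coarse (need >= 8)"
        )
    if not 0 < u_lattice_max < 0.1:
        raise ConfigurationError(
            f"u_lattice_max={u_lattice_max} outside (0, 0.1): low-Mach contract"
        )
    dx = scenario.channel_width / cells_across_width
    dt = u_lattice_max * dx / scenario.u_max_inflow
    nu_lattice = scenario.fluid.kinematic_viscosity * dt / dx**2
    tau = 3.0 * nu_lattice + 0.5
    if not 0.5 < tau <= max_tau:
        raise ConfigurationError(
            f"derived tau={tau:.4f} outside (0.5, {max_tau}]: adjust "
            "cells_across_width or u_lattice_max"
        )
    return UnitSystem(dx=dx, dt=dt, tau=tau, u_lattice_max=u_lattice_max)


def reynolds_number(fluid: FluidProperties, u_characteristic: float, diameter: float) -> float:
    """Re = rho u D / mu.

    With the default scenario (blood, D = 3 mm, u = u_max/2 = 25 mm/s) this
    evaluates to 19.875.
    """
    if u_characteristic <= 0:
        raise ConfigurationError("u_characteristic must be > 0")
    if diameter <= 0:
        raise ConfigurationError("diameter must be > 0")
    return fluid.density * u_characteristic * diameter / fluid.dynamic_viscosity


def mach_number(u_lattice_max: float) -> float:
    """Lattice Mach number u / c_s with c_s = 1/sqrt(3).

    Warns above 0.17 where compressibility errors (which scale with Ma^2)
    start to matter.
    """
    if u_lattice_max < 0:
        raise ConfigurationError("u_lattice_max must be >= 0")
    ma = u_lattice_max / LATTICE_SOUND_SPEED
    if ma > 0.17:
        warnings.warn(
            f"Mach number {ma:.3f} > 0.17: compressibility error may be significant",
            stacklevel=2,
        )
    return ma
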