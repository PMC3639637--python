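"""Synthetic aneurysm-bearing vessel geometry and its rasterization.

The study domain is a straight vessel (2D plane channel of width D, or 3D
circular tube of diameter D) carrying a saccular sidewall aneurysm at one of
two growth stages ("medium", "larger").  The sac is a circle (2D) / sphere
(3D) whose centre sits outside the vessel wall such that the opening between
sac and lumen — the neck — has a prescribed width.  An optional coarse
endoluminal stent is modelled as a row of circular struts spanning the neck;
the default 5 struts leave exactly 4 gaps.

All shapes are described by signed distance level sets (negative inside
fluid) and rasterized onto a uniform cell-centered grid, from which the
solvers derive their fluid/solid/inlet/outlet node masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .exceptions import GeometryError

Shape = Callable[..., np.ndarray]  # phi(X, Y[, Z]) -> signed distance field


class NodeClass(IntEnum):
    SOLID = 0
    FLUID = 1
    INLET = 2
    OUTLET = 3


#: Default sac radii per growth stage [m] and shared neck width [m]; chosen so
#: the 45-degree mid cutline through the neck spans 5 mm (medium) / 6 mm
#: (larger) including a short lumen-side overhang.
SAC_RADIUS = {"medium": 2.25e-3, "larger": 3.0e-3}
NECK_WIDTH_DEFAULT = 2.0e-3
MID_CUTLINE_LENGTH = {"medium": 5.0e-3, "larger": 6.0e-3}


@dataclass(frozen=True)
class VesselSpec:
    """Straight vessel: 2D plane channel or 3D circular tube."""

    width: float = 3.0e-3       # channel width / tube diameter [m]
    length: float = 15.0e-3     # axial length [m]
    dimensionality: int = 2

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise GeometryError("vessel width and length must be > 0")
        if self.length < 4 * self.width:
            raise GeometryError(
                f"length {self.length} < 4 x width {self.width}: no room for "
                "pre/post cutlines"
            )
        if self.dimensionality not in (2, 3):
            raise GeometryError("dimensionality must be 2 or 3")


@dataclass(frozen=True)
class AneurysmSpec:
    """Saccular sidewall aneurysm at a growth stage.

    ``neck_center`` is the axial position of the neck midpoint [m];
    ``neck_angle_deg`` the angle of the mid cutline relative to the vessel
    axis (45 degrees by convention).
    """

    stage: str = "medium"                 # none | medium | larger
    sac_radius: float = SAC_RADIUS["medium"]
    neck_width: float = NECK_WIDTH_DEFAULT
    neck_center: float = 7.5e-3
    neck_angle_deg: float = 45.0

    def __post_init__(self) -> None:
        if self.stage not in ("none", "medium", "larger"):
            raise GeometryError(f"unknown aneurysm stage {self.stage!r}")
        if self.stage != "none":
            if self.neck_width >= 2 * self.sac_radius:
                raise GeometryError(
                    "neck_width must be smaller than the sac diameter"
                )

    @classmethod
    def from_stage(cls, stage: str, vessel: VesselSpec) -> "AneurysmSpec":
        if stage == "none":
            return cls(stage="none", neck_center=vessel.length / 2)
        return cls(
            stage=stage,
            sac_radius=SAC_RADIUS[stage],
            neck_width=NECK_WIDTH_DEFAULT,
            neck_center=vessel.length / 2,
        )

    @property
    def wall_offset(self) -> float:
        """Distance of the sac centre from the wall line/surface [m]."""
        return math.sqrt(self.sac_radius**2 - (self.neck_width / 2) ** 2)


@dataclass(frozen=True)
class StentSpec:
    """Coarse endoluminal stent: circular struts spanning the neck.

    Struts are evenly spaced across the neck opening (first and last strut
    centred on the neck corners), so ``n_struts`` struts leave
    ``n_struts - 1`` gaps; the default 5 struts leave 4 gaps.
    """

    n_struts: int = 5
    strut_diameter: float = 0.2e-3

    def __post_init__(self) -> None:
        if self.n_struts < 2:
            raise GeometryError("a stent needs at least 2 struts")
        if self.strut_diameter <= 0:
            raise GeometryError("strut_diameter must be > 0")

    def strut_positions(self, aneurysm: AneurysmSpec) -> np.ndarray:
        """Axial strut-centre positions across the neck [m]."""
        half = aneurysm.neck_width / 2
        return aneurysm.neck_center + np.linspace(-half, half, self.n_struts)

    @property
    def n_gaps(self) -> int:
        return self.n_struts - 1


@dataclass(frozen=True)
class CutlineSpec:
    """Straight sampling segment through the domain.

    ``neck_span`` (optional) marks the arc-length interval [m] of the segment
    that lies inside the neck aperture; used to restrict peak-velocity
    queries to the neck opening.
    """

    name: str
    start: tuple
    end: tuple
    n_samples: int = 101
    neck_span: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise GeometryError("n_samples must be >= 2")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.end) - np.asarray(self.start)))

    def points(self) -> np.ndarray:
        """(n_samples, dim) evenly spaced sample coordinates [m]."""
        t = np.linspace(0.0, 1.0, self.n_samples)[:, None]
        a = np.asarray(self.start, dtype=float)
        b = np.asarray(self.end, dtype=float)
        return a + t * (b - a)

    def arclength(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_samples)


@dataclass
class DomainMask:
    """Rasterized domain: node classes and level-set field on a uniform grid.

    Grid convention: cell-centered nodes, 0-based indices, first axis is the
    vessel axis (x); node centre i has coordinate origin + (i + 0.5) dx.  A
    node is solid iff its centre lies in the solid phase (phi >= 0).
    """

    classes: np.ndarray          # NodeClass values, shape (nx, ny[, nz])
    phi: np.ndarray              # signed distance, negative in fluid
    dx: float
    origin: tuple                # coordinate of the grid corner (not a centre)
    vessel: VesselSpec
    aneurysm: AneurysmSpec | None = None
    stent: StentSpec | None = None

    @property
    def shape(self) -> tuple:
        return self.classes.shape

    @property
    def ndim(self) -> int:
        return self.classes.ndim

    @property
    def fluid(self) -> np.ndarray:
        """Boolean mask of all non-solid (fluid, inlet, outlet) nodes."""
        return self.classes != NodeClass.SOLID

    @property
    def n_fluid(self) -> int:
        return int(np.count_nonzero(self.fluid))

    def axes(self) -> list[np.ndarray]:
        """Cell-centre coordinates along each axis [m]."""
        return [
            self.origin[d] + (np.arange(n) + 0.5) * self.dx
            for d, n in enumerate(self.shape)
        ]

    def meshgrid(self) -> list[np.ndarray]:
        return list(np.meshgrid(*self.axes(), indexing="ij"))


# ---------------------------------------------------------------------------
# Level-set primitives (signed distance, negative inside fluid)
# ---------------------------------------------------------------------------

def sdf_slab(y: np.ndarray, width: float) -> np.ndarray:
    """Fluid slab 0 <= y <= width (a plane channel)."""
    return np.maximum(-y, y - width)


def sdf_circle(coords: Sequence[np.ndarray], center: Sequence[float], radius: float) -> np.ndarray:
    """Fluid disc/sphere of given centre and radius."""
    d2 = sum((c - c0) ** 2 for c, c0 in zip(coords, center))
    return np.sqrt(d2) - radius


def sdf_tube(y: np.ndarray, z: np.ndarray, radius: float) -> np.ndarray:
    """Fluid circular tube of given radius around the x axis."""
    return np.sqrt(y**2 + z**2) - radius


def rasterize_levelset(shapes: Sequence[np.ndarray]) -> np.ndarray:
    """CSG union of fluid level sets: pointwise minimum.

    Each entry is an already-evaluated signed distance field (negative in
    fluid); the union of fluid regions is their pointwise minimum.
    """
    if len(shapes) == 0:
        raise GeometryError("rasterize_levelset needs at least one shape")
    phi = shapes[0]
    for s in shapes[1:]:
        phi = np.minimum(phi, s)
    return phi


def subtract_levelset(phi: np.ndarray, solid_shape: np.ndarray) -> np.ndarray:
    """Remove a fluid region (make it solid): max(phi, -phi_solid_shape)."""
    return np.maximum(phi, -solid_shape)


# ---------------------------------------------------------------------------
# Domain construction
# ---------------------------------------------------------------------------

def _grid_axes_2d(vessel: VesselSpec, aneurysm: AneurysmSpec | None, dx: float,
                  margin_cells: int = 2):
    y_top = vessel.width
    if aneurysm is not None and aneurysm.stage != "none":
        y_top = vessel.width + aneurysm.wall_offset + aneurysm.sac_radius
    nx = int(round(vessel.length / dx))
    y_lo = -margin_cells * dx
    y_hi = y_top + margin_cells * dx
    ny = int(math.ceil((y_hi - y_lo) / dx))
    return nx, ny, (0.0, y_lo)


def _grid_axes_3d(vessel: VesselSpec, aneurysm: AneurysmSpec | None, dx: float,
                  margin_cells: int = 2):
    R = vessel.width / 2
    z_top = R
    y_half = R
    if aneurysm is not None and aneurysm.stage != "none":
        z_top = _sac_center_offset_3d(vessel, aneurysm) + aneurysm.sac_radius
        y_half = max(R, aneurysm.sac_radius)  # sac sphere may be wider than the tube
    nx = int(round(vessel.length / dx))
    y_lo = -y_half - margin_cells * dx
    y_hi = y_half + margin_cells * dx
    ny = int(math.ceil((y_hi - y_lo) / dx))
    z_lo = -R - margin_cells * dx
    z_hi = z_top + margin_cells * dx
    nz = int(math.ceil((z_hi - z_lo) / dx))
    return nx, ny, nz, (0.0, y_lo, z_lo)


def _sac_center_offset_3d(vessel: VesselSpec, aneurysm: AneurysmSpec) -> float:
    """Distance of the 3D sac centre from the tube axis.

    Chosen so the circle of intersection (the neck aperture) has the
    prescribed neck width: the radical plane of tube-wall and sac spheres.
    """
    R = vessel.width / 2
    w2 = aneurysm.neck_width / 2
    return math.sqrt(R**2 - w2**2) + math.sqrt(aneurysm.sac_radius**2 - w2**2)


def build_domain(
    vessel: VesselSpec,
    aneurysm: AneurysmSpec | None = None,
    stent: StentSpec | None = None,
    resolution: int = 30,
    margin_cells: int = 2,
) -> DomainMask:
    """Rasterize vessel + sac + stent to a watertight node mask.

    ``resolution`` is the number of cells across the vessel width.  Inlet and
    outlet are the fluid nodes of the first and last axial grid column.
    """
    if resolution < 8:
        raise GeometryError(f"resolution={resolution} too coarse (need >= 8)")
    if aneurysm is not None and aneurysm.stage == "none":
        aneurysm = None
    dx = vessel.width / resolution

    if aneurysm is not None:
        lo = aneurysm.neck_center - aneurysm.sac_radius
        hi = aneurysm.neck_center + aneurysm.sac_radius
        if lo < vessel.width or hi > vessel.length - vessel.width:
            raise GeometryError(
                "aneurysm sac overlaps the inlet/outlet region: move "
                "neck_center or lengthen the vessel"
            )
    if stent is not None and aneurysm is None:
        raise GeometryError("a stent requires an aneurysm to span")

    if vessel.dimensionality == 2:
        nx, ny, origin = _grid_axes_2d(vessel, aneurysm, dx, margin_cells)
        shape = (nx, ny)
        x = origin[0] + (np.arange(nx) + 0.5) * dx
        y = origin[1] + (np.arange(ny) + 0.5) * dx
        X, Y = np.meshgrid(x, y, indexing="ij")
        parts = [sdf_slab(Y, vessel.width)]
        if aneurysm is not None:
            center = (aneurysm.neck_center, vessel.width + aneurysm.wall_offset)
            parts.append(sdf_circle((X, Y), center, aneurysm.sac_radius))
        phi = rasterize_levelset(parts)
        if stent is not None:
            # struts sit inside the lumen, tangent to the wall line from
            # below, spanning the neck opening
            y_strut = vessel.width - stent.strut_diameter / 2
            for xs in stent.strut_positions(aneurysm):
                strut = sdf_circle((X, Y), (xs, y_strut), stent.strut_diameter / 2)
                phi = subtract_levelset(phi, strut)
    else:
        nx, ny, nz, origin = _grid_axes_3d(vessel, aneurysm, dx, margin_cells)
        shape = (nx, ny, nz)
        x = origin[0] + (np.arange(nx) + 0.5) * dx
        y = origin[1] + (np.arange(ny) + 0.5) * dx
        z = origin[2] + (np.arange(nz) + 0.5) * dx
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        R = vessel.width / 2
        parts = [sdf_tube(Y, Z, R)]
        if aneurysm is not None:
            center = (aneurysm.neck_center, 0.0, _sac_center_offset_3d(vessel, aneurysm))
            parts.append(sdf_circle((X, Y, Z), center, aneurysm.sac_radius))
        phi = rasterize_levelset(parts)
        if stent is not None:
            z_neck = math.sqrt(R**2 - (aneurysm.neck_width / 2) ** 2)
            z_strut = z_neck - stent.strut_diameter / 2
            for xs in stent.strut_positions(aneurysm):
                # strut axis along y, inside the lumen tangent to the aperture
                strut = sdf_circle((X, Z), (xs, z_strut), stent.strut_diameter / 2)
                phi = subtract_levelset(phi, strut)

    classes = np.where(phi < 0, NodeClass.FLUID, NodeClass.SOLID).astype(np.uint8)
    classes[0][classes[0] == NodeClass.FLUID] = NodeClass.INLET
    classes[-1][classes[-1] == NodeClass.FLUID] = NodeClass.OUTLET

    mask = DomainMask(
        classes=classes, phi=phi, dx=dx, origin=origin,
        vessel=vessel, aneurysm=aneurysm, stent=stent,
    )
    validate_watertight(mask)
    return mask


def validate_watertight(mask: DomainMask) -> None:
    """Raise GeometryError if fluid leaks to the transverse grid boundary or
    the inlet cannot reach the outlet through fluid."""
    fluid = mask.fluid
    # transverse boundaries (all axes except the first) must be solid
    for axis in range(1, mask.ndim):
        lo = np.take(fluid, 0, axis=axis)
        hi = np.take(fluid, fluid.shape[axis] - 1, axis=axis)
        if lo.any() or hi.any():
            raise GeometryError("fluid touches a transverse grid boundary (leak)")
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    labels, _ = ndimage.label(fluid, structure=structure)
    inlet_labels = set(np.unique(labels[mask.classes == NodeClass.INLET])) - {0}
    outlet_labels = set(np.unique(labels[mask.classes == NodeClass.OUTLET])) - {0}
    if not inlet_labels or not outlet_labels:
        raise GeometryError("domain has no inlet or no outlet fluid nodes")
    if not (inlet_labels & outlet_labels):
        raise GeometryError("inlet and outlet are not connected through fluid")


def sac_region(mask: DomainMask, aneurysm: AneurysmSpec | None = None) -> np.ndarray:
    """Boolean mask of fluid nodes inside the sac (outside the vessel lumen).

    Deterministic for fixed inputs; the lumen is the unperturbed vessel
    interior, so sac nodes are fluid nodes beyond the wall line/surface.
    """
    aneurysm = aneurysm if aneurysm is not None else mask.aneurysm
    if aneurysm is None or aneurysm.stage == "none":
        raise GeometryError("sac_region requires an aneurysm (stage != 'none')")
    coords = mask.meshgrid()
    if mask.ndim == 2:
        outside_lumen = coords[1] > mask.vessel.width
    else:
        outside_lumen = coords[1] ** 2 + coords[2] ** 2 > (mask.vessel.width / 2) ** 2
    return mask.fluid & outside_lumen


def lumen_region(mask: DomainMask) -> np.ndarray:
    """Fluid nodes inside the unperturbed vessel lumen."""
    if mask.aneurysm is None:
        return mask.fluid
    return mask.fluid & ~sac_region(mask)


def count_neck_gaps(mask: DomainMask) -> int:
    """Number of connected fluid intervals across the neck line at strut
    level (2D).  The default 5-strut stent yields exactly 4 gaps."""
    if mask.stent is None or mask.aneurysm is None:
        raise GeometryError("count_neck_gaps requires a stented aneurysm mask")
    if mask.ndim != 2:
        raise GeometryError("count_neck_gaps is defined for 2D masks")
    xs, ys = mask.axes()
    y_level = mask.vessel.width - mask.stent.strut_diameter / 2
    j = int(np.argmin(np.abs(ys - y_level)))
    half = mask.aneurysm.neck_width / 2
    sel = (xs >= mask.aneurysm.neck_center - half) & (
        xs <= mask.aneurysm.neck_center + half
    )
    row = mask.fluid[sel, j]
    # count runs of fluid cells
    return int(np.count_nonzero(row[1:] & ~row[:-1]) + (1 if row.size and row[0] else 0))


def make_cutlines(
    aneurysm: AneurysmSpec,
    vessel: VesselSpec,
    n_samples: int = 101,
) -> dict[str, CutlineSpec]:
    """The three standard sampling cutlines: pre, mid, post.

    pre/post are perpendicular to the vessel axis, one vessel-width long
    (3 mm by default), placed 1 mm outside the neck corners.  mid passes
    through the neck midpoint at the neck angle (45 degrees) and is 5 mm
    (medium) or 6 mm (larger) long, centred on the neck midpoint; its
    ``neck_span`` marks the sac-side half of the neck aperture.
    """
    D = vessel.width
    xc = aneurysm.neck_center
    offset = aneurysm.neck_width / 2 + 1.0e-3 if aneurysm.stage != "none" else D / 2

    def transverse(name: str, xpos: float) -> CutlineSpec:
        if vessel.dimensionality == 2:
            return CutlineSpec(name, (xpos, 0.0), (xpos, D), n_samples)
        R = D / 2
        return CutlineSpec(name, (xpos, 0.0, -R), (xpos, 0.0, R), n_samples)

    cutlines = {
        "pre": transverse("pre", xc - offset),
        "post": transverse("post", xc + offset),
    }

    if aneurysm.stage == "none":
        cutlines["mid"] = transverse("mid", xc)
        return cutlines

    length = MID_CUTLINE_LENGTH[aneurysm.stage]
    a = math.radians(aneurysm.neck_angle_deg)
    half = length / 2
    if vessel.dimensionality == 2:
        center = np.array([xc, D])
        d = np.array([math.cos(a), math.sin(a)])
    else:
        R = D / 2
        z_neck = math.sqrt(R**2 - (aneurysm.neck_width / 2) ** 2)
        center = np.array([xc, 0.0, z_neck])
        d = np.array([math.cos(a), 0.0, math.sin(a)])
    start = tuple(center - half * d)
    end = tuple(center + half * d)
    # neck aperture segment: sac side of the wall crossing, within one
    # half-neck-width of the neck midpoint (arc length from `start`)
    neck_span = (half, half + aneurysm.neck_width / 2)
    cutlines["mid"] = CutlineSpec("mid", start, end, n_samples, neck_span=neck_span)
    return cutlines
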