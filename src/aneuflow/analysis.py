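"""Post-processing of steady flow fields.

Reproduces the study's quantitative observables: velocity-magnitude profiles
along the pre/mid/post cutlines, mean velocity magnitude over the aneurysm
sac (the stagnation measure an occluding stent is meant to deepen), peak
velocity on the neck aperture, in-plane vorticity, and relative-difference
metrics for cross-solver comparison.  Velocities are reported in mm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .exceptions import AnalysisError
from .geometry import CutlineSpec, DomainMask, sac_region

MM_PER_M = 1.0e3


@dataclass
class CutlineProfile:
    """Velocity-magnitude samples along a named cutline."""

    name: str
    positions: np.ndarray       # arc length along the cutline [m]
    velocity_mm_s: np.ndarray
    solver: str = ""
    neck_span: tuple | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocity_mm_s = np.asarray(self.velocity_mm_s, dtype=float)
        if self.positions.shape != self.velocity_mm_s.shape:
            raise AnalysisError("positions and samples must have equal length")
        if np.any(self.velocity_mm_s < -1e-12):
            raise AnalysisError("velocity magnitudes must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.positions.size


@dataclass
class FlowSummary:
    """Headline observables of one steady run."""

    sac_mean_mm_s: float
    neck_peak_mm_s: float
    max_vorticity_in_sac: float     # 1/s
    stented: bool
    solver: str = ""

    def __post_init__(self) -> None:
        vals = (self.sac_mean_mm_s, self.neck_peak_mm_s, self.max_vorticity_in_sac)
        if not all(np.isfinite(v) for v in vals):
            raise AnalysisError("summary values must be finite")

    def to_dict(self) -> dict:
        return {
            "sac_mean_mm_s": self.sac_mean_mm_s,
            "neck_peak_mm_s": self.neck_peak_mm_s,
            "max_vorticity_in_sac_per_s": self.max_vorticity_in_sac,
            "stented": self.stented,
            "solver": self.solver,
        }


def _magnitude_interpolator(velocity: np.ndarray, mask: DomainMask):
    speed = np.sqrt((np.asarray(velocity) ** 2).sum(axis=0))
    speed = np.where(mask.fluid, speed, 0.0)  # solid contributes zero
    return RegularGridInterpolator(
        mask.axes(), speed, method="linear", bounds_error=False, fill_value=0.0
    )


def sample_cutline(
    velocity: np.ndarray,
    mask: DomainMask,
    line: CutlineSpec,
    solver: str = "",
) -> CutlineProfile:
    """Interpolate velocity magnitude at evenly spaced points along a cutline.

    ``velocity`` is the cell-centered field (d, *grid) in m/s.  Bilinear /
    trilinear interpolation; sample points in solid (or outside the grid)
    report zero.
    """
    pts = line.points()
    lo = [ax[0] - mask.dx for ax in mask.axes()]
    hi = [ax[-1] + mask.dx for ax in mask.axes()]
    inside = np.all((pts >= lo) & (pts <= hi), axis=1)
    if not inside.any():
        raise AnalysisError(f"cutline {line.name!r} lies fully outside the domain")
    interp = _magnitude_interpolator(velocity, mask)
    samples = interp(pts) * MM_PER_M
    return CutlineProfile(
        name=line.name,
        positions=line.arclength(),
        velocity_mm_s=np.clip(samples, 0.0, None),
        solver=solver,
        neck_span=line.neck_span,
    )


def sac_mean_velocity(velocity: np.ndarray, sac_mask: np.ndarray) -> float:
    """Unweighted mean velocity magnitude over sac fluid nodes [mm/s]."""
    sac_mask = np.asarray(sac_mask, dtype=bool)
    if not sac_mask.any():
        raise AnalysisError("sac region is empty")
    speed = np.sqrt((np.asarray(velocity) ** 2).sum(axis=0))
    return float(speed[sac_mask].mean()) * MM_PER_M


def neck_peak_velocity(
    velocity: np.ndarray,
    mask: DomainMask,
    mid_line: CutlineSpec,
    solver: str = "",
) -> float:
    """Peak velocity magnitude on the neck aperture segment of the mid
    cutline [mm/s].

    The aperture segment is ``mid_line.neck_span`` (set by
    ``geometry.make_cutlines``); without one the whole profile is used.
    """
    profile = sample_cutline(velocity, mask, mid_line, solver=solver)
    return neck_peak_from_profile(profile)


def neck_peak_from_profile(profile: CutlineProfile) -> float:
    v = profile.velocity_mm_s
    if profile.neck_span is not None:
        lo, hi = profile.neck_span
        sel = (profile.positions >= lo) & (profile.positions <= hi)
        if sel.any():
            v = v[sel]
    return float(v.max())


def vorticity_2d(velocity: np.ndarray, dx: float) -> np.ndarray:
    """Out-of-plane vorticity w = dv/dx - du/dy [1/s], central differences
    in the interior and one-sided at grid boundaries."""
    velocity = np.asarray(velocity, dtype=float)
    if velocity.ndim != 3 or velocity.shape[0] != 2:
        raise AnalysisError("vorticity_2d expects a 2D field of shape (2, nx, ny)")
    dvdx = np.gradient(velocity[1], dx, axis=0)
    dudy = np.gradient(velocity[0], dx, axis=1)
    return dvdx - dudy


def compare_profiles(a: CutlineProfile, b: CutlineProfile):
    """Relative L2 difference ||a-b|| / ||a|| and max pointwise difference.

    Both profiles must sample the same cutline with the same count; the
    relative norm is undefined for an identically-zero reference.
    """
    if a.name != b.name:
        raise AnalysisError(f"cutline mismatch: {a.name!r} vs {b.name!r}")
    if a.n_samples != b.n_samples:
        raise AnalysisError("profiles have different sample counts")
    ref = np.linalg.norm(a.velocity_mm_s)
    if ref == 0:
        raise AnalysisError("relative norm undefined: reference profile is zero")
    diff = a.velocity_mm_s - b.velocity_mm_s
    return float(np.linalg.norm(diff) / ref), float(np.abs(diff).max())


def summarize(
    velocity: np.ndarray,
    mask: DomainMask,
    cutlines: dict[str, CutlineSpec],
    solver: str = "",
) -> FlowSummary:
    """Assemble the headline observables for one steady field."""
    if mask.aneurysm is not None:
        sac = sac_region(mask)
        sac_mean = sac_mean_velocity(velocity, sac)
        if mask.ndim == 2:
            vort = vorticity_2d(velocity, mask.dx)
            max_vort = float(np.abs(vort[sac]).max())
        else:
            max_vort = float("nan")
    else:
        sac_mean, max_vort = 0.0, 0.0
    neck_peak = neck_peak_velocity(velocity, mask, cutlines["mid"], solver=solver)
    summary = FlowSummary(
        sac_mean_mm_s=sac_mean,
        neck_peak_mm_s=neck_peak,
        max_vorticity_in_sac=max_vort if np.isfinite(max_vort) else 0.0,
        stented=mask.stent is not None,
        solver=solver,
    )
    return summary
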