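# Methods

`aneuflow` simulates steady, laminar blood flow through a small (3 mm)
synthetic aneurysm-bearing vessel with two independent numerical methods — a
D2Q9/D3Q19 BGK lattice Boltzmann solver and a structured-grid incompressible
Navier–Stokes solver — and compares their velocity fields along standard
cutlines, with and without a coarse endoluminal stent across the aneurysm
neck.  This note records the models, the numerical choices, the defaults and
their rationale, and the known limitations.

## Physical model and regime

Blood is treated as an incompressible Newtonian fluid with density
ρ = 1060 kg/m³ and dynamic viscosity μ = 0.004 Pa·s (ν = μ/ρ ≈ 3.77·10⁻⁶
m²/s).  The vessel is a straight 2D plane channel of width D = 3 mm (or a 3D
circular tube of diameter 3 mm) with no-slip walls, a parabolic inflow
profile peaking at u_max = 50 mm/s, and a zero-gradient outflow.  With the
characteristic velocity taken as the mean of a parabolic pipe profile,
u_char = u_max/2 = 25 mm/s, the Reynolds number is

    Re = ρ u_char D / μ = 19.875,

deep in the laminar, steady regime.  The characteristic-velocity convention
matters: with the 2D plane-channel mean (2/3)u_max the same configuration
would read Re = 26.5.  We fix u_char = u_max/2 in both 2D and 3D so that a
single Reynolds number describes all scenarios.

Everything is steady-state: inflow is constant (no cardiac-cycle pulsation),
walls are rigid, and the rheology is Newtonian.  These are deliberate scope
limits, not oversights; see Limitations.

## Synthetic geometry

The aneurysm is a saccular sidewall pouch modelled as a circle (2D) /
sphere (3D) whose centre lies outside the vessel wall.  Given a sac radius
r and a neck width w, the centre sits at distance √(r² − (w/2)²) beyond the
wall line, which makes the opening between lumen and sac exactly w wide.
Two growth stages are built in:

| stage  | sac radius | neck width | 45°-cutline span |
|--------|-----------:|-----------:|-----------------:|
| medium |    2.25 mm |     2.0 mm |             5 mm |
| larger |    3.00 mm |     2.0 mm |             6 mm |

The radii were chosen so the mid cutline through the neck (below) spans
5 mm / 6 mm of fluid for the two stages; with the shared 2 mm neck the
larger-stage fluid region strictly contains the medium-stage one, so growth
is a monotone set operation.  The vessel is straight by default — a straight
channel admits an exact Poiseuille solution, which anchors the validation
suite.

The stent is a deliberately coarse scaffold: n = 5 circular struts of
diameter 0.2 mm, evenly spaced across the neck (first and last strut on the
neck corners), leaving exactly 4 gaps of ≈0.3 mm.  Struts lie inside the
lumen, tangent to the wall line, as a real endoluminal scaffold rests
against the vessel wall.

All shapes are signed distance level sets (negative inside fluid); unions
are pointwise minima, struts are subtracted as solids.  Rasterization is
cell-centred: a node is solid iff its centre has φ ≥ 0.  Masks are validated
for watertightness (no fluid on transverse grid boundaries; inlet and outlet
connected through one fluid component).

### Cutlines

Three sampling segments follow the standard pre/mid/post convention: `pre`
and `post` are perpendicular to the axis, one vessel width (3 mm) long,
placed 1 mm outside the neck corners; `mid` passes through the neck midpoint
at 45° to the axis and spans 5 mm (medium) or 6 mm (larger), centred on the
neck midpoint.  Profiles are bilinear/trilinear interpolations of the
velocity magnitude at evenly spaced points, with solid nodes contributing
zero.

Two scalar observables summarise each run:

- **sac mean velocity** — unweighted mean of |u| over all fluid nodes outside
  the unperturbed lumen (the pouch), in mm/s.  The spatial mean is used
  because the stagnation relevant to thrombosis is a bulk property of the
  pouch.
- **neck peak velocity** — maximum of the mid-cutline profile restricted to
  the *neck aperture segment*: samples within w/2 of the neck midpoint on the
  sac side of the wall line.  The aperture (not the lumen interior) is where
  "velocity at the neck" is physically defined; one half-neck-width into the
  lumen the undisturbed parabola already exceeds 30 mm/s and would swamp the
  aperture signal.

## Lattice Boltzmann solver

Single-relaxation-time (BGK) scheme on D2Q9/D3Q19.  Per node and direction,

    f_i(x + e_i, t+1) − f_i(x, t) = −(f_i − f_i^eq)/τ,
    f_i^eq = w_i ρ (1 + 3 e_i·u + 9/2 (e_i·u)² − 3/2 u·u),

with ρ = Σ f_i, ρu = Σ f_i e_i and lattice viscosity ν_lat = (τ − ½)/3.
The weights are the standard isotropy-satisfying sets (D2Q9: 4/9, 1/9×4,
1/36×4; D3Q19: 1/3, 1/18×6, 1/36×12); the test suite verifies the moment
constraints by brute-force summation rather than trusting the constants.

Unit scaling exposes two free parameters with defaults
`cells_across_width = 30` and `u_lattice_max = 0.05`:
Δx = D/30 = 0.1 mm, Δt = u_lat·Δx/u_max = 0.1 ms, and τ = 3ν_lat + ½ ≈
0.6132 from matching the physical viscosity.  The lattice Mach number is
0.05·√3 ≈ 0.087, so compressibility errors (∝ Ma²) are below 1%.  τ is
rejected outside (0.5, 2]: BGK is formally stable for any τ > ½ but accuracy
degrades well before 2.

Boundary conditions:

- **Walls** — full-way bounce-back (opposite-PDF swap at solid nodes); the
  effective wall sits half a cell beyond the last fluid node, which the MAC
  grid of the reference solver matches exactly.
- **Inlet** — velocity Dirichlet: inlet nodes hold equilibrium PDFs at the
  parabolic profile, with density extrapolated from the first interior
  column.  Equilibrium forcing is simpler than Zou–He and adequate at
  Re ≈ 20.
- **Outlet** — zero-gradient copy of the upstream column, rescaled to the
  reference density ρ = 1.  The rescaling is essential: velocity is a
  scale-invariant moment, so the copy stays a Neumann condition for u, but
  with a velocity inlet and a plain copy outlet *nothing* anchors the global
  pressure level and the density drifts exponentially (we measured ≈13% mass
  growth per 8000 steps before anchoring).

Step order is collide → stream → bounce-back → inlet → outlet.  Runs start
from the parabolic channel solution (zero in the sac), which is exact in the
lumen and cuts the transient to the sac spin-up time.  Steadiness is declared
when the max-node velocity change over a 100-step interval, relative to the
max velocity, falls below 10⁻⁶; runs are capped at 2·10⁵ steps and flagged
if unconverged.  Divergence (|u| ≥ c_s = 1/√3) raises a stability error with
diagnostics.

## Navier–Stokes reference solver

The cross-check solver integrates the incompressible Navier–Stokes equations
ρ(∂u/∂t + u·∇u) = −∇p + μ∇²u, ∇·u = 0 on the *same rasterized mask*,
using a MAC staggered grid (pressure at cell centres, velocities on faces)
and Chorin projection: explicit predictor with first-order upwind advection
and central diffusion, then a pressure Poisson solve discretised with the
same face stencil as the divergence, factorised once with sparse LU and
reused every step.  The projected field therefore satisfies discrete
continuity to machine precision — the lattice-scaled divergence
max|∇·u|·Δx/u_max stays below 10⁻¹² in practice (contract: < 10⁻⁸).

Walls sit on cell faces (normal velocity zero on the face, tangential
velocity zero via ghost reflection u_ghost = −u, or 2U − u for the optional
moving wall used in Couette validation), which reproduces the bounce-back
wall placement of the LBM bit-for-bit on the shared mask.  The inlet
prescribes the parabolic profile on the first face column; the outlet holds
p = 0 half a cell beyond the last centre with zero-gradient velocity.

The explicit step obeys the combined bound 4νΔt/Δx² + uΔt/Δx ≤ 1 with a
0.6 safety factor (Δt ≈ 0.3 ms at default resolution).  Violating the
combined bound (rather than the diffusion-only bound) produces a slowly
growing advective instability that we observed directly; the conservative
factor removes it.  The same steadiness criterion as the LBM is used, for a
fair comparison.  The solver is 2D-only: the 3D cross-check is out of scope
and the LBM covers 3D scenarios.

This solver is first-order in time and in advection, which is sufficient
here because at Re ≈ 20 the steady solution is diffusion-dominated and the
fully developed channel flow has u·∇u = 0; measured Poiseuille error at 30
cells is 0.06% (LBM: 0.5%).

## Validation and measured agreement

At default resolution (30 cells across the width):

- 2D Poiseuille, both solvers: relative L2 error < 1% against the analytic
  parabola (contract); errors shrink under refinement.
- Planar Couette with moving wall (NS): < 1% against the linear profile.
- 3D pipe (D3Q19, 12–15 cells across the bore): 3–5% — limited by staircase
  walls, consistent with first-order wall placement.
- Closed-cavity global mass: constant to 10⁻¹² relative over 10⁴ steps;
  per-node collision invariants hold to 10⁻¹⁴.
- LBM vs NS on the medium-stage aneurysm: 0.2–0.5% relative L2 on all three
  cutlines (contract: < 5%), and sac means within 1.5% of each other.

## Measured observables and an honest discrepancy

At the default conditions the unstented runs give a medium-stage sac mean of
≈1.4 mm/s and a larger-stage neck peak of ≈13 mm/s — the expected order
(≈1 mm/s and 14–20 mm/s) for this regime.  Inserting the default stent
reduces both *strictly*, as it must, but very strongly: sac mean ≈0.04 mm/s
and neck peak ≈0.23 mm/s, i.e. near-total decoupling of the pouch rather
than the moderate reduction (to roughly 0.75 mm/s and 5 mm/s) reported for
curved-vessel geometries.  We verified this is converged physics, not a
numerical artifact: both independent solvers agree on the unstented fields,
grid refinement from 30 to 50 cells changes the stented sac mean by < 10%,
and tightening the convergence tolerance by 2½ orders of magnitude changes
it by < 1%.  The interpretation: in a *straight* vessel the sac is driven
only by the shear layer across the aperture, and a five-strut fence kills
that weak driving almost completely; in a gently *curved* vessel the sac at
the outer bend is additionally fed by inertial impingement, which a coarse
stent only partly blocks.  Since the straight default is what makes exact
Poiseuille validation possible, and the reference sac/strut dimensions are
not published, we keep the straight geometry and report the stented
magnitudes as they come out.

## Desk-scale problem sizes

Default lattices are ≈150×90 cells in 2D and ≈50×30×40 in 3D (the
`medium-3d-small` preset); steady state takes 1–3·10⁴ steps, under a minute
per 2D run on one core.  These sizes were chosen as the package's desk-scale
operating point; the physics regime (Re, Mach, geometry proportions) is
preserved at any finer resolution and all validation contracts are expressed
resolution-independently.

## Determinism and seeds

Every solver stage is deterministic: identical configs produce byte-identical
artifacts.  `RunConfig.seed` is recorded in run metadata and reserved for
optional randomized initial perturbations, which default to none.

## Limitations

- Rigid walls; no fluid–structure interaction.
- Newtonian rheology; no shear-thinning, no thrombosis model.
- Steady inflow; no cardiac-cycle pulsatility.
- Straight vessel; curvature-driven sac impingement is absent (see above).
- Synthetic geometry only; no patient-derived (MRI) lumens.
- Full-way bounce-back and upwind advection are first-order at walls;
  accuracy contracts are set accordingly.
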