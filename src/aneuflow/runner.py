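"""Run orchestration: single scenarios, cross-solver comparisons, artifacts.

``run_scenario`` executes one configuration end to end (geometry -> solver ->
analysis) and optionally writes CSV profiles, a JSON summary, legacy-VTK
fields, a compressed field checkpoint and a convergence log into an output
directory.  ``run_comparison`` runs both solvers on the same mask and reports
per-cutline relative-difference metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import analysis, export, geometry, lbm, reference_ns
from .config import RunConfig
from .exceptions import ConfigurationError


@dataclass
class RunResult:
    config: RunConfig
    summary: analysis.FlowSummary
    profiles: dict[str, analysis.CutlineProfile]
    report: lbm.ConvergenceReport
    velocity: np.ndarray          # cell-centered m/s
    mask: geometry.DomainMask
    solver: str


def _build_mask(config: RunConfig) -> geometry.DomainMask:
    vessel = config.vessel_spec()
    aneurysm = config.aneurysm_spec()
    return geometry.build_domain(
        vessel,
        aneurysm=aneurysm,
        stent=config.stent_spec(),
        resolution=config.scenario.cells_across_width,
    )


def _solve(config: RunConfig, mask: geometry.DomainMask, solver: str):
    criterion = config.criterion()
    if solver == "lbm":
        sim, report = lbm.run_to_steady(mask, config.unit_system(), criterion)
        return sim.velocity_physical(), report
    if solver == "ns":
        if config.geometry.dimensionality != 2:
            raise ConfigurationError(
                "the NS reference solver supports 2D only; use solver=lbm in 3D"
            )
        fld, report = reference_ns.solve_ns(mask, config.flow_scenario(),
                                            criterion=criterion)
        return fld.u, report
    raise ConfigurationError(f"unknown solver {solver!r} (use lbm|ns|both)")


def run_scenario(config: RunConfig, out_dir=None, solver: str | None = None) -> RunResult:
    """Execute one scenario with one solver; write artifacts if requested."""
    solver = solver or config.solver.name
    if solver == "both":
        raise ConfigurationError("run_scenario takes one solver; see run_comparison")
    mask = _build_mask(config)
    velocity, report = _solve(config, mask, solver)
    cutlines = geometry.make_cutlines(
        config.aneurysm_spec(), config.vessel_spec(),
        n_samples=config.analysis.n_samples,
    )
    profiles = {
        name: analysis.sample_cutline(velocity, mask, line, solver=solver)
        for name, line in cutlines.items()
    }
    summary = analysis.summarize(velocity, mask, cutlines, solver=solver)
    result = RunResult(config, summary, profiles, report, velocity, mask, solver)
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: RunResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    export.profiles_to_csv(result.profiles.values(), out / "profiles.csv")
    summary = result.summary.to_dict()
    if result.mask.stent is not None:
        summary["n_stent_gaps"] = result.mask.stent.n_gaps
    summary["converged"] = result.report.converged
    export.write_summary_json(summary, out / "summary.json")
    export.save_fields_npz(
        out / "fields.npz",
        velocity_m_s=result.velocity,
        classes=result.mask.classes,
        phi=result.mask.phi,
        dx=result.mask.dx,
        origin=np.asarray(result.mask.origin),
    )
    if result.mask.ndim == 2:
        vort = analysis.vorticity_2d(result.velocity, result.mask.dx)
        export.write_vtk_structured_points(
            out / "fields.vtk",
            origin=[o + result.mask.dx / 2 for o in result.mask.origin],
            spacing=result.mask.dx,
            fields={"velocity_m_s": result.velocity, "vorticity_per_s": vort},
        )
    log = [f"{n} {r:.6e}" for n, r in result.report.history]
    (out / "convergence.log").write_text("\n".join(log) + "\n")


def run_comparison(config: RunConfig, out_dir=None) -> dict:
    """Run LBM and NS on the same mask; per-cutline difference metrics."""
    if config.geometry.dimensionality != 2:
        raise ConfigurationError("cross-solver comparison requires a 2D scenario")
    res_lbm = run_scenario(config, solver="lbm")
    res_ns = run_scenario(config, solver="ns")
    cutline_metrics = {}
    for name in res_lbm.profiles:
        rel_l2, max_abs = analysis.compare_profiles(
            res_lbm.profiles[name], res_ns.profiles[name]
        )
        cutline_metrics[name] = {"rel_l2": rel_l2, "max_abs_mm_s": max_abs}
    report = {
        "cutlines": cutline_metrics,
        "lbm": res_lbm.summary.to_dict(),
        "ns": res_ns.summary.to_dict(),
        "converged": {
            "lbm": res_lbm.report.converged,
            "ns": res_ns.report.converged,
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "comparison.json").write_text(json.dumps(report, indent=2) + "\n")
        export.profiles_to_csv(
            list(res_lbm.profiles.values()) + list(res_ns.profiles.values()),
            out / "profiles.csv",
        )
    return report
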