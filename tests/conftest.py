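"""Shared fixtures: steady solver runs are expensive, so each scenario is
solved once per session and reused across unit, property and acceptance
tests."""

from __future__ import annotations

import numpy as np
import pytest

from aneuflow import (
    SteadyStateCriterion,
    VesselSpec,
    build_domain,
    build_unit_system,
    default_scenario,
)
from aneuflow import lbm as lbm_mod
from aneuflow import reference_ns as ns_mod
from aneuflow.config import get_preset
from aneuflow.runner import run_scenario


def poiseuille_2d(u_max: float, width: float, y: np.ndarray) -> np.ndarray:
    """Analytic plane-channel parabola, zero outside the channel."""
    s = y / width
    return np.where((s > 0) & (s < 1), 4.0 * u_max * s * (1.0 - s), 0.0)


@pytest.fixture(scope="session")
def scenario2d():
    return default_scenario(2)


@pytest.fixture(scope="session")
def channel_mask():
    return build_domain(VesselSpec(length=12e-3), resolution=30)


@pytest.fixture(scope="session")
def poiseuille_lbm(channel_mask, scenario2d):
    units = build_unit_system(scenario2d)
    solver, report = lbm_mod.run_to_steady(
        channel_mask, units, SteadyStateCriterion(tolerance=1e-7)
    )
    return solver, report


@pytest.fixture(scope="session")
def poiseuille_ns(channel_mask, scenario2d):
    solver = ns_mod.NSSolver2D(channel_mask, scenario2d)
    report = solver.run_to_steady(SteadyStateCriterion(tolerance=1e-7))
    return solver, report


@pytest.fixture(scope="session")
def medium_run_lbm():
    return run_scenario(get_preset("medium-2d"), solver="lbm")


@pytest.fixture(scope="session")
def medium_run_ns():
    return run_scenario(get_preset("medium-2d"), solver="ns")


@pytest.fixture(scope="session")
def larger_run_lbm():
    return run_scenario(get_preset("larger-2d"), solver="lbm")


@pytest.fixture(scope="session")
def larger_stented_run_lbm():
    return run_scenario(get_preset("larger-2d-stented"), solver="lbm")
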