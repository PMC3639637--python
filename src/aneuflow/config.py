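"""Run configuration: YAML config files, validation, and scenario presets.

A config is a nested key-value document with blocks ``scenario``,
``geometry``, ``solver`` and ``analysis``; all physical quantities carry an
explicit unit suffix in their key names.  Two runs from the same config are
bit-identical (the solvers are fully deterministic; ``seed`` is recorded for
provenance and reserved for optional randomized initial perturbations,
which default to none).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .geometry import AneurysmSpec, StentSpec, VesselSpec
from .lbm import SteadyStateCriterion
from .units import FlowScenario, FluidProperties, build_unit_system


@dataclass(frozen=True)
class ScenarioConfig:
    density_kg_m3: float = 1060.0
    viscosity_pa_s: float = 0.004
    channel_width_mm: float = 3.0
    u_max_mm_s: float = 50.0
    cells_across_width: int = 30
    u_lattice_max: float = 0.05


@dataclass(frozen=True)
class GeometryConfig:
    stage: str = "medium"            # none | medium | larger
    dimensionality: int = 2
    vessel_length_mm: float = 15.0
    stent: bool = False
    n_struts: int = 5
    strut_diameter_mm: float = 0.2


@dataclass(frozen=True)
class SolverConfig:
    name: str = "lbm"                # lbm | ns | both
    tolerance: float = 1.0e-6
    check_interval: int = 100
    max_steps: int = 200_000


@dataclass(frozen=True)
class AnalysisConfig:
    n_samples: int = 101


@dataclass(frozen=True)
class RunConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int | None = None

    # -- (de)serialisation ------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        blocks = {"scenario": ScenarioConfig, "geometry": GeometryConfig,
                  "solver": SolverConfig, "analysis": AnalysisConfig}
        unknown = set(data) - set(blocks) - {"seed"}
        if unknown:
            raise ConfigurationError(f"unknown config blocks: {sorted(unknown)}")
        kwargs = {}
        for name, block_cls in blocks.items():
            block = data.get(name, {})
            if not isinstance(block, dict):
                raise ConfigurationError(f"config block {name!r} must be a mapping")
            valid = {f.name for f in fields(block_cls)}
            bad = set(block) - valid
            if bad:
                raise ConfigurationError(
                    f"unknown keys in config block {name!r}: {sorted(bad)}"
                )
            kwargs[name] = block_cls(**block)
        return cls(seed=data.get("seed"), **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seed"] = self.seed
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    # -- domain-object construction ---------------------------------------
    def flow_scenario(self) -> FlowScenario:
        s = self.scenario
        return FlowScenario(
            channel_width=s.channel_width_mm * 1e-3,
            u_max_inflow=s.u_max_mm_s * 1e-3,
            fluid=FluidProperties(s.density_kg_m3, s.viscosity_pa_s),
            dimensionality=self.geometry.dimensionality,
        )

    def unit_system(self):
        s = self.scenario
        return build_unit_system(
            self.flow_scenario(), s.cells_across_width, s.u_lattice_max
        )

    def vessel_spec(self) -> VesselSpec:
        g = self.geometry
        return VesselSpec(
            width=self.scenario.channel_width_mm * 1e-3,
            length=g.vessel_length_mm * 1e-3,
            dimensionality=g.dimensionality,
        )

    def aneurysm_spec(self) -> AneurysmSpec:
        return AneurysmSpec.from_stage(self.geometry.stage, self.vessel_spec())

    def stent_spec(self) -> StentSpec | None:
        g = self.geometry
        if not g.stent:
            return None
        return StentSpec(n_struts=g.n_struts, strut_diameter=g.strut_diameter_mm * 1e-3)

    def criterion(self) -> SteadyStateCriterion:
        s = self.solver
        return SteadyStateCriterion(
            tolerance=s.tolerance,
            check_interval=s.check_interval,
            max_steps=s.max_steps,
        )


#: Deterministic scenario presets; these double as the fixture generator.
PRESETS: dict[str, RunConfig] = {
    "poiseuille-2d": RunConfig(
        geometry=GeometryConfig(stage="none"),
    ),
    "medium-2d": RunConfig(
        geometry=GeometryConfig(stage="medium"),
    ),
    "larger-2d": RunConfig(
        geometry=GeometryConfig(stage="larger"),
    ),
    "larger-2d-stented": RunConfig(
        geometry=GeometryConfig(stage="larger", stent=True),
    ),
    # reduced desk-scale 3D tube (the full-study 3D lattice is GPU-scale);
    # same Reynolds regime, coarser lattice
    "medium-3d-small": RunConfig(
        scenario=ScenarioConfig(cells_across_width=16),
        geometry=GeometryConfig(stage="medium", dimensionality=3, vessel_length_mm=13.0),
        solver=SolverConfig(tolerance=2.0e-6),
    ),
}


def get_preset(name: str) -> RunConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
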