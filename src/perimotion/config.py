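"""JSON configuration: schema, defaults, round-trip IO.

A single JSON document with sections {micromotion, fluid, geometry, ppfc,
void, sweep, synth} drives every CLI entry point.  Boundary units are the
ones practitioners quote (µm, mPa·s, mL/min); conversion to SI happens in
the accessor methods, so the numeric core never sees mixed units.
Validation is strict: unknown keys are rejected with the offending field
path.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError
from .gap_flow import EndCondition, GapGeometry
from .kinematics import FluidProperties, HarmonicComponent, MicromotionWaveform
from .sweep import Solver, SweepGrid
from .void_dynamics import VoidModelParams, WSSMetric

__all__ = ["PerimotionConfig", "read_config", "write_config",
           "default_config"]

_UM = 1e-6
_MPAS = 1e-3
_ML_MIN = 1e-6 / 60.0


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class HarmonicSpec(_Strict):
    amplitude_um: float = Field(gt=0)
    frequency_hz: float = Field(gt=0)
    phase_rad: float = 0.0


class MicromotionSection(_Strict):
    # respiratory default: 15 um (30 um peak-to-peak) at 0.5 Hz
    components: list[HarmonicSpec] = Field(
        default_factory=lambda: [HarmonicSpec(amplitude_um=15.0,
                                              frequency_hz=0.5)])

    def waveform(self) -> MicromotionWaveform:
        return MicromotionWaveform(tuple(
            HarmonicComponent(c.amplitude_um * _UM, c.frequency_hz,
                              c.phase_rad) for c in self.components))


class FluidSection(_Strict):
    # interstitial fluid: CSF density; mid-range literature viscosity
    density_kg_m3: float = Field(default=1006.0, gt=0)
    viscosity_mpas: float = Field(default=50.0, gt=0)

    def fluid(self) -> FluidProperties:
        return FluidProperties(self.density_kg_m3,
                               self.viscosity_mpas * _MPAS)


class GeometrySection(_Strict):
    electrode_diameter_um: float = Field(default=100.0, gt=0)
    side_gap_um: float = Field(default=50.0, gt=0)
    end_condition: EndCondition = EndCondition.CLOSED

    def gap(self) -> GapGeometry:
        return GapGeometry(side_gap=self.side_gap_um * _UM,
                           electrode_diameter=self.electrode_diameter_um * _UM,
                           end_condition=self.end_condition)


class PPFCSection(_Strict):
    # geometry is derived from aspect ratio + the (Q, tau) calibration
    # pair rather than hard-coded; the derived h ~ 327 um, b ~ 39 mm
    aspect_ratio: float = Field(default=120.0, gt=1)
    density_kg_m3: float = Field(default=1009.0, gt=0)
    viscosity_mpas: float = Field(default=0.930, gt=0)
    calibration_flow_ml_min: float = Field(default=4.49, gt=0)
    calibration_wss_pa: float = Field(default=0.1, gt=0)
    frequency_hz: float = Field(default=0.5, ge=0)

    def fluid(self) -> FluidProperties:
        return FluidProperties(self.density_kg_m3,
                               self.viscosity_mpas * _MPAS)

    @property
    def calibration_flow_si(self) -> float:
        return self.calibration_flow_ml_min * _ML_MIN


class VoidSection(_Strict):
    tau_threshold_pa: float = Field(default=0.1, gt=0)
    rate_k: float = Field(default=1e-9, gt=0)      # m/(Pa s)
    initial_gap_um: float = Field(default=10.0, gt=0)
    wss_metric: WSSMetric = WSSMetric.PEAK

    def params(self, fluid: FluidProperties, waveform: MicromotionWaveform,
               electrode_diameter: float) -> VoidModelParams:
        return VoidModelParams(tau_threshold=self.tau_threshold_pa,
                               rate_k=self.rate_k,
                               initial_gap=self.initial_gap_um * _UM,
                               wss_metric=self.wss_metric, fluid=fluid,
                               waveform=waveform,
                               electrode_diameter=electrode_diameter)


class SweepSection(_Strict):
    gaps_um: list[float] = Field(
        default_factory=lambda: [10, 30, 50, 70, 90, 110, 130, 150])
    viscosities_mpas: list[float] = Field(
        default_factory=lambda: [1.2, 2.267, 4.283, 8.092, 15.287,
                                 28.882, 54.567, 100.0])
    solver: Solver = Solver.ANALYTIC

    def grid(self, end_condition: EndCondition = EndCondition.CLOSED
             ) -> SweepGrid:
        return SweepGrid(gaps=tuple(g * _UM for g in self.gaps_um),
                         viscosities=tuple(v * _MPAS
                                           for v in self.viscosities_mpas),
                         solver=self.solver, end_condition=end_condition)


class SynthSection(_Strict):
    respiratory_amplitude_um: float = Field(default=15.0, gt=0)
    respiratory_frequency_hz: float = Field(default=0.5, gt=0)
    cardiac_amplitude_um: float | None = Field(default=None, gt=0)
    cardiac_frequency_hz: float | None = Field(default=None, gt=0)
    displacement_noise_sd_um: float = Field(default=0.0, ge=0)
    wss_noise_rel_sd: float = Field(default=0.05, ge=0)
    n_samples: int = Field(default=1000, ge=2)
    seed: int = 0


class PerimotionConfig(_Strict):
    """Top-level configuration document."""

    micromotion: MicromotionSection = Field(default_factory=MicromotionSection)
    fluid: FluidSection = Field(default_factory=FluidSection)
    geometry: GeometrySection = Field(default_factory=GeometrySection)
    ppfc: PPFCSection = Field(default_factory=PPFCSection)
    void: VoidSection = Field(default_factory=VoidSection)
    sweep: SweepSection = Field(default_factory=SweepSection)
    synth: SynthSection = Field(default_factory=SynthSection)


def default_config() -> PerimotionConfig:
    return PerimotionConfig()


def read_config(path: str | Path) -> PerimotionConfig:
    """Load and validate a JSON config; schema violations report the
    offending field path."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        return PerimotionConfig.model_validate(payload)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(p) for p in err["loc"]) + f": {err['msg']}"
            for err in exc.errors())
        raise ConfigError(f"invalid config {path}: {paths}") from exc


def write_config(config: PerimotionConfig, path: str | Path) -> None:
    Path(path).write_text(config.model_dump_json(indent=2))
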