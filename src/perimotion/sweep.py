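"""Parameter sweep over gap width and interstitial-fluid viscosity.

Recomputes the gap-vs-viscosity shear surface: for every (h, μ) cell the
closed-cavity model yields a peak and a cycle-averaged tissue-wall WSS
plus the gap Womersley number.  Default axes span the physiological
ranges — gaps 10–150 µm, viscosities 1.2–100 mPa·s (log-spaced, since
plausible interstitial viscosities span two decades).

Results are a long-form (tidy) table so both shear metrics live in the
same row; the tidy layout also round-trips losslessly through CSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from . import __version__
from .errors import InvalidParameterError, PerimotionError
from .gap_flow import (EndCondition, GapGeometry, fd_gap_solver,
                       wss_timeseries_analytic)
from .kinematics import (FluidProperties, MicromotionWaveform,
                         womersley_number)

__all__ = ["Solver", "SweepGrid", "SweepResult", "run_sweep", "write_csv"]


class Solver(str, Enum):
    ANALYTIC = "analytic"
    FD = "fd"


def _default_gaps() -> tuple[float, ...]:
    return tuple(np.linspace(10e-6, 150e-6, 8))


def _default_viscosities() -> tuple[float, ...]:
    return tuple(np.geomspace(1.2e-3, 100e-3, 8))


@dataclass(frozen=True)
class SweepGrid:
    """Axes of the sweep: per-side gaps (m) and viscosities (Pa·s)."""

    gaps: tuple[float, ...] = field(default_factory=_default_gaps)
    viscosities: tuple[float, ...] = field(default_factory=_default_viscosities)
    solver: Solver = Solver.ANALYTIC
    end_condition: EndCondition = EndCondition.CLOSED

    def __post_init__(self) -> None:
        for name, vals in (("gaps", self.gaps),
                           ("viscosities", self.viscosities)):
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0 or np.any(arr <= 0):
                raise InvalidParameterError(f"{name} must all be > 0")
            if np.any(np.diff(arr) <= 0) and arr.size > 1:
                raise InvalidParameterError(
                    f"{name} must be sorted strictly ascending")


@dataclass(frozen=True)
class SweepResult:
    """Tidy sweep table plus a provenance block.

    ``table`` columns: gap_m, viscosity_pa_s, wss_peak_pa,
    wss_cycle_avg_pa, womersley.  ``provenance`` records the package
    version and a hash of the generating configuration.
    """

    table: pd.DataFrame
    provenance: dict

    def __post_init__(self) -> None:
        if self.table.isna().any().any() or \
                not np.all(np.isfinite(self.table.to_numpy(dtype=float))):
            raise PerimotionError("sweep produced non-finite entries")


def run_sweep(grid: SweepGrid,
              waveform: MicromotionWaveform | None = None,
              fluid_density: float = 1006.0,
              electrode_diameter: float = 100e-6) -> SweepResult:
    """Evaluate the gap-flow model on every (gap, viscosity) cell."""
    waveform = waveform or MicromotionWaveform()
    f_max = max(c.frequency for c in waveform.components)
    rows = []
    for mu in grid.viscosities:
        fluid = FluidProperties(density=fluid_density, dynamic_viscosity=mu)
        for h in grid.gaps:
            geom = GapGeometry(side_gap=h,
                               electrode_diameter=electrode_diameter,
                               end_condition=grid.end_condition)
            try:
                if grid.solver is Solver.FD:
                    series = fd_gap_solver(geom, fluid, waveform)
                else:
                    series = wss_timeseries_analytic(geom, fluid, waveform)
            except PerimotionError as exc:
                raise PerimotionError(
                    f"sweep cell failed at gap={h:.3g} m, "
                    f"viscosity={mu:.3g} Pa·s: {exc}") from exc
            rows.append({
                "gap_m": h,
                "viscosity_pa_s": mu,
                "wss_peak_pa": series.peak_abs,
                "wss_cycle_avg_pa": series.cycle_avg_abs,
                "womersley": womersley_number(h, fluid, f_max),
            })
    table = pd.DataFrame(rows)
    cfg = {
        "gaps_m": list(grid.gaps),
        "viscosities_pa_s": list(grid.viscosities),
        "solver": grid.solver.value,
        "end_condition": grid.end_condition.value,
        "fluid_density": fluid_density,
        "electrode_diameter_m": electrode_diameter,
        "waveform": [(c.amplitude, c.frequency, c.phase)
                     for c in waveform.components],
    }
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    provenance = {"package_version": __version__, "config_hash": digest}
    return SweepResult(table=table, provenance=provenance)


def write_csv(obj, path) -> None:
    """Write a sweep table / shear series / void trajectory to tidy CSV.

    Floats carry 9 significant digits so a reload reproduces the values.
    """
    df = _as_frame(obj)
    df.to_csv(path, index=False, float_format="%.9g")


def _as_frame(obj) -> pd.DataFrame:
    from .gap_flow import WallShearSeries
    from .void_dynamics import VoidTrajectory
    if isinstance(obj, SweepResult):
        return obj.table
    if isinstance(obj, pd.DataFrame):
        return obj
    if isinstance(obj, WallShearSeries):
        return pd.DataFrame({"t_s": obj.times,
                             "tau_tissue_pa": obj.tau_tissue,
                             "tau_electrode_pa": obj.tau_electrode})
    if isinstance(obj, VoidTrajectory):
        return pd.DataFrame({"t_s": obj.times,
                             "gap_um": obj.gap * 1e6,
                             "wss_pa": obj.wss})
    raise InvalidParameterError(
        f"cannot serialize object of type {type(obj).__name__}")
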