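"""Parallel-plate flow chamber (PPFC) shear dosimetry.

The in-vitro arm of the micromotion problem delivers a prescribed wall
shear stress to a cell monolayer with plane-Poiseuille flow between
parallel plates.  For a channel of width b and height h (b ≫ h) the wall
shear stress under a volumetric flow rate Q is

    τ_w = 6 Q μ / (b h²)

This module implements that dosimetry formula, its inverse (flow rate for
a target stress), the closure of the chamber geometry from the aspect
ratio b/h = 120 plus one calibrated (Q, τ) pair, and the dimensionless
checks (Reynolds, Womersley) that justify treating the 0.5 Hz oscillatory
flow as a quasi-steady laminar modulation of the steady profile.

Reynolds convention: characteristic length = channel height h, so with
the mean speed ū = Q/(b·h),  Re = ρ ū h / μ = ρ Q / (μ b).  Under this
convention the 0.1 Pa condition gives Re ≈ 2.07, consistent with the
quoted operating bound of 2.4 (a hydraulic-diameter convention would give
roughly twice that).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidParameterError
from .kinematics import CULTURE_MEDIUM, FluidProperties, womersley_number

__all__ = [
    "PPFCChannel",
    "PPFCCondition",
    "HomogeneityReport",
    "wss_from_flow",
    "flow_for_wss",
    "solve_height",
    "reynolds_channel",
    "make_condition",
    "homogeneity_report",
    "DEFAULT_ASPECT_RATIO",
    "LAMINAR_RE_LIMIT",
]

#: Channel width-to-height ratio of the microchannel device.
DEFAULT_ASPECT_RATIO = 120.0

#: Plane-channel transition heuristic (Re based on height).
LAMINAR_RE_LIMIT = 1400.0


@dataclass(frozen=True)
class PPFCChannel:
    """Rectangular flow channel: width b across the flow, height h between
    the plates.  Wide-channel dosimetry assumes b ≫ h."""

    width_b: float
    height_h: float

    def __post_init__(self) -> None:
        if not (self.height_h > 0):
            raise InvalidParameterError(
                f"height_h must be > 0, got {self.height_h}")
        if not (self.width_b > self.height_h):
            raise InvalidParameterError(
                f"width_b must exceed height_h, got b={self.width_b}, "
                f"h={self.height_h}")

    @property
    def aspect_ratio(self) -> float:
        """b/h (dimensionless)."""
        return self.width_b / self.height_h


@dataclass(frozen=True)
class PPFCCondition:
    """One flow condition with its dosimetry and regime numbers."""

    flow_rate: float                 # m³/s
    fluid: FluidProperties
    channel: PPFCChannel
    frequency: float = 0.0           # Hz; 0 for steady flow
    wss: float = field(init=False, default=0.0)
    reynolds: float = field(init=False, default=0.0)
    womersley: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if self.flow_rate < 0:
            raise InvalidParameterError(
                f"flow_rate must be >= 0, got {self.flow_rate}")
        if self.frequency < 0:
            raise InvalidParameterError(
                f"frequency must be >= 0, got {self.frequency}")
        object.__setattr__(self, "wss", _wss(self.flow_rate, self.fluid,
                                             self.channel))
        object.__setattr__(self, "reynolds",
                           _reynolds(self.flow_rate, self.fluid, self.channel))
        object.__setattr__(self, "womersley",
                           womersley_number(self.channel.height_h / 2.0,
                                            self.fluid, self.frequency))


def _wss(flow_rate: float, fluid: FluidProperties,
         channel: PPFCChannel) -> float:
    b, h = channel.width_b, channel.height_h
    return 6.0 * flow_rate * fluid.dynamic_viscosity / (b * h * h)


def _reynolds(flow_rate: float, fluid: FluidProperties,
              channel: PPFCChannel) -> float:
    return (fluid.density * flow_rate
            / (fluid.dynamic_viscosity * channel.width_b))


def wss_from_flow(flow_rate: float, fluid: FluidProperties,
                  channel: PPFCChannel) -> float:
    """Wall shear stress τ = 6Qμ/(b h²), Pa, for flow rate Q in m³/s."""
    if not (flow_rate >= 0):
        raise InvalidParameterError(
            f"flow_rate must be >= 0, got {flow_rate}")
    return _wss(flow_rate, fluid, channel)


def flow_for_wss(target_wss: float, fluid: FluidProperties,
                 channel: PPFCChannel) -> float:
    """Flow rate delivering a target wall shear stress: Q = τ b h² / (6μ).

    Exact inverse of :func:`wss_from_flow`; dosimetry is linear in Q, so
    e.g. five times the 0.1 Pa flow rate yields 0.5 Pa.
    """
    if not (target_wss > 0):
        raise InvalidParameterError(
            f"target_wss must be > 0, got {target_wss}")
    b, h = channel.width_b, channel.height_h
    return target_wss * b * h * h / (6.0 * fluid.dynamic_viscosity)


def solve_height(aspect_ratio: float, flow_rate: float,
                 fluid: FluidProperties, target_wss: float) -> PPFCChannel:
    """Close the chamber geometry from b/h and one calibrated (Q, τ) pair.

    With b = aspect·h the dosimetry formula becomes τ = 6Qμ/(aspect·h³),
    so h = (6Qμ/(τ·aspect))^(1/3).  For the 0.1 Pa calibration at
    4.49 mL/min in culture medium and aspect 120 this yields h ≈ 327 µm
    and b ≈ 39.2 mm (consistent with a standard 38 mm slide width).
    """
    if not (aspect_ratio > 1):
        raise InvalidParameterError(
            f"aspect_ratio must be > 1, got {aspect_ratio}")
    if not (flow_rate > 0) or not (target_wss > 0):
        raise InvalidParameterError(
            "flow_rate and target_wss must be > 0, got "
            f"Q={flow_rate}, tau={target_wss}")
    h = (6.0 * flow_rate * fluid.dynamic_viscosity
         / (target_wss * aspect_ratio)) ** (1.0 / 3.0)
    return PPFCChannel(width_b=aspect_ratio * h, height_h=h)


def reynolds_channel(flow_rate: float, fluid: FluidProperties,
                     channel: PPFCChannel) -> float:
    """Channel Reynolds number Re = ρ ū h / μ = ρ Q / (μ b)."""
    if not (flow_rate >= 0):
        raise InvalidParameterError(
            f"flow_rate must be >= 0, got {flow_rate}")
    return _reynolds(flow_rate, fluid, channel)


def make_condition(target_wss: float, frequency: float = 0.5,
                   fluid: FluidProperties = CULTURE_MEDIUM,
                   aspect_ratio: float = DEFAULT_ASPECT_RATIO,
                   calibration_flow: float = 4.49e-6 / 60.0,
                   calibration_wss: float = 0.1) -> PPFCCondition:
    """Build the flow condition delivering ``target_wss`` in the default
    chamber (geometry closed from the 4.49 mL/min ↦ 0.1 Pa calibration)."""
    channel = solve_height(aspect_ratio, calibration_flow, fluid,
                           calibration_wss)
    q = flow_for_wss(target_wss, fluid, channel)
    return PPFCCondition(flow_rate=q, fluid=fluid, channel=channel,
                         frequency=frequency)


@dataclass(frozen=True)
class HomogeneityReport:
    """Flow-regime screen for an oscillatory chamber condition."""

    womersley: float
    reynolds: float
    quasi_steady: bool
    laminar: bool


def homogeneity_report(condition: PPFCCondition,
                       frequency: float | None = None) -> HomogeneityReport:
    """Check that an oscillatory condition delivers homogeneous WSS.

    quasi_steady ⟺ α(h/2) < 1: the oscillatory profile is an in-phase
    modulation of the steady one, so the monolayer sees a spatially
    uniform stress.  laminar ⟺ Re < 1400 (plane-channel heuristic).
    """
    f = condition.frequency if frequency is None else frequency
    alpha = womersley_number(condition.channel.height_h / 2.0,
                             condition.fluid, f)
    return HomogeneityReport(womersley=alpha, reynolds=condition.reynolds,
                             quasi_steady=alpha < 1.0,
                             laminar=condition.reynolds < LAMINAR_RE_LIMIT)
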