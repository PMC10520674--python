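"""Periodic electrode micromotion waveforms and flow-regime numbers.

A chronically implanted neural probe moves relative to the surrounding
brain tissue with every breath and heartbeat.  This module represents that
micromotion as a sum of sinusoidal displacement components and provides the
Womersley number used to decide whether the induced gap flow may be treated
as quasi-steady.

Units are SI throughout (m, s, Hz, Pa·s, kg/m³, rad).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import reduce
from fractions import Fraction

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "HarmonicComponent",
    "MicromotionWaveform",
    "FluidProperties",
    "displacement",
    "velocity",
    "womersley_number",
    "DEFAULT_WAVEFORM",
    "INTERSTITIAL_FLUID",
    "CULTURE_MEDIUM",
]

#: Respiratory micromotion amplitude, m (30 µm peak-to-peak).
DEFAULT_AMPLITUDE = 15e-6
#: Respiratory micromotion frequency, Hz.
DEFAULT_FREQUENCY = 0.5


@dataclass(frozen=True)
class HarmonicComponent:
    """One sinusoidal displacement component A·sin(2πf·t + φ)."""

    amplitude: float  # m
    frequency: float  # Hz
    phase: float = 0.0  # rad

    def __post_init__(self) -> None:
        if not (self.amplitude > 0):
            raise InvalidParameterError(
                f"component amplitude must be > 0, got {self.amplitude}")
        if not (self.frequency > 0):
            raise InvalidParameterError(
                f"component frequency must be > 0, got {self.frequency}")

    @property
    def omega(self) -> float:
        """Angular frequency ω = 2πf, rad/s."""
        return 2.0 * math.pi * self.frequency


@dataclass(frozen=True)
class MicromotionWaveform:
    """Periodic electrode displacement as a sum of harmonics.

    The default is the single respiratory component: 15 µm amplitude
    (30 µm peak-to-peak) at 0.5 Hz, zero phase.
    """

    components: tuple[HarmonicComponent, ...] = field(
        default_factory=lambda: (
            HarmonicComponent(DEFAULT_AMPLITUDE, DEFAULT_FREQUENCY, 0.0),))

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise InvalidParameterError("waveform needs at least one component")

    @classmethod
    def single(cls, amplitude: float = DEFAULT_AMPLITUDE,
               frequency: float = DEFAULT_FREQUENCY,
               phase: float = 0.0) -> "MicromotionWaveform":
        return cls((HarmonicComponent(amplitude, frequency, phase),))

    @property
    def period(self) -> float:
        """Common period: 1 / (greatest common rate of the component
        frequencies).  For the default single 0.5 Hz component this is 2 s.

        Frequencies are rationalized with ``Fraction.limit_denominator`` so
        that floating-point frequencies such as 0.1 behave as expected.
        """
        fracs = [Fraction(c.frequency).limit_denominator(10**6)
                 for c in self.components]
        gcd = reduce(lambda a, b: Fraction(
            math.gcd(a.numerator, b.numerator),
            math.lcm(a.denominator, b.denominator)), fracs)
        return float(1 / gcd)

    @property
    def amplitude_sum(self) -> float:
        """Σ|A| — an upper bound for |displacement|."""
        return sum(c.amplitude for c in self.components)

    @property
    def peak_speed_bound(self) -> float:
        """Σ A·ω — an upper bound for |velocity|."""
        return sum(c.amplitude * c.omega for c in self.components)


def displacement(waveform: MicromotionWaveform, t):
    """Electrode displacement x(t) = Σ A·sin(2πf·t + φ), in m.

    ``t`` may be a scalar or array of times in seconds.
    """
    t = np.asarray(t, dtype=float)
    x = np.zeros_like(t)
    for c in waveform.components:
        x = x + c.amplitude * np.sin(c.omega * t + c.phase)
    return x if x.ndim else float(x)


def velocity(waveform: MicromotionWaveform, t):
    """Electrode speed U(t) = dx/dt = Σ A·ω·cos(ωt + φ), in m/s."""
    t = np.asarray(t, dtype=float)
    u = np.zeros_like(t)
    for c in waveform.components:
        u = u + c.amplitude * c.omega * np.cos(c.omega * t + c.phase)
    return u if u.ndim else float(u)


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: density ρ (kg/m³) and dynamic viscosity μ (Pa·s)."""

    density: float
    dynamic_viscosity: float

    def __post_init__(self) -> None:
        if not (self.density > 0):
            raise InvalidParameterError(
                f"density must be > 0, got {self.density}")
        if not (self.dynamic_viscosity > 0):
            raise InvalidParameterError(
                f"dynamic viscosity must be > 0, got {self.dynamic_viscosity}")

    @property
    def kinematic_viscosity(self) -> float:
        """ν = μ/ρ, m²/s."""
        return self.dynamic_viscosity / self.density


#: Brain interstitial fluid: density of cerebrospinal fluid; viscosity is a
#: free parameter spanning 1.2–100 mPa·s, here set to the literature
#: mid-range 50 mPa·s used for the reference cavity scenario.
INTERSTITIAL_FLUID = FluidProperties(density=1006.0, dynamic_viscosity=50e-3)

#: DMEM/F12 + 1% FBS culture medium perfused through the flow chamber.
CULTURE_MEDIUM = FluidProperties(density=1009.0, dynamic_viscosity=0.930e-3)


def womersley_number(char_length: float, fluid: FluidProperties,
                     frequency: float) -> float:
    """Womersley number α = L·√(ωρ/μ) with ω = 2πf.

    α² compares the oscillation period with the time viscosity needs to
    diffuse momentum across the characteristic length L; α ≪ 1 means the
    velocity profile tracks the instantaneous wall motion (quasi-steady).

    The characteristic length convention is the caller's: use the full gap
    width for the peri-electrode channel and the half-height for the
    parallel-plate chamber.  ``frequency`` = 0 returns 0 (steady flow).
    """
    if not (char_length > 0):
        raise InvalidParameterError(
            f"char_length must be > 0, got {char_length}")
    if frequency < 0 or not math.isfinite(frequency):
        raise InvalidParameterError(
            f"frequency must be finite and >= 0, got {frequency}")
    if frequency == 0:
        return 0.0
    omega = 2.0 * math.pi * frequency
    return char_length * math.sqrt(omega * fluid.density
                                   / fluid.dynamic_viscosity)


DEFAULT_WAVEFORM = MicromotionWaveform()
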