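"""Wall shear stress in the fluid-filled peri-electrode gap.

The electrode oscillates tangentially inside a sealed, fluid-filled void
bounded by (rigid) brain tissue.  Each side gap of width ``h`` is modelled
as a plane channel: tissue wall at y = 0 (stationary), electrode wall at
y = h moving at the micromotion speed U(t).  Because the cavity is closed,
the end walls force the instantaneous cross-sectional flux to zero, which
superimposes a pressure-driven backflow on the Couette profile.

Three solution routes are provided:

* quasi-steady analytic (``couette_wss`` / ``wss_timeseries_analytic``) —
  valid when the Womersley number of the gap is small, which it is for all
  physiological parameter combinations considered (α ≤ 0.03);
* an unsteady finite-difference Stokes solver (``fd_gap_solver``) that
  makes no quasi-steady assumption and serves as the internal
  cross-check;
* the exact single-harmonic solution of the finite-gap oscillating-wall
  Stokes problem (``stokes_oscillating_wall_exact``), used to validate the
  FD solver outside the quasi-steady regime.

An optional lubrication (squeeze-film) term accounts for shear under the
electrode tip face when the motion has a component normal to the tissue.

Sign convention: reported wall shear stresses are τ = μ ∂u/∂y evaluated
at the wall (y measured from tissue to electrode).  For the closed cavity
the backflow reverses the velocity gradient at the tissue wall, so
``tau_tissue`` carries the sign of -U(t) while ``tau_electrode`` carries
the sign of U(t); flipping the drive flips every sign.  Peak and
cycle-average summaries use magnitudes and are convention-independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.linalg import solve_banded

from .errors import (ContactSingularityError, InvalidGeometryError,
                     InvalidParameterError, SolverFailureError)
from .kinematics import (FluidProperties, MicromotionWaveform, displacement,
                         velocity, womersley_number)

__all__ = [
    "EndCondition",
    "GapGeometry",
    "TissueProperties",
    "WallShearSeries",
    "couette_wss",
    "wss_timeseries_analytic",
    "fd_gap_solver",
    "stokes_oscillating_wall_exact",
    "squeeze_film_wss",
    "squeeze_film_radial_profile",
]

#: Womersley number above which the quasi-steady closed form is flagged.
QUASI_STEADY_ALPHA = 0.3


class EndCondition(str, Enum):
    """Axial boundary of the gap: sealed cavity or open channel."""

    CLOSED = "closed"
    OPEN = "open"


@dataclass(frozen=True)
class GapGeometry:
    """Peri-electrode void geometry.

    ``side_gap`` is the per-side electrode-tissue distance h.  The default
    electrode is the 100 µm probe; tip-face fields feed the optional
    squeeze-film term only.
    """

    side_gap: float
    electrode_diameter: float = 100e-6
    end_condition: EndCondition = EndCondition.CLOSED
    tip_face_radius: float | None = None
    tip_face_gap: float | None = None

    def __post_init__(self) -> None:
        if not (self.side_gap > 0):
            raise InvalidGeometryError(
                f"side_gap must be > 0, got {self.side_gap}")
        if not (self.electrode_diameter > 0):
            raise InvalidGeometryError(
                f"electrode_diameter must be > 0, got {self.electrode_diameter}")
        if self.tip_face_gap is not None and not (self.tip_face_gap > 0):
            raise InvalidGeometryError(
                f"tip_face_gap must be > 0, got {self.tip_face_gap}")
        # default tip face radius = electrode radius
        if self.tip_face_radius is None:
            object.__setattr__(self, "tip_face_radius",
                               self.electrode_diameter / 2.0)

    @property
    def void_diameter(self) -> float:
        """Void diameter = electrode diameter + both side gaps, m."""
        return self.electrode_diameter + 2.0 * self.side_gap


@dataclass(frozen=True)
class TissueProperties:
    """Mechanical constants of the peri-electrode brain tissue.

    Recorded for configuration completeness only: the flow model treats
    the tissue wall as rigid, so these values are consumed by no flow
    computation (a test asserts bit-identical results when they vary).
    """

    density: float = 1060.0          # kg/m³
    youngs_modulus: float = 6e3      # Pa
    poisson_ratio: float = 0.45


@dataclass(frozen=True)
class WallShearSeries:
    """Wall shear stress over (at least) one full period on a uniform grid.

    ``tau_tissue`` / ``tau_electrode`` are signed stresses at the two
    walls; ``peak_abs`` and ``cycle_avg_abs`` summarize the tissue-wall
    magnitude over exactly one period.
    """

    times: np.ndarray
    tau_tissue: np.ndarray
    tau_electrode: np.ndarray
    peak_abs: float
    cycle_avg_abs: float
    converged: bool = True

    @staticmethod
    def from_arrays(times: np.ndarray, tau_tissue: np.ndarray,
                    tau_electrode: np.ndarray,
                    converged: bool = True) -> "WallShearSeries":
        """Build a series, computing summaries by trapezoidal averaging.

        The arrays must span exactly one period with both endpoints
        included (times[-1] - times[0] = period).
        """
        mag = np.abs(tau_tissue)
        peak = float(np.max(mag))
        span = float(times[-1] - times[0])
        avg = float(np.trapezoid(mag, times) / span)
        return WallShearSeries(times=times, tau_tissue=tau_tissue,
                               tau_electrode=tau_electrode, peak_abs=peak,
                               cycle_avg_abs=avg, converged=converged)


def _check_quasi_steady(gap: GapGeometry, fluid: FluidProperties,
                        frequency: float) -> float:
    alpha = womersley_number(gap.side_gap, fluid, frequency)
    if alpha >= QUASI_STEADY_ALPHA:
        warnings.warn(
            f"gap Womersley number alpha={alpha:.3g} >= "
            f"{QUASI_STEADY_ALPHA}: quasi-steady closed form may be "
            "inaccurate; prefer fd_gap_solver", stacklevel=3)
    return alpha


def couette_wss(gap: GapGeometry, fluid: FluidProperties,
                wall_speed: float) -> tuple[float, float]:
    """Quasi-steady wall shear for electrode wall speed U.

    Closed ends (zero net flux): the Couette flux U·h/2 is cancelled by a
    pressure-driven backflow with dp/dx = 6μU/h², giving wall gradients
    du/dy = -2U/h at the tissue and +4U/h at the electrode, hence
    |τ_tissue| = 2μU/h and |τ_electrode| = 4μU/h.  Open ends: pure Couette,
    both |τ| = μU/h.

    Returns ``(tau_tissue, tau_electrode)`` in Pa, signed per the module
    convention (stress exerted by the fluid on each wall).
    """
    mu = fluid.dynamic_viscosity
    h = gap.side_gap
    u = wall_speed
    if gap.end_condition is EndCondition.CLOSED:
        # tau = mu*du/dy at the wall: du/dy|0 = -2U/h, du/dy|h = +4U/h
        return (-2.0 * mu * u / h, 4.0 * mu * u / h)
    return (mu * u / h, mu * u / h)


def wss_timeseries_analytic(gap: GapGeometry, fluid: FluidProperties,
                            waveform: MicromotionWaveform,
                            samples_per_period: int = 512) -> WallShearSeries:
    """Quasi-steady WSS time series: ``couette_wss`` applied to U(t).

    Samples one full period on ``samples_per_period`` + 1 points (both
    endpoints included) and summarizes peak and cycle-average magnitude.
    """
    if samples_per_period < 64:
        raise InvalidParameterError(
            f"samples_per_period must be >= 64, got {samples_per_period}")
    f_max = max(c.frequency for c in waveform.components)
    _check_quasi_steady(gap, fluid, f_max)
    period = waveform.period
    t = np.linspace(0.0, period, samples_per_period + 1)
    u = velocity(waveform, t)
    mu = fluid.dynamic_viscosity
    h = gap.side_gap
    if gap.end_condition is EndCondition.CLOSED:
        tau_t = -2.0 * mu * u / h
        tau_e = 4.0 * mu * u / h
    else:
        tau_t = mu * u / h
        tau_e = mu * u / h
    return WallShearSeries.from_arrays(t, tau_t, tau_e)


# ---------------------------------------------------------------------------
# Unsteady finite-difference solver (1-D Stokes, Crank-Nicolson)
# ---------------------------------------------------------------------------

def fd_gap_solver(gap: GapGeometry, fluid: FluidProperties,
                  waveform: MicromotionWaveform, n_points: int = 201,
                  steps_per_period: int = 400,
                  n_periods: int = 5) -> WallShearSeries:
    """Unsteady Stokes solver for the gap flow.

    Solves ∂u/∂t = ν ∂²u/∂y² - G(t)/ρ on y ∈ [0, h] with u(0,t) = 0
    (tissue) and u(h,t) = U(t) (electrode).  For a closed cavity the axial
    pressure gradient G(t) is determined at every step so that the
    cross-sectional flux ∫u dy vanishes exactly; for open ends G ≡ 0.

    Time integration is Crank-Nicolson.  The flux constraint is imposed by
    linear superposition: each step solves one tridiagonal system with
    G = 0 and one with a unit forcing and homogeneous BCs, then combines
    them so the discrete (trapezoidal) flux is zero to round-off.

    The first ``n_periods - 2`` periods are discarded as transient (at
    least 3); the returned series covers the last full period.  Tissue-wall
    WSS uses a one-sided second-order derivative stencil.
    """
    if n_points < 51:
        raise InvalidParameterError(f"n_points must be >= 51, got {n_points}")
    if steps_per_period < 200:
        raise InvalidParameterError(
            f"steps_per_period must be >= 200, got {steps_per_period}")
    if n_periods < 5:
        raise InvalidParameterError(
            f"n_periods must be >= 5, got {n_periods}")

    h = gap.side_gap
    nu = fluid.kinematic_viscosity
    mu = fluid.dynamic_viscosity
    closed = gap.end_condition is EndCondition.CLOSED

    period = waveform.period
    dt = period / steps_per_period
    dy = h / (n_points - 1)
    n_in = n_points - 2                      # interior unknowns
    r = nu * dt / dy**2                      # diffusion number

    # Crank-Nicolson tridiagonal operators for the interior.
    ab = np.zeros((3, n_in))
    ab[0, 1:] = -0.5 * r
    ab[1, :] = 1.0 + r
    ab[2, :-1] = -0.5 * r

    n_steps = steps_per_period * n_periods
    t_grid = dt * np.arange(n_steps + 1)
    u_wall = velocity(waveform, t_grid)       # electrode wall speed

    u = np.zeros(n_points)                    # start from rest
    # storage for the final period (endpoints inclusive)
    keep_from = n_steps - steps_per_period
    tau_t = np.empty(steps_per_period + 1)
    tau_e = np.empty(steps_per_period + 1)

    # trapezoidal quadrature weights for the flux constraint
    w = np.full(n_points, dy)
    w[0] = w[-1] = dy / 2.0

    def wall_shear(field: np.ndarray) -> tuple[float, float]:
        # one-sided second-order stencils at both walls; tau = mu*du/dy
        # evaluated at the wall matches the couette_wss sign convention
        dudy_0 = (-3.0 * field[0] + 4.0 * field[1] - field[2]) / (2.0 * dy)
        dudy_h = (3.0 * field[-1] - 4.0 * field[-2] + field[-3]) / (2.0 * dy)
        return (mu * dudy_0, mu * dudy_h)

    if 0 >= keep_from:
        tau_t[0], tau_e[0] = wall_shear(u)

    for step in range(1, n_steps + 1):
        ub_old, ub_new = u_wall[step - 1], u_wall[step]
        # RHS: explicit half of CN
        rhs = (u[1:-1] + 0.5 * r * (u[2:] - 2.0 * u[1:-1] + u[:-2]))
        rhs[-1] += 0.5 * r * ub_new          # new-time Dirichlet at y=h
        u_a = np.empty(n_points)
        u_a[0] = 0.0
        u_a[-1] = ub_new
        u_a[1:-1] = solve_banded((1, 1), ab, rhs)

        if closed:
            # unit-forcing response: (I - 0.5 r D) u_b = -dt (per unit G/rho)
            u_b = np.zeros(n_points)
            u_b[1:-1] = solve_banded((1, 1), ab, np.full(n_in, -dt))
            flux_a = float(w @ u_a)
            flux_b = float(w @ u_b)
            g_over_rho = -flux_a / flux_b
            u = u_a + g_over_rho * u_b
        else:
            u = u_a

        if not np.all(np.isfinite(u)):
            raise SolverFailureError(
                "non-finite velocity field", step=step, diagnostic=r)

        if step >= keep_from:
            k = step - keep_from
            tau_t[k], tau_e[k] = wall_shear(u)

    t_out = t_grid[keep_from:]
    return WallShearSeries.from_arrays(t_out, tau_t, tau_e)


def fd_flux_history(gap: GapGeometry, fluid: FluidProperties,
                    waveform: MicromotionWaveform, n_points: int = 201,
                    steps_per_period: int = 400,
                    n_periods: int = 5) -> np.ndarray:
    """Normalized closed-end flux residual |∫u dy| / (h·max|u|) per step.

    Re-runs the solver loop retaining the constraint residual; used to
    verify that the zero-net-flux condition holds to round-off.
    """
    h = gap.side_gap
    nu = fluid.kinematic_viscosity
    period = waveform.period
    dt = period / steps_per_period
    dy = h / (n_points - 1)
    n_in = n_points - 2
    r = nu * dt / dy**2
    ab = np.zeros((3, n_in))
    ab[0, 1:] = -0.5 * r
    ab[1, :] = 1.0 + r
    ab[2, :-1] = -0.5 * r
    n_steps = steps_per_period * n_periods
    u_wall = velocity(waveform, dt * np.arange(n_steps + 1))
    u = np.zeros(n_points)
    w = np.full(n_points, dy)
    w[0] = w[-1] = dy / 2.0
    out = np.empty(n_steps)
    for step in range(1, n_steps + 1):
        rhs = (u[1:-1] + 0.5 * r * (u[2:] - 2.0 * u[1:-1] + u[:-2]))
        rhs[-1] += 0.5 * r * u_wall[step]
        u_a = np.empty(n_points)
        u_a[0] = 0.0
        u_a[-1] = u_wall[step]
        u_a[1:-1] = solve_banded((1, 1), ab, rhs)
        u_b = np.zeros(n_points)
        u_b[1:-1] = solve_banded((1, 1), ab, np.full(n_in, -dt))
        u = u_a - (float(w @ u_a) / float(w @ u_b)) * u_b
        scale = gap.side_gap * max(float(np.max(np.abs(u))), 1e-300)
        out[step - 1] = abs(float(w @ u)) / scale
    return out


def stokes_oscillating_wall_exact(gap: GapGeometry, fluid: FluidProperties,
                                  amplitude: float,
                                  frequency: float) -> float:
    """Tissue-wall WSS amplitude for the open-ended oscillating-wall flow.

    Exact single-harmonic solution of ∂u/∂t = ν ∂²u/∂y² with u(0) = 0 and
    u(h,t) = Re[Û e^{iωt}], Û = Aω:

        u(y,t) = Re[Û sinh(λy)/sinh(λh) e^{iωt}],   λ = √(iω/ν)

    so the tissue-wall shear amplitude is |μ Û λ / sinh(λh)|.  Valid at any
    Womersley number; reduces to μÛ/h as α → 0.
    """
    if gap.end_condition is not EndCondition.OPEN:
        raise InvalidParameterError(
            "exact oscillating-wall solution applies to open ends only")
    omega = 2.0 * math.pi * frequency
    nu = fluid.kinematic_viscosity
    lam = np.sqrt(1j * omega / nu)
    u_hat = amplitude * omega
    return float(np.abs(fluid.dynamic_viscosity * u_hat * lam
                        / np.sinh(lam * gap.side_gap)))


# ---------------------------------------------------------------------------
# Squeeze film under the tip face
# ---------------------------------------------------------------------------

def squeeze_film_wss(tip_face_radius: float, mean_gap: float,
                     waveform_normal: MicromotionWaveform,
                     fluid: FluidProperties, r, t):
    """Lubrication shear under a rigid disc approaching a plane.

    Film thickness g(t) = mean_gap + normal displacement; the Reynolds
    equation for the radial squeeze flow gives a tissue-wall shear
    magnitude τ(r,t) = 3μ·r·|ġ(t)| / g(t)², zero on the axis and maximal
    at the disc rim.  Refuses to run if the normal-motion amplitude
    reaches the mean gap (film contact).
    """
    if not (tip_face_radius > 0) or not (mean_gap > 0):
        raise InvalidParameterError("tip_face_radius and mean_gap must be > 0")
    if waveform_normal.amplitude_sum >= mean_gap:
        raise ContactSingularityError(
            f"normal-motion amplitude {waveform_normal.amplitude_sum:.3g} m "
            f">= mean gap {mean_gap:.3g} m: film contact")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > tip_face_radius):
        raise InvalidParameterError("r must lie in [0, tip_face_radius]")
    g = mean_gap + displacement(waveform_normal, t)
    gdot = velocity(waveform_normal, t)
    tau = 3.0 * fluid.dynamic_viscosity * r * np.abs(gdot) / np.asarray(g)**2
    return tau if np.ndim(tau) else float(tau)


def squeeze_film_radial_profile(mean_gap: float,
                                waveform_normal: MicromotionWaveform,
                                fluid: FluidProperties, r: float, t: float,
                                y: np.ndarray) -> np.ndarray:
    """Radial velocity profile u_r(y) of the squeeze film at radius r.

    Poiseuille profile driven by dp/dr = 6μ r ġ / g³; integrating it over
    the film and around the circumference recovers the displaced volume
    rate -ġ·πr² (mass conservation), which the tests verify numerically.
    """
    mu = fluid.dynamic_viscosity
    g = mean_gap + float(displacement(waveform_normal, t))
    gdot = float(velocity(waveform_normal, t))
    dpdr = 6.0 * mu * r * gdot / g**3
    return (dpdr / (2.0 * mu)) * (np.asarray(y)**2 - g * np.asarray(y))
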