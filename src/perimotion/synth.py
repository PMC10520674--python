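"""Synthetic micromotion and WSS traces with known ground truth.

No raw micromotion recordings are published with the modelling study this
package operationalizes, so validation runs on synthetic data: the
forward model is the quasi-steady closed-cavity shear series, observed
with multiplicative Gaussian noise (relative noise, because shear
magnitudes span four orders of magnitude across the parameter sweep).

Micromotion is a respiratory sinusoid (15 µm, 0.5 Hz) optionally summed
with a cardiac component; the literature attributes micromotion to both
sources but prints no cardiac numbers, so the cardiac default here
(3 µm at 5 Hz) is a synthetic choice confined to this module.

Recovery is single-parameter weighted least squares by construction: the
tissue-wall shear 2μU(t)/h depends on μ and h only through μ/h, so the
pair is structurally non-identifiable from a shear trace and a joint fit
is refused rather than regularized away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (EstimationFailureError, InvalidParameterError,
                     NonIdentifiableError)
from .gap_flow import EndCondition, GapGeometry
from .kinematics import (FluidProperties, HarmonicComponent,
                         MicromotionWaveform, displacement, velocity)

__all__ = [
    "SyntheticSpec",
    "NoisyWSSTrace",
    "gen_micromotion",
    "gen_wss_observations",
    "recover_gap",
    "recover_viscosity",
    "recover_joint",
    "DEFAULT_CARDIAC",
]

#: Synthetic cardiac micromotion component (amplitude m, frequency Hz).
#: Not a published value — a plausible pulsatile term for test traces.
DEFAULT_CARDIAC = (3e-6, 5.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic trace.

    ``respiratory`` / ``cardiac`` are (amplitude m, frequency Hz) pairs;
    ``displacement_noise_sd`` is additive (m) on the motion trace,
    ``wss_noise_rel_sd`` is the relative SD of the multiplicative WSS
    noise.  The same seed and spec always reproduce the trace bit for
    bit.
    """

    respiratory: tuple[float, float] = (15e-6, 0.5)
    cardiac: tuple[float, float] | None = None
    displacement_noise_sd: float = 0.0
    wss_noise_rel_sd: float = 0.0
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.displacement_noise_sd < 0 or self.wss_noise_rel_sd < 0:
            raise InvalidParameterError("noise SDs must be >= 0")
        if self.n_samples < 2:
            raise InvalidParameterError(
                f"n_samples must be >= 2, got {self.n_samples}")

    def waveform(self) -> MicromotionWaveform:
        comps = [HarmonicComponent(*self.respiratory)]
        if self.cardiac is not None:
            comps.append(HarmonicComponent(*self.cardiac))
        return MicromotionWaveform(tuple(comps))


@dataclass(frozen=True)
class NoisyWSSTrace:
    """Observed shear series plus the ground truth that generated it."""

    times: np.ndarray
    tau_obs: np.ndarray
    truth_gap: float
    truth_viscosity: float
    truth_waveform: MicromotionWaveform
    seed: int

    def __post_init__(self) -> None:
        if len(self.times) != len(self.tau_obs):
            raise InvalidParameterError("times/tau_obs length mismatch")


def _time_grid(waveform: MicromotionWaveform, n: int) -> np.ndarray:
    """n samples over one common period, endpoint excluded."""
    return np.linspace(0.0, waveform.period, n, endpoint=False)


def gen_micromotion(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample the (possibly multi-harmonic) displacement trace.

    Returns ``(times, displacement)`` over one common period with
    additive zero-mean Gaussian noise of SD ``displacement_noise_sd``.
    """
    wf = spec.waveform()
    t = _time_grid(wf, spec.n_samples)
    x = displacement(wf, t)
    if spec.displacement_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        x = x + rng.normal(0.0, spec.displacement_noise_sd, size=t.shape)
    return t, x


def gen_wss_observations(gap: GapGeometry, fluid: FluidProperties,
                         spec: SyntheticSpec) -> NoisyWSSTrace:
    """Forward-simulate a noisy tissue-wall shear trace.

    τ_obs(t) = τ_model(t)·(1 + ε),  ε ~ N(0, wss_noise_rel_sd²) i.i.d.,
    where τ_model is the quasi-steady closed-cavity tissue-wall shear.
    With zero noise the trace equals the forward model exactly.
    """
    wf = spec.waveform()
    t = _time_grid(wf, spec.n_samples)
    u = velocity(wf, t)
    mu = fluid.dynamic_viscosity
    h = gap.side_gap
    if gap.end_condition is EndCondition.CLOSED:
        tau = -2.0 * mu * u / h
    else:
        tau = mu * u / h
    if spec.wss_noise_rel_sd > 0:
        rng = np.random.default_rng(spec.seed)
        tau = tau * (1.0 + rng.normal(0.0, spec.wss_noise_rel_sd,
                                      size=t.shape))
    return NoisyWSSTrace(times=t, tau_obs=tau, truth_gap=h,
                         truth_viscosity=mu, truth_waveform=wf,
                         seed=spec.seed)


def _scale_fit(tau_obs: np.ndarray, regressor: np.ndarray) -> tuple[float, float]:
    """WLS slope of τ_obs on a known regressor under relative noise.

    Model: τ_obs_i = β·c_i·(1+ε_i).  With weights 1/c_i² (inverse noise
    variance) the estimator reduces to β̂ = mean(τ_obs_i/c_i) over samples
    with c_i ≠ 0; its standard error comes from the curvature of the
    weighted least-squares objective, se = sd(τ_obs/c)/√m.
    """
    if not np.all(np.isfinite(tau_obs)):
        raise EstimationFailureError("trace contains non-finite values")
    keep = np.abs(regressor) > 1e-12 * np.max(np.abs(regressor))
    if not np.any(keep) or np.allclose(tau_obs, 0.0):
        raise EstimationFailureError("trace is all-zero or degenerate")
    ratio = tau_obs[keep] / regressor[keep]
    m = ratio.size
    beta = float(np.mean(ratio))
    se = float(np.std(ratio, ddof=1) / math.sqrt(m)) if m > 1 else math.inf
    if beta <= 0:
        raise EstimationFailureError(
            f"fitted scale is non-positive ({beta:.3g})")
    return beta, se


def recover_gap(trace: NoisyWSSTrace, known_fluid: FluidProperties,
                known_waveform: MicromotionWaveform) -> dict[str, float]:
    """Estimate the per-side gap from a shear trace, μ and U(t) known.

    The forward model is τ(t) = -2μU(t)/h, linear in 1/h, so the WLS
    scale fit yields 1/ĥ directly; the delta method converts the scale
    standard error to one on ĥ.  Returns ``{"gap_hat": m, "se": m}``.
    """
    u = velocity(known_waveform, trace.times)
    c = -2.0 * known_fluid.dynamic_viscosity * u   # tau = c / h
    beta, se_beta = _scale_fit(trace.tau_obs, c)   # beta = 1/h
    gap_hat = 1.0 / beta
    return {"gap_hat": gap_hat, "se": se_beta * gap_hat**2}


def recover_viscosity(trace: NoisyWSSTrace, known_gap: GapGeometry,
                      known_waveform: MicromotionWaveform) -> dict[str, float]:
    """Estimate the fluid viscosity from a shear trace, h and U(t) known.

    Mirror of :func:`recover_gap`: τ(t) = μ·(-2U(t)/h) is linear in μ.
    Returns ``{"mu_hat": Pa·s, "se": Pa·s}``.
    """
    u = velocity(known_waveform, trace.times)
    c = -2.0 * u / known_gap.side_gap              # tau = mu * c
    mu_hat, se = _scale_fit(trace.tau_obs, c)
    return {"mu_hat": mu_hat, "se": se}


def recover_joint(trace: NoisyWSSTrace,
                  known_waveform: MicromotionWaveform) -> None:
    """Joint (μ, h) recovery — structurally impossible; always refused.

    The tissue-wall shear depends on μ and h only through the ratio μ/h:
    scaling both by any c > 0 leaves the noiseless trace unchanged, so no
    amount of data separates them.  Fix one parameter and use
    :func:`recover_gap` or :func:`recover_viscosity`.
    """
    raise NonIdentifiableError(
        "joint (viscosity, gap) recovery is refused: the tissue-wall shear "
        "2*mu*U(t)/h depends on mu and h only through mu/h, so the pair is "
        "structurally non-identifiable from a WSS trace; fix one parameter "
        "and use recover_gap or recover_viscosity")
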