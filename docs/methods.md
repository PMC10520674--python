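# Methods

## Physical picture

A cylindrical neural probe (diameter 100 µm) sits inside a fluid-filled
void in brain tissue and oscillates tangentially with respiration:
displacement x(t) = A·sin(ωt), A = 15 µm (30 µm peak-to-peak),
f = 0.5 Hz. The fluid is treated as Newtonian with the density of
cerebrospinal fluid (1006 kg·m⁻³) and a dynamic viscosity swept over the
literature range for brain interstitial fluid, 1.2–100 mPa·s (50 mPa·s is
used as the mid-range reference). The tissue wall is rigid: tissue
elastic constants (1060 kg·m⁻³, E = 6 kPa, ν = 0.45) are recorded in
`TissueProperties` for configuration completeness but are consumed by no
flow computation, and a test asserts flow outputs are unchanged when they
vary. Fluid–structure interaction is out of scope.

## Gap flow

Each side gap of width h is a plane channel with a stationary wall
(tissue, y = 0) and a wall moving at U(t) = Aω·cos(ωt) (electrode,
y = h). Two regimes:

**Quasi-steady (α ≪ 1).** The Womersley number α = h√(ωρ/μ) compares the
oscillation period with the viscous diffusion time across the gap. For
every physiological combination considered here α ≤ 0.25 (0.013 at the
reference point), so the profile tracks the instantaneous wall speed.
With sealed ends the instantaneous flux must vanish; superposing the
Couette profile (flux Uh/2) with the Poiseuille backflow needed to cancel
it (dp/dx = 6μU/h²) gives wall velocity gradients −2U/h at the tissue and
+4U/h at the electrode, hence

|τ_tissue| = 2μU/h, |τ_electrode| = 4μU/h (closed), |τ| = μU/h (open).

The closed-end condition is the default: the void is a sealed cavity, and
only the closed-end tissue formula reproduces the ≈0.1 Pa reference value
at (h, μ) = (50 µm, 50 mPa·s) — the open-end value is 0.047 Pa. Reported
stresses are τ = μ∂u/∂y at the wall; peak and cycle-average summaries use
magnitudes and are phase- and sign-convention-invariant (tested). For a
single sinusoid the cycle-average/peak ratio is 2/π.

**Unsteady (any α).** `fd_gap_solver` integrates
∂u/∂t = ν∂²u/∂y² − G(t)/ρ with u(0,t) = 0, u(h,t) = U(t), by
Crank–Nicolson (θ = ½, second order in time and space). For closed ends
G(t) is found by linear superposition — two tridiagonal solves per step
(`scipy.linalg.solve_banded`), combined so the trapezoidal flux is zero
to round-off (verified ≤ 10⁻¹⁰·h·max|u| at every step). Wall shear uses a
one-sided second-order stencil so WSS convergence matches the field's
order. Defaults: 201 grid points, 400 steps per period, 5 periods with
the first 4 discarded as start-up transient (the slowest transient mode
decays like exp(−νπ²t/h²), negligible after one period in the quasi-steady
regime and after ~4 periods at α = 5). The solver is validated two ways:
against the quasi-steady closed form (1% at α < 0.1, randomized (h, μ)
pairs) and against the exact finite-gap oscillating-wall solution
u = Re[Û sinh(λy)/sinh(λh)·e^{iωt}], λ = √(iω/ν), whose tissue-wall shear
amplitude is |μÛλ/sinh(λh)| (1% at α = 5, open ends). Observed grid
convergence is second order.

**Squeeze film.** Motion normal to the tip face is covered by the
lubrication result for a rigid disc approaching a plane: film g(t) =
mean gap + normal displacement, radial pressure gradient dp/dr = 6μrġ/g³,
wall shear magnitude τ(r) = 3μr|ġ|/g² — zero on the axis, maximal at the
rim, with the radial flux at radius r equal to the displaced volume rate
−ġπr² (tested by numerical integration of the profile). The term refuses
to run at amplitude ≥ mean gap (contact singularity). It is an optional
account of the higher tip-region stresses; it is deliberately not tuned
to reproduce any full-geometry reference value.

**Known limitation.** The reduced-order tangential model is 1-D. The
published full finite-volume sweep value at the high-shear corner
(10 µm, 100 mPa·s) is ≈2 Pa, about 2× the tangential prediction
(0.94 Pa peak); the spatial-averaging surface and tip-gap dimension
needed to close that factor are not derivable from printed information,
so the package asserts only order-of-magnitude agreement and the correct
monotone position (sweep maximum) for that corner. The low-shear corner
(150 µm, 1.2 mPa·s) agrees with its 6×10⁻⁴ Pa reference within a factor
of 1.25. Whether published sweep values are peak or time-averaged is
ambiguous, so both metrics are always reported.

## Flow-chamber dosimetry

Plane-Poiseuille dosimetry τ_w = 6Qμ/(bh²) with culture medium
(1009 kg·m⁻³, 0.930 mPa·s). Only the aspect ratio b/h = 120 and the
calibration pair (4.49 mL·min⁻¹, 0.1 Pa) are published, so the geometry
is closed at run time: h = (6Qμ/(τ·120))^{1/3} = 326.5 µm,
b = 120h = 39.2 mm — consistent with a 38 mm slide. Linearity then gives
22.45 mL·min⁻¹ for 0.5 Pa and 44.9 mL·min⁻¹ for 1 Pa. (The published
upper flow bound of 381 mL·min⁻¹ cannot be reconciled with linear scaling
to 10 Pa, which requires 449 mL·min⁻¹; surfaced here, not modelled.)

The Reynolds convention is the channel height: Re = ρūh/μ = ρQ/(μb),
the only standard choice under which the 0.1 Pa condition (Re = 2.07)
obeys the quoted operating bound of 2.4 — a hydraulic-diameter
convention gives ≈4.1. This inference is recorded as such.
Oscillatory operation at 0.5 Hz is treated as quasi-steady modulation of
the steady profile, justified by α(h/2) = 0.30 < 1; `homogeneity_report`
echoes α and Re with quasi-steady (α < 1) and laminar (Re < 1400,
plane-channel transition heuristic) flags. Entrance effects and the
cell layer's perturbation of the profile are not modelled.

## Void expansion

Only two facts anchor the biology: WSS above ≈0.1 Pa marks astrocyte
reactivity, and chronic voids stabilize at a finite diameter. The
dynamic law dg/dt = k·max(0, τ(g) − τ_c) is this package's own minimal
closure: regression rate proportional to the shear excess, per side with
symmetric gaps. The rate constant k (m·Pa⁻¹·s⁻¹) is explicitly
non-identifiable from published information and sets only the relaxation
time ≈ g\*/(kτ_c); the terminal gap is k-independent (tested). With the
peak metric and the closed-cavity model, τ(g) = 2μU_peak/g gives the
closed form g\* = 2μU_peak/τ_c; `steady_state_gap` solves the general
monotone root problem with Brent's method and reproduces the closed form
to 10⁻⁶. Integration is explicit Euler with step-halving acceptance
(increment ≤ 1% of the current gap) — adequate for a monotone scalar ODE;
trajectories are flagged unconverged if the shear excess has not fallen
to 10⁻⁶τ_c by the horizon.

At the reference parameters (μ = 50 mPa·s, τ_c = 0.1 Pa, peak metric) the
model predicts a 194 µm void, 1.9× the electrode diameter — at the lower
edge of the observed 2–4× envelope, and below the ≈3–4× sometimes
quoted. The shortfall is documented rather than calibrated away: it is
sensitive to the metric choice (the cycle-average metric shrinks g\* by
2/π; a lower effective threshold or tip squeeze-film contributions
enlarge it), and all three knobs are exposed (`wss_metric`,
`tau_threshold`, the squeeze-film term). Default metric is peak because
the 0.1 Pa benchmark is reproduced by the peak formula.

## Synthetic data and recovery

The generator emulates what a bench characterization of the system would
produce, not any published raw data: a respiratory sinusoid (15 µm,
0.5 Hz), optionally a cardiac harmonic (defaults 3 µm, 5 Hz — synthetic
choices, no published values exist; confined to this module), additive
Gaussian displacement noise, and WSS observations with multiplicative
noise τ_obs = τ·(1+ε), ε ~ N(0, σ²_rel). Relative noise is chosen because
shear magnitudes span four decades across the sweep. All generators are
seeded (`numpy.random.default_rng`) and bit-reproducible.

Recovery exploits the model's structure: τ(t) = β·c(t) with known
regressor c(t) = −2μU(t) (β = 1/h) or −2U(t)/h (β = μ). Under relative
noise, inverse-variance weights make the WLS estimator
β̂ = mean(τ_obs/c) over samples with c ≠ 0, with the standard error from
the curvature of the weighted objective. Noiseless recovery is exact;
at 5% noise and n = 1000 the error is ≲1% RMS (well inside the 10%
validation band), bias ≤1% over 200 replicates, and the RMS error scales
as 1/√n (tested over n = 10²–10⁴). Joint (μ, h) recovery is refused with
an explanatory error: the trace depends on the pair only through μ/h, a
structural non-identifiability that is enforced, not worked around.
What passing these tests shows is internal consistency of the estimator
with the forward model under idealized noise; real micromotion spectra,
non-stationary noise and model misspecification are not represented.

## Problem sizes and numerical defaults

Defaults are chosen so every routine is interactive on a laptop: analytic
series at 512 samples/period (2048 where the 2/π identity is checked to
0.5%); FD solver 201×400×5 (about 2×10³ tridiagonal solves); sweep 8×8
cells; recovery validation at n = 10²–10⁴ with ≤200 replicates. The
whole test suite runs in ~10 s.

## Configuration and units

SI units internally, everywhere. The JSON config and CLI accept the
practitioner units (µm, mPa·s, mL·min⁻¹) and convert at the boundary.
Config validation is strict (unknown keys rejected with their field
path, via pydantic). Computational output is tidy CSV on stdout or
`--out`; logs go to stderr only. Exit codes: 0 success, 2 validation
error, 3 solver failure.
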