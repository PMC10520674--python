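# perimotion

Reduced-order biofluid mechanics of neuroelectrode micromotion.

Chronically implanted neural probes move relative to the brain with every
breath (≈30 µm peak-to-peak at 0.5 Hz). That micromotion pumps the
interstitial fluid filling the peri-electrode void and imparts a wall
shear stress (WSS) on the surrounding tissue — a candidate mechanical
driver of reactive astrogliosis and of the progressive tissue recession
that leaves chronic electrodes sitting in a fluid-filled cavity several
times their own diameter. `perimotion` is a small, tested Python package
for engineers and mechanobiologists working on implant–tissue interfaces.
It computes:

1. **Peri-electrode gap flow.** Each side gap of width *h* is a plane
   channel: stationary tissue wall, electrode wall moving at
   *U(t) = 2πfA·*cos(2π*f t*). In a sealed cavity the end walls force the
   cross-sectional flux to zero, superimposing a pressure-driven backflow,
   so the tissue-wall shear is

   |τ_tissue| = 2 μ U / h (closed ends), μ U / h (open ends).

   Validity of this quasi-steady form is governed by the Womersley number
   α = h√(ωρ/μ) ≪ 1; an unsteady finite-difference Stokes solver
   (Crank–Nicolson, exact per-step zero-net-flux constraint) covers the
   general case and cross-checks the closed form. A lubrication
   (squeeze-film) term τ = 3 μ r |ġ| / g² is available for normal motion
   under the electrode tip face.

2. **Parallel-plate flow-chamber (PPFC) dosimetry.** The in-vitro arm
   delivers a prescribed WSS to a cell monolayer through plane Poiseuille
   flow, τ_w = 6 Q μ / (b h²). The chamber geometry is closed from the
   aspect ratio b/h = 120 plus the calibration 4.49 mL·min⁻¹ ↦ 0.1 Pa,
   and every condition carries its Reynolds (Re = ρQ/(μb)) and Womersley
   numbers to confirm laminar, quasi-steady, spatially homogeneous shear.

3. **Void expansion to a steady state.** If tissue regresses while the
   WSS exceeds a reactivity threshold τ_c (default 0.1 Pa), the gap obeys
   dg/dt = k·max(0, τ(g) − τ_c) and stops growing at the fixed point
   g\* = 2 μ U_peak / τ_c — a predicted steady-state void diameter of
   electrode + 2g\*.

4. **Synthetic traces and parameter recovery.** Seeded generators produce
   multi-harmonic micromotion and noisy WSS observations with known
   ground truth; weighted least squares recovers the gap or viscosity
   (the pair (μ, h) is structurally non-identifiable from a shear trace
   and a joint fit is refused).

## Worked example

Shear in the reference cavity — a 100 µm electrode with a 50 µm gap on
each side, interstitial viscosity 50 mPa·s:

```console
$ perimotion gapflow --gap-um 50 --viscosity-mpas 50
gap_um,viscosity_mpas,wss_peak_pa,wss_cycle_avg_pa,womersley,solver
50,50,0.0942477796,0.059999247,0.0125706846,analytic
```

The peak tissue-wall WSS is 0.094 Pa (≈0.1 Pa), the cycle-averaged
magnitude is 2/π of the peak, and α ≈ 0.013 confirms the quasi-steady
regime. The matching in-vitro dose:

```console
$ perimotion ppfc --target-wss-pa 0.1
flow_ml_min,wss_pa,height_um,width_mm,reynolds,womersley,quasi_steady
4.49,0.1,326.474562,39.1769474,2.07239585,0.301368875,True
```

i.e. the solved chamber is 326 µm high and 39.2 mm wide, and the 0.1 Pa
condition runs at Re ≈ 2.07 (laminar) with α ≈ 0.30 (quasi-steady, hence
homogeneous WSS over the monolayer). Finally, the predicted steady state
of the expanding void:

```console
$ perimotion void
steady_gap_um,void_diameter_um,ratio_to_electrode_diameter,converged
47.1238429,194.247686,1.94247686,True
```

The per-side gap settles at 47.1 µm where the peak WSS has fallen to the
0.1 Pa threshold, giving a 194 µm void — about 1.9× the electrode
diameter, at the lower edge of the 2–4× envelope reported from chronic
implants. `perimotion sweep` reproduces the full gap × viscosity WSS
surface as tidy CSV, and `perimotion synth` / `perimotion recover` drive
the synthetic-data validation loop.

## Layout

- `src/perimotion/kinematics.py` — waveforms, fluid properties, Womersley number
- `src/perimotion/gap_flow.py` — analytic + FD gap-flow solvers, squeeze film
- `src/perimotion/ppfc.py` — chamber dosimetry and regime checks
- `src/perimotion/void_dynamics.py` — threshold-regression void model
- `src/perimotion/synth.py` — synthetic traces and parameter recovery
- `src/perimotion/sweep.py`, `config.py`, `cli.py` — sweep engine, JSON config, CLI

See `docs/methods.md` for the model derivations, assumptions, numerical
choices and known limitations.
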