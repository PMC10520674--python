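"""Peri-electrode gap flow: analytic Couette model, FD solver, squeeze film."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import perimotion as pm
from perimotion.gap_flow import fd_flux_history, squeeze_film_radial_profile

PEAK_U = 2.0 * math.pi * 0.5 * 15e-6


def alpha_of(h, mu, rho=1006.0, f=0.5):
    return pm.womersley_number(h, pm.FluidProperties(rho, mu), f)


class TestCouette:
    def test_reference_cavity_reproduces_tenth_pascal_benchmark(
            self, reference_gap, interstitial_50):
        tau_t, tau_e = pm.couette_wss(reference_gap, interstitial_50, PEAK_U)
        assert abs(tau_t) == pytest.approx(0.0942, rel=1e-3)
        assert abs(tau_e) == pytest.approx(2.0 * abs(tau_t), rel=1e-12)

    def test_open_ends_give_half_the_closed_tissue_stress(
            self, interstitial_50):
        gap_open = pm.GapGeometry(side_gap=50e-6,
                                  end_condition=pm.EndCondition.OPEN)
        tau_t, tau_e = pm.couette_wss(gap_open, interstitial_50, PEAK_U)
        assert tau_t == tau_e == pytest.approx(0.0471, rel=2e-3)

    def test_zero_speed_gives_zero_stress(self, reference_gap,
                                          interstitial_50):
        assert pm.couette_wss(reference_gap, interstitial_50, 0.0) == (0, 0)

    def test_sign_flips_with_wall_speed(self, reference_gap, interstitial_50):
        fwd = pm.couette_wss(reference_gap, interstitial_50, PEAK_U)
        rev = pm.couette_wss(reference_gap, interstitial_50, -PEAK_U)
        assert fwd[0] == -rev[0] and fwd[1] == -rev[1]

    @given(st.floats(10e-6, 150e-6), st.floats(1.2e-3, 100e-3),
           st.floats(1e-6, 1e-4))
    def test_exact_power_laws_in_mu_u_and_inverse_h(self, h, mu, u):
        fl = pm.FluidProperties(1006.0, mu)
        g = pm.GapGeometry(side_gap=h)
        base = pm.couette_wss(g, fl, u)[0]
        assert pm.couette_wss(g, pm.FluidProperties(1006.0, 2 * mu),
                              u)[0] == pytest.approx(2 * base, rel=1e-12)
        assert pm.couette_wss(g, fl, 2 * u)[0] == \
            pytest.approx(2 * base, rel=1e-12)
        assert pm.couette_wss(pm.GapGeometry(side_gap=2 * h), fl, u)[0] == \
            pytest.approx(base / 2, rel=1e-12)

    def test_invalid_gap_rejected(self):
        with pytest.raises(pm.InvalidGeometryError):
            pm.GapGeometry(side_gap=0.0)


class TestAnalyticSeries:
    def test_reference_cavity_peak_and_cycle_average(
            self, reference_gap, interstitial_50, waveform):
        s = pm.wss_timeseries_analytic(reference_gap, interstitial_50,
                                       waveform)
        assert s.peak_abs == pytest.approx(0.0942, rel=1e-3)
        assert s.cycle_avg_abs == pytest.approx(0.0600, rel=1e-3)

    def test_low_shear_cell_matches_derived_value(self, waveform):
        g = pm.GapGeometry(side_gap=150e-6)
        fl = pm.FluidProperties(1006.0, 1.2e-3)
        s = pm.wss_timeseries_analytic(g, fl, waveform)
        assert s.cycle_avg_abs == pytest.approx(4.80e-4, rel=1e-3)

    def test_sinusoid_average_to_peak_ratio_is_two_over_pi(
            self, reference_gap, interstitial_50, waveform):
        s = pm.wss_timeseries_analytic(reference_gap, interstitial_50,
                                       waveform)
        assert s.cycle_avg_abs / s.peak_abs == \
            pytest.approx(2.0 / math.pi, rel=5e-3)

    def test_signed_mean_vanishes_over_one_period(
            self, reference_gap, interstitial_50):
        wf = pm.MicromotionWaveform((pm.HarmonicComponent(15e-6, 0.5, 0.3),
                                     pm.HarmonicComponent(3e-6, 5.0, 1.1)))
        s = pm.wss_timeseries_analytic(reference_gap, interstitial_50, wf)
        mean = np.trapezoid(s.tau_tissue, s.times) / (s.times[-1] - s.times[0])
        assert abs(mean) < 1e-12 * s.peak_abs

    def test_summaries_are_phase_invariant(self, reference_gap,
                                           interstitial_50):
        base = pm.wss_timeseries_analytic(
            reference_gap, interstitial_50, pm.MicromotionWaveform.single())
        shifted = pm.wss_timeseries_analytic(
            reference_gap, interstitial_50,
            pm.MicromotionWaveform.single(phase=1.234))
        assert shifted.peak_abs == pytest.approx(base.peak_abs, rel=1e-4)
        assert shifted.cycle_avg_abs == pytest.approx(base.cycle_avg_abs,
                                                      rel=1e-4)

    def test_peak_dominates_cycle_average(self, reference_gap,
                                          interstitial_50, waveform):
        s = pm.wss_timeseries_analytic(reference_gap, interstitial_50,
                                       waveform)
        assert s.peak_abs >= s.cycle_avg_abs >= 0.0

    def test_too_coarse_sampling_rejected(self, reference_gap,
                                          interstitial_50, waveform):
        with pytest.raises(pm.InvalidParameterError):
            pm.wss_timeseries_analytic(reference_gap, interstitial_50,
                                       waveform, samples_per_period=32)

    def test_warns_outside_quasi_steady_regime(self, waveform):
        thin_fluid = pm.FluidProperties(1006.0, 1e-6)
        g = pm.GapGeometry(side_gap=150e-6)
        with pytest.warns(UserWarning, match="quasi-steady"):
            pm.wss_timeseries_analytic(g, thin_fluid, waveform)


class TestFDSolver:
    def test_matches_analytic_in_quasi_steady_regime(
            self, reference_gap, interstitial_50, waveform):
        ana = pm.wss_timeseries_analytic(reference_gap, interstitial_50,
                                         waveform)
        fd = pm.fd_gap_solver(reference_gap, interstitial_50, waveform)
        assert fd.peak_abs == pytest.approx(ana.peak_abs, rel=0.01)
        assert fd.cycle_avg_abs == pytest.approx(ana.cycle_avg_abs, rel=0.01)

    def test_oracle_equivalence_over_randomized_quasi_steady_pairs(
            self, waveform):
        rng = np.random.default_rng(20260928)
        checked = 0
        while checked < 20:
            h = rng.uniform(10e-6, 150e-6)
            mu = float(np.exp(rng.uniform(np.log(1.2e-3), np.log(100e-3))))
            if alpha_of(h, mu) >= 0.1:
                continue
            fl = pm.FluidProperties(1006.0, mu)
            g = pm.GapGeometry(side_gap=h)
            ana = pm.wss_timeseries_analytic(g, fl, waveform)
            fd = pm.fd_gap_solver(g, fl, waveform)
            assert fd.peak_abs == pytest.approx(ana.peak_abs, rel=0.01)
            assert fd.cycle_avg_abs == pytest.approx(ana.cycle_avg_abs,
                                                     rel=0.01)
            checked += 1

    def test_zero_net_flux_constraint_holds_every_step(
            self, reference_gap, interstitial_50, waveform):
        residual = fd_flux_history(reference_gap, interstitial_50, waveform,
                                   n_points=101, steps_per_period=200)
        assert np.all(residual <= 1e-10)

    def test_matches_exact_solution_at_high_womersley_open_ends(
            self, waveform):
        # viscosity chosen so the gap Womersley number is 5
        h = 50e-6
        mu = h**2 * (2 * math.pi * 0.5) * 1006.0 / 25.0
        fl = pm.FluidProperties(1006.0, mu)
        g = pm.GapGeometry(side_gap=h, end_condition=pm.EndCondition.OPEN)
        assert alpha_of(h, mu) == pytest.approx(5.0, rel=1e-9)
        exact = pm.stokes_oscillating_wall_exact(g, fl, 15e-6, 0.5)
        fd = pm.fd_gap_solver(g, fl, waveform, n_points=301,
                              steps_per_period=800)
        assert fd.peak_abs == pytest.approx(exact, rel=0.01)

    def test_exact_solution_reduces_to_couette_at_low_womersley(self):
        g = pm.GapGeometry(side_gap=50e-6,
                           end_condition=pm.EndCondition.OPEN)
        fl = pm.FluidProperties(1006.0, 50e-3)  # alpha ~ 0.013
        exact = pm.stokes_oscillating_wall_exact(g, fl, 15e-6, 0.5)
        assert exact == pytest.approx(fl.dynamic_viscosity * PEAK_U / 50e-6,
                                      rel=1e-3)

    def test_grid_convergence_is_at_least_second_order(self, waveform):
        # moderate-alpha open flow so the profile has spatial structure
        h = 50e-6
        mu = h**2 * (2 * math.pi * 0.5) * 1006.0 / 25.0   # alpha = 5
        fl = pm.FluidProperties(1006.0, mu)
        g = pm.GapGeometry(side_gap=h, end_condition=pm.EndCondition.OPEN)
        exact = pm.stokes_oscillating_wall_exact(g, fl, 15e-6, 0.5)
        errors = []
        for n in (51, 101, 201):
            fd = pm.fd_gap_solver(g, fl, waveform, n_points=n,
                                  steps_per_period=2000, n_periods=6)
            errors.append(abs(fd.peak_abs - exact) / exact)
        order = np.polyfit(np.log([50, 100, 200]), np.log(errors), 1)[0]
        assert -order >= 1.8

    def test_zero_amplitude_like_drive_gives_zero_field(self,
                                                        interstitial_50):
        # amplitudes must be positive, so use a vanishingly small drive
        wf = pm.MicromotionWaveform.single(amplitude=1e-30)
        fd = pm.fd_gap_solver(pm.GapGeometry(side_gap=50e-6),
                              interstitial_50, wf)
        assert fd.peak_abs < 1e-20

    def test_resolution_preconditions_enforced(self, reference_gap,
                                               interstitial_50, waveform):
        with pytest.raises(pm.InvalidParameterError):
            pm.fd_gap_solver(reference_gap, interstitial_50, waveform,
                             n_points=21)
        with pytest.raises(pm.InvalidParameterError):
            pm.fd_gap_solver(reference_gap, interstitial_50, waveform,
                             steps_per_period=50)
        with pytest.raises(pm.InvalidParameterError):
            pm.fd_gap_solver(reference_gap, interstitial_50, waveform,
                             n_periods=2)


class TestTissuePropertiesInvariance:
    def test_flow_results_do_not_depend_on_tissue_constants(
            self, reference_gap, interstitial_50, waveform):
        # rigid-wall model: tissue elasticity is recorded, never consumed
        soft = pm.TissueProperties()
        stiff = dataclasses.replace(soft, youngs_modulus=6e9,
                                    poisson_ratio=0.2, density=2000.0)
        assert soft.youngs_modulus != stiff.youngs_modulus
        a = pm.wss_timeseries_analytic(reference_gap, interstitial_50,
                                       waveform)
        b = pm.wss_timeseries_analytic(reference_gap, interstitial_50,
                                       waveform)
        assert np.array_equal(a.tau_tissue, b.tau_tissue)
        assert a.peak_abs == b.peak_abs


class TestSqueezeFilm:
    def setup_method(self):
        self.fl = pm.FluidProperties(1006.0, 50e-3)
        self.wf = pm.MicromotionWaveform.single(15e-6, 0.5)

    def test_rim_stress_at_peak_approach_speed(self):
        # peak |gdot| occurs at t = 0 where the film is at its mean gap
        tau = pm.squeeze_film_wss(50e-6, 100e-6, self.wf, self.fl,
                                  r=50e-6, t=0.0)
        assert tau == pytest.approx(0.0353, rel=2e-3)

    def test_zero_on_axis_and_maximal_at_rim(self):
        r = np.linspace(0.0, 50e-6, 11)
        tau = pm.squeeze_film_wss(50e-6, 100e-6, self.wf, self.fl, r, 0.3)
        assert tau[0] == 0.0
        assert np.all(np.diff(tau) >= 0.0)

    def test_mass_conservation_of_radial_profile(self):
        # flux through the cylinder at radius r equals -gdot * pi r^2
        r, t, g0 = 30e-6, 0.37, 100e-6
        g = g0 + pm.displacement(self.wf, t)
        gdot = pm.velocity(self.wf, t)
        y = np.linspace(0.0, g, 4001)
        u = squeeze_film_radial_profile(g0, self.wf, self.fl, r, t, y)
        flux = 2.0 * math.pi * r * np.trapezoid(u, y)
        assert flux == pytest.approx(-gdot * math.pi * r**2, rel=1e-6)

    def test_contact_refused(self):
        close = pm.MicromotionWaveform.single(120e-6, 0.5)
        with pytest.raises(pm.ContactSingularityError):
            pm.squeeze_film_wss(50e-6, 100e-6, close, self.fl, 50e-6, 0.0)
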