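"""Dose conversion and heat-source tests."""

import numpy as np
import pytest
from scipy.integrate import quad

from scartherm import (
    DoseParams,
    GridSpec,
    SourceOptions,
    build_domain,
    deposited_energy_check,
    dose_to_energy_power,
    heat_source,
    material_for,
    peak_flux,
)
from scartherm.laser import HeatSourceField, envelope, envelope_integral

LITERAL = SourceOptions(envelope="gaussian-literal")


class TestDoseConversion:
    def test_reference_dose_energy_and_power(self):
        s, W, P = dose_to_energy_power(7.5, 4e-3, 7.0)
        assert s == pytest.approx(0.38485, rel=1e-4)
        assert W == pytest.approx(2.886, rel=1e-3)
        assert P == pytest.approx(721.6, rel=1e-3)

    def test_high_dose_pulse_energy(self):
        _, W, _ = dose_to_energy_power(10.0, 4e-3, 7.0)
        assert W == pytest.approx(3.849, rel=1e-3)

    def test_zero_energy_density_limit(self):
        _, W, P = dose_to_energy_power(0.0, 4e-3, 7.0)
        assert W == 0.0 and P == 0.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            dose_to_energy_power(7.5, -1e-3, 7.0)
        with pytest.raises(ValueError):
            DoseParams(7.5, 4.0, 0.0)

    def test_peak_flux_of_reference_dose(self):
        assert peak_flux(721.6, 7.0) == pytest.approx(3750, rel=1e-3)

    def test_peak_flux_zero_and_linearity(self):
        assert peak_flux(0.0, 5.0) == 0.0
        assert peak_flux(200.0, 5.0) == pytest.approx(2 * peak_flux(100.0, 5.0))

    def test_flux_is_independent_of_spot_at_fixed_fluence(self):
        # Phi0 = 2P/(pi w^2) with W = q*s collapses to 2q/tau
        for spot in (5.0, 6.0, 7.0):
            assert DoseParams(7.5, 4.0, spot).Phi0 == pytest.approx(2 * 7.5 / 4e-3)


class TestHeatSource:
    def test_surface_axis_peak_matches_hand_calculation(self):
        # all spatial/temporal factors equal 1 at r=0, z=0, t=tau for the
        # literal envelope: Q = mu_a (1-R) Phi0 = 1.672e4 W/cm^3
        mat = material_for("hps")
        dose = DoseParams(7.5, 4.0, 7.0)
        q = heat_source(dose, mat, 0.0, 0.0, dose.tau_s, LITERAL)
        assert q == pytest.approx(5.574 * 0.8 * 3750 * 1e6, rel=1e-3)
        assert q / 1e6 == pytest.approx(1.672e4, rel=1e-3)

    def test_temporal_decay_to_zero(self):
        mat = material_for("hps")
        dose = DoseParams(7.5, 4.0, 7.0)
        assert heat_source(dose, mat, 0.0, 0.0, 1.0) < 1e-12

    def test_separability_radial_profile_independent_of_depth_and_time(self):
        mat = material_for("hps")
        dose = DoseParams(7.5, 4.0, 7.0)
        r = np.linspace(0, 3e-3, 7)
        profiles = [
            heat_source(dose, mat, r, z, t) / heat_source(dose, mat, 0.0, z, t)
            for z in (0.0, 1e-4, 5e-4)
            for t in (2e-3, 4e-3)
        ]
        for p in profiles[1:]:
            np.testing.assert_allclose(p, profiles[0], rtol=1e-12)

    def test_monotone_decay_in_r_and_z(self):
        mat = material_for("hps")
        dose = DoseParams(7.5, 4.0, 7.0)
        r = np.linspace(0, 5e-3, 20)
        z = np.linspace(0, 2e-3, 20)
        assert (np.diff(heat_source(dose, mat, r, 0.0, 4e-3)) < 0).all()
        assert (np.diff(heat_source(dose, mat, 0.0, z, 4e-3)) < 0).all()

    def test_linearity_in_energy_density(self):
        mat = material_for("hps")
        q1 = heat_source(DoseParams(4.0, 4.0, 7.0), mat, 1e-3, 1e-4, 3e-3)
        q2 = heat_source(DoseParams(8.0, 4.0, 7.0), mat, 1e-3, 1e-4, 3e-3)
        assert q2 == pytest.approx(2 * q1, rel=1e-12)

    @pytest.mark.parametrize("env", ["gaussian-normalized", "gaussian-literal", "tophat"])
    def test_envelope_integral_matches_quadrature(self, env):
        dose = DoseParams(7.5, 4.0, 7.0)
        opts = SourceOptions(envelope=env)
        ref, _ = quad(lambda t: envelope(t, dose, opts), 0.0, 2e-3, limit=200)
        assert envelope_integral(0.0, 2e-3, dose, opts) == pytest.approx(ref, rel=1e-9)

    def test_normalized_envelope_delivers_the_pulse_duration(self):
        # integral of the default envelope over the pulse window equals tau,
        # so Phi0 * integral reproduces the prescribed fluence exactly
        dose = DoseParams(7.5, 4.0, 7.0)
        opts = SourceOptions()
        val = envelope_integral(-np.inf, np.inf, dose, opts)
        assert val == pytest.approx(dose.tau_s, rel=1e-12)


class TestEnergyBookkeeping:
    def test_zero_dose_deposits_nothing(self):
        _, grid = build_domain("hps", GridSpec(dr_mm=0.5, dz_mm=0.2))
        report = deposited_energy_check(DoseParams(1e-12, 4.0, 7.0), grid)
        assert report["absorbed_J"] == pytest.approx(0.0, abs=1e-9)

    def test_absorption_cannot_exceed_transmitted_energy(self, coarse_grid):
        _, grid = build_domain("hps", coarse_grid)
        dose = DoseParams(10.0, 4.0, 7.0)
        for opts in (SourceOptions(), LITERAL):
            rep = deposited_energy_check(dose, grid, opts)
            envelope_factor = 1.0 if opts.envelope == "gaussian-normalized" else np.sqrt(np.pi) / 2
            assert 0 < rep["absorbed_J"] <= rep["incident_after_reflection_J"] * envelope_factor

    def test_matches_independent_quadrature_oracle(self):
        # brute-force tensor quadrature of the point source over r, z, t
        _, grid = build_domain("hps", GridSpec(dr_mm=0.2, dz_mm=0.1))
        dose = DoseParams(7.5, 4.0, 7.0)
        mat = grid.tissue
        radial, _ = quad(lambda r: 2 * np.pi * r * heat_source(dose, mat, r, 0.0, dose.tau_s),
                         0.0, 10e-3, limit=200)
        axial, _ = quad(lambda z: heat_source(dose, mat, 0.0, z, dose.tau_s), 0.0, 4e-3,
                        points=[1e-4, 5e-4], limit=200)
        temporal, _ = quad(lambda t: envelope(t, dose, SourceOptions()), 0.0, 2.5 * dose.tau_s,
                           limit=200)
        # the source is separable, so total = amp * (int G)(int X)(int E);
        # the three quadratures each carry one extra factor amp * E(tau)
        peak = heat_source(dose, mat, 0.0, 0.0, dose.tau_s)
        envelope_at_tau = envelope(dose.tau_s, dose, SourceOptions())
        oracle = radial * axial * temporal / (peak * envelope_at_tau)
        report = deposited_energy_check(dose, grid)
        assert report["absorbed_J"] == pytest.approx(oracle, rel=0.01)
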