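"""Metrology chain: calibration, hydrostatic correction, contact, modulus."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dipchar import mechtest as mt
from dipchar import photosim as ps
from dipchar.errors import (
    DegenerateFitError,
    DomainError,
    DoubleCorrectionError,
    InsufficientDataError,
    NoContactError,
)

from conftest import ols_oracle

G = mt.G_STANDARD


def make_trace(z, force, corrected=False):
    return mt.ForceTrace(
        time=np.arange(len(z), dtype=float), z=np.asarray(z, float),
        force=np.asarray(force, float), corrected=corrected,
    )


class TestCalibration:
    def test_identity_mapping(self):
        curve = mt.calibrate_load_cell([(0, 0), (100, 100)])
        assert curve.scale_alpha == pytest.approx(1.0)
        assert curve.offset_beta == pytest.approx(0.0)

    def test_recovers_generating_parameters_noiseless(self):
        # counts generated from mass = alpha * (D - beta)
        alpha, beta = 0.005, -12.0
        masses = np.linspace(1, 100, 10)
        counts = masses / alpha + beta
        curve = mt.calibrate_load_cell(list(zip(masses, counts)))
        assert curve.scale_alpha == pytest.approx(alpha, rel=1e-9)
        assert curve.offset_beta == pytest.approx(beta, rel=1e-9)

    def test_held_out_mass_within_linearity_spec(self):
        alpha, beta = 0.005, -12.0
        masses = np.linspace(1, 100, 10)
        counts = masses / alpha + beta
        curve = mt.calibrate_load_cell(list(zip(masses, counts)))
        held_mass = 55.0
        held_counts = held_mass / alpha + beta
        assert curve.validate(held_mass, held_counts, tol_frac=5e-4)
        # a grossly wrong reading fails validation
        assert not curve.validate(held_mass, held_counts + 500, tol_frac=5e-4)

    def test_residuals_available_per_point(self):
        curve = mt.calibrate_load_cell([(0, 10), (50, 5010), (100, 10010)])
        assert curve.residuals.shape == (3,)

    @given(
        alpha=st.floats(1e-4, 1.0),
        beta=st.floats(-100, 100),
        noise=st.floats(0, 0.5),
        seed=st.integers(0, 1000),
    )
    def test_matches_closed_form_ols(self, alpha, beta, noise, seed):
        rng = np.random.default_rng(seed)
        masses = np.linspace(0, 100, 8) + rng.normal(0, noise, 8)
        masses = np.abs(masses)
        counts = masses / alpha + beta + rng.normal(0, noise, 8)
        if np.ptp(counts) < 1e-6:
            return
        curve = mt.calibrate_load_cell(list(zip(masses, counts)))
        slope, intercept = ols_oracle(counts, masses)
        assert curve.scale_alpha == pytest.approx(slope, rel=1e-9)
        assert curve.offset_beta == pytest.approx(-intercept / slope, rel=1e-6, abs=1e-9)

    def test_degenerate_and_insufficient(self):
        with pytest.raises(DegenerateFitError):
            mt.calibrate_load_cell([(0, 5), (10, 5), (20, 5)])
        with pytest.raises(InsufficientDataError):
            mt.calibrate_load_cell([(0, 0)])
        with pytest.raises(DomainError):
            mt.calibrate_load_cell([(-1, 0), (10, 100)])


class TestHydrostatic:
    def test_null_fluid(self):
        trace = make_trace(np.linspace(0, 0.01, 20), np.zeros(20))
        model = mt.fit_hydrostatic(trace, wetted_area_Ap=1e-4)
        assert model.beta0 == pytest.approx(0.0)
        assert model.beta1 == pytest.approx(0.0)
        assert model.density_rho == pytest.approx(0.0)

    def test_recovers_rho_g_Ap_noiseless(self):
        rho, ap = 1000.0, 1e-4
        z = np.linspace(0.01, 0.02, 50)
        trace = make_trace(z, 0.03 + rho * 9.81 * ap * z)
        model = mt.fit_hydrostatic(trace, ap, g_const=9.81)
        assert model.beta1 == pytest.approx(rho * 9.81 * ap, rel=1e-9)
        assert model.density_rho == pytest.approx(rho, rel=1e-9)

    @given(seed=st.integers(0, 500))
    def test_matches_closed_form_ols(self, seed):
        rng = np.random.default_rng(seed)
        z = np.sort(rng.uniform(0, 0.04, 30))
        if np.ptp(z) == 0:
            return
        f = rng.normal(0, 0.01, 30)
        model = mt.fit_hydrostatic(make_trace(z, f), 1e-4)
        slope, intercept = ols_oracle(z, f)
        assert model.beta1 == pytest.approx(slope, rel=1e-9, abs=1e-12)
        assert model.beta0 == pytest.approx(intercept, rel=1e-9, abs=1e-12)

    def test_errors(self):
        flat = make_trace(np.full(10, 0.01), np.zeros(10))
        with pytest.raises(DegenerateFitError):
            mt.fit_hydrostatic(flat, 1e-4)
        good = make_trace(np.linspace(0, 0.01, 10), np.zeros(10))
        with pytest.raises(DomainError):
            mt.fit_hydrostatic(good, -1e-4)


class TestSubtraction:
    def test_zero_model_is_identity(self):
        trace = make_trace(np.linspace(0, 0.01, 10), np.linspace(0, 1, 10))
        model = mt.HydrostaticModel(0.0, 0.0, 1e-4)
        out = mt.subtract_hydrostatic(trace, model)
        assert np.array_equal(out.force, trace.force)
        assert out.corrected

    def test_additive_construction_recovered_exactly(self):
        z = np.linspace(0.03, 0.01, 80)
        structural = np.where(z < 0.02, (0.02 - z) * 50.0, 0.0)
        b0, b1 = 0.07, 0.98
        trace = make_trace(z[::-1], (structural + b0 + b1 * z)[::-1])
        out = mt.subtract_hydrostatic(trace, mt.HydrostaticModel(b0, b1, 1e-4))
        assert np.allclose(out.force, structural[::-1], atol=1e-15)

    def test_double_correction_rejected(self):
        trace = make_trace([0.0, 0.01], [0.0, 0.0], corrected=True)
        with pytest.raises(DoubleCorrectionError):
            mt.subtract_hydrostatic(trace, mt.HydrostaticModel(0, 0, 1e-4))

    def test_refit_on_corrected_no_contact_trace_is_flat(self, rng):
        z = np.linspace(0.01, 0.03, 200)
        model = mt.HydrostaticModel(0.05, 0.98, 1e-4)
        trace = make_trace(z, model.predict(z) + rng.normal(0, 1e-5, z.size))
        out = mt.subtract_hydrostatic(trace, model)
        refit = mt.fit_hydrostatic(out, 1e-4)
        assert abs(refit.beta1) < 5e-4  # slope consistent with zero at this noise


class TestContactDetection:
    def test_step_trace(self):
        f = np.concatenate([np.zeros(50), np.full(30, 0.1)])
        trace = make_trace(np.linspace(0.03, 0.01, 80), f, corrected=True)
        idx, z_c = mt.detect_contact(trace, noise_sd=0.001)
        assert idx == 50
        assert z_c == pytest.approx(trace.z[50])

    def test_matches_brute_force_scan(self, rng):
        z = np.linspace(0.03, 0.01, 300)
        ramp = np.maximum(0.0, 0.02 - z) * 40.0
        f = ramp + rng.normal(0, 1e-3, z.size)
        trace = make_trace(z, f, corrected=True)
        k_sigma, m = 5.0, 5
        idx, _ = mt.detect_contact(trace, noise_sd=1e-3, k_sigma=k_sigma, m_sustain=m)

        # exhaustive scan of the same sustained-threshold rule
        above = np.abs(f) > k_sigma * 1e-3
        expected = next(
            i for i in range(len(f) - m + 1) if all(above[i : i + m])
        )
        assert idx == expected

    def test_all_zero_raises_no_contact(self):
        trace = make_trace(np.linspace(0.03, 0.01, 40), np.zeros(40), corrected=True)
        with pytest.raises(NoContactError):
            mt.detect_contact(trace, noise_sd=1e-3)

    def test_uncorrected_trace_rejected(self):
        trace = make_trace([0.0, 0.01], [0.0, 1.0])
        with pytest.raises(DomainError):
            mt.detect_contact(trace, noise_sd=1e-3)


class TestStressStrain:
    def test_zero_force_gives_zero_stress(self):
        z = np.linspace(0.02, 0.015, 20)
        trace = make_trace(z, np.zeros(20), corrected=True)
        curve = mt.stress_strain(trace, 0.01, 0.005, z_contact=0.02)
        assert np.all(curve.stress == 0)

    def test_footprint_area_analytic(self):
        z = np.linspace(0.02, 0.015, 5)
        trace = make_trace(z, np.zeros(5), corrected=True)
        curve = mt.stress_strain(trace, diameter_D=0.010, initial_height_H0=0.005,
                                 z_contact=0.02)
        assert curve.footprint_area_A0 == pytest.approx(np.pi * 0.005**2, rel=1e-12)

    def test_full_compression_strain_one(self):
        h0 = 0.005
        z = np.array([0.02, 0.02 - h0])
        trace = make_trace(z, np.zeros(2), corrected=True)
        curve = mt.stress_strain(trace, 0.01, h0, z_contact=0.02)
        assert curve.strain[-1] == pytest.approx(1.0)

    def test_domain_errors(self):
        trace = make_trace([0.02, 0.015], [0.0, 0.0], corrected=True)
        with pytest.raises(DomainError):
            mt.stress_strain(trace, -0.01, 0.005, 0.02)
        with pytest.raises(DomainError):
            mt.stress_strain(trace, 0.01, 0.0, 0.02)


class TestEffectiveModulus:
    def test_exact_linear_curve(self):
        eps = np.linspace(0, 0.2, 100)
        curve = mt.StressStrainCurve(eps, 25e3 * eps, np.pi * 25e-6, 0.01, 0.005)
        est = mt.effective_modulus(curve)
        assert est.E_eff == pytest.approx(25e3, rel=1e-12)
        assert est.strain_window_L == (0.05, 0.10)

    def test_biphasic_curve_matches_pairwise_slope_oracle(self):
        # compliant toe then strain-stiffening: sigma = a*eps + b*eps^3
        a, b = 10e3, 4e6
        eps = np.linspace(0, 0.15, 301)
        sigma = a * eps + b * eps**3
        est = mt.effective_modulus(mt.StressStrainCurve(eps, sigma, 1.0, 0.01, 0.005))

        # independent brute-force oracle: the window slope as the mean of all
        # pairwise difference quotients weighted by their squared strain span
        w = (eps >= 0.05) & (eps <= 0.10)
        e, s = eps[w], sigma[w]
        num = den = 0.0
        for i in range(len(e)):
            for j in range(i + 1, len(e)):
                de = e[j] - e[i]
                num += de * (s[j] - s[i])
                den += de * de
        assert est.E_eff == pytest.approx(num / den, rel=1e-3)

    def test_insufficient_points_in_window(self):
        eps = np.array([0.0, 0.2])
        curve = mt.StressStrainCurve(eps, eps * 1e3, 1.0, 0.01, 0.005)
        with pytest.raises(InsufficientDataError):
            mt.effective_modulus(curve)


class TestEndToEnd:
    def test_modulus_invariant_to_affine_offset(self, rng):
        """Adding any affine-in-z term and subtracting the matching model
        leaves E_eff unchanged."""
        spec = ps.VirtualSpecimen(E_true=20e3)
        comp = ps.simulate_compression(spec, np.linspace(0, 0.15, 150), rng=rng)
        base_corr = mt.subtract_hydrostatic(comp, spec.hydro)
        _, z_c = mt.detect_contact(base_corr)
        base = mt.effective_modulus(
            mt.stress_strain(base_corr, spec.diameter_D, spec.height_H0, z_c)
        )

        extra = mt.HydrostaticModel(0.3, 17.0, 1e-4)
        shifted = mt.ForceTrace(comp.time, comp.z, comp.force + extra.predict(comp.z))
        combined = mt.HydrostaticModel(
            spec.hydro.beta0 + 0.3, spec.hydro.beta1 + 17.0, 1e-4
        )
        corr = mt.subtract_hydrostatic(shifted, combined)
        _, z_c2 = mt.detect_contact(corr)
        est = mt.effective_modulus(
            mt.stress_strain(corr, spec.diameter_D, spec.height_H0, z_c2)
        )
        assert est.E_eff == pytest.approx(base.E_eff, rel=1e-9)

    def test_noiseless_round_trip_recovers_E_true(self, rng):
        spec = ps.VirtualSpecimen(E_true=25e3)
        sweep = ps.simulate_density_sweep(spec, (0.025, 0.035), rng=rng)
        comp = ps.simulate_compression(spec, np.linspace(0, 0.15, 150), rng=rng)
        est, hydro, _ = mt.run_characterisation(
            sweep, comp, 1e-4, spec.diameter_D, spec.height_H0
        )
        assert est.E_eff == pytest.approx(25e3, rel=1e-6)
        assert hydro.density_rho == pytest.approx(1000.0, rel=1e-6)
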