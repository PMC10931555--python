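"""Generator contracts: closed forms, instrument effects, determinism."""

import numpy as np
import pytest
from scipy.integrate import quad

from bilayerlab.synthetic import (EndothermParams, FluorescenceParams,
                                  LamellarModelParams, SansModelParams,
                                  core_shell_vesicle_intensity,
                                  endotherm_peak_shape, gen_fluorescence,
                                  gen_sans_curve, gen_saxs_waxs_pattern,
                                  gen_thermogram, guinier_sheet_intensity,
                                  lamellar_pattern_model,
                                  smear_wavelength_spread,
                                  uniform_slab_intensity)


class TestSansGenerator:
    def test_guinier_point_value(self, clean_sans_params):
        # thickness sqrt(12) nm gives Rg = 1 nm, so I(1) = exp(-1)
        params = clean_sans_params(thickness=np.sqrt(12.0),
                                   q_grid=np.array([0.5, 1.0, 2.0]))
        curve = gen_sans_curve(params)
        assert curve.I[1] == pytest.approx(np.exp(-1.0), rel=1e-12)

    @pytest.mark.parametrize("kind,model", [
        ("guinier_sheet",
         lambda q, p: guinier_sheet_intensity(q, p.thickness_true,
                                              p.scale_C)),
        ("uniform_slab",
         lambda q, p: uniform_slab_intensity(q, p.thickness_true, p.scale_C)),
        ("core_shell_vesicle",
         lambda q, p: core_shell_vesicle_intensity(
             q, p.thickness_true, p.vesicle_radius, p.scale_C)),
    ])
    def test_noise_free_equals_closed_form(self, clean_sans_params, kind,
                                           model):
        params = clean_sans_params(thickness=4.0, model_kind=kind,
                                   background_B=0.07)
        curve = gen_sans_curve(params)
        expected = model(params.q_grid, params) + 0.07
        np.testing.assert_allclose(curve.I, expected, rtol=1e-13)

    def test_slab_matches_numerical_fourier_oracle(self):
        # independent oracle: numerical Fourier transform of the slab
        # thickness profile rho(z) = 1 on [-L/2, L/2]
        L = 4.0
        q_vals = np.linspace(0.31, 1.14, 9)
        oracle = []
        for q in q_vals:
            re, _ = quad(lambda z: np.cos(q * z), -L / 2, L / 2)
            oracle.append(re ** 2 / (L ** 2 * q ** 2))
        model = uniform_slab_intensity(q_vals, L, scale_C=1.0)
        np.testing.assert_allclose(model, oracle, rtol=1e-3)

    def test_kratky_porod_exact_linearity(self, clean_sans_params):
        # noise-free sheets: ln(I q^2) is exactly linear in q^2,
        # slope -Rg^2
        params = clean_sans_params(thickness=3.88)
        curve = gen_sans_curve(params)
        y = np.log(curve.I * curve.q ** 2)
        x = curve.q ** 2
        coeffs = np.polyfit(x, y, 1)
        assert coeffs[0] == pytest.approx(-(3.88 ** 2) / 12.0, rel=1e-12)
        resid = y - np.polyval(coeffs, x)
        assert np.max(np.abs(resid)) < 1e-10

    def test_smearing_zero_spread_is_identity(self):
        q = np.linspace(0.05, 5.0, 100)
        model = lambda qq: guinier_sheet_intensity(qq, 3.88)
        np.testing.assert_array_equal(
            smear_wavelength_spread(model, q, 0.0), model(q))

    def test_smearing_broadens_curve(self, clean_sans_params):
        sharp = gen_sans_curve(clean_sans_params())
        smeared = gen_sans_curve(clean_sans_params(wavelength_spread=0.10))
        assert not np.allclose(sharp.I, smeared.I)
        # smearing conserves the low-q intensity scale to first order
        assert smeared.I[0] == pytest.approx(sharp.I[0], rel=0.02)

    def test_rejects_invalid_params(self):
        with pytest.raises(ValueError):
            SansModelParams(q_grid=np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            SansModelParams(thickness_true=-1.0)
        with pytest.raises(ValueError):
            SansModelParams(scale_C=0.0)
        with pytest.raises(ValueError):
            SansModelParams(model_kind="nope")

    def test_noise_sigma_scales_with_sqrt_intensity(self, clean_sans_params):
        params = clean_sans_params(noise_level=0.02, background_B=0.05)
        curve = gen_sans_curve(params)
        model = (guinier_sheet_intensity(curve.q, 3.88) + 0.05)
        np.testing.assert_allclose(curve.sigma, 0.02 * np.sqrt(model),
                                   rtol=1e-12)


class TestLamellarGenerator:
    def test_peak_centers_forced_by_repeat_distance(self,
                                                    clean_lamellar_params):
        curve = gen_saxs_waxs_pattern(clean_lamellar_params(d=7.8))
        for n, expected in ((1, 0.8055), (2, 1.6111)):
            center = 2 * np.pi * n / 7.8
            assert center == pytest.approx(expected, abs=5e-5)
            # noise-free local maximum within one grid step of the center
            near = (curve.q > center - 0.1) & (curve.q < center + 0.1)
            q_near = curve.q[near]
            assert abs(q_near[np.argmax(curve.I[near])] - center) <= 0.011

    def test_waxs_single_local_maximum_without_crystals(
            self, clean_lamellar_params):
        curve = gen_saxs_waxs_pattern(clean_lamellar_params())
        m = (curve.q >= 10.0) & (curve.q <= 18.0)
        I = curve.I[m]
        interior_maxima = np.flatnonzero(
            (I[1:-1] > I[:-2]) & (I[1:-1] > I[2:]))
        assert len(interior_maxima) == 1

    def test_rejects_duplicate_crystalline_centers(self):
        with pytest.raises(ValueError):
            LamellarModelParams(
                crystalline_peaks=[(14.0, 0.05, 1.0), (14.0, 0.05, 2.0)])

    def test_rejects_nonpositive_widths(self):
        with pytest.raises(ValueError):
            LamellarModelParams(peak_widths=(0.0, 0.05))

    def test_crystalline_peaks_visible_in_residual(self,
                                                   clean_lamellar_params):
        centers = [13.1, 14.8, 14.9, 16.2]
        params = clean_lamellar_params(
            crystalline_peaks=[(c, 0.05, 0.2) for c in centers])
        with_peaks = gen_saxs_waxs_pattern(params)
        base = lamellar_pattern_model(clean_lamellar_params(),
                                      with_peaks.q)
        resid = with_peaks.I - base
        for c in centers:
            near = (with_peaks.q > c - 0.025) & (with_peaks.q < c + 0.025)
            assert resid[near].max() > 0.1


class TestEndothermGenerator:
    def test_symmetric_case_has_gaussian_core(self, wide_T_grid,
                                              clean_endotherm_params):
        # at zero asymmetry the peak inside its half-max region is an exact
        # Gaussian of sigma = FWHM/2.3548 (the completion taper only acts
        # outside it and rescales the height uniformly)
        params = clean_endotherm_params(asymmetry=0.0,
                                        baseline_intercept=0.0,
                                        baseline_slope=0.0,
                                        T_grid=wide_T_grid)
        tg = gen_thermogram(params)
        sigma = 12.5 / (2 * np.sqrt(2 * np.log(2)))
        gauss = np.exp(-0.5 * ((wide_T_grid - 28.1) / sigma) ** 2)
        core = np.abs(wide_T_grid - 28.1) < 6.0  # inside half-max points
        shape = tg.cp_excess / tg.cp_excess.max()
        np.testing.assert_allclose(shape[core], gauss[core], rtol=1e-6)
        # and it is symmetric about Tm
        left = tg.cp_excess[np.searchsorted(wide_T_grid, 28.1 - 5.0)]
        right = tg.cp_excess[np.searchsorted(wide_T_grid, 28.1 + 5.0)]
        assert left == pytest.approx(right, rel=1e-9)

    @pytest.mark.parametrize("asym", [-2.0, -1.0, 0.0, 1.0, 2.0])
    def test_area_exact_for_any_asymmetry(self, wide_T_grid, asym,
                                          clean_endotherm_params):
        params = clean_endotherm_params(asymmetry=asym,
                                        baseline_intercept=0.0,
                                        baseline_slope=0.0,
                                        T_grid=wide_T_grid)
        tg = gen_thermogram(params)
        area = np.trapezoid(tg.cp_excess, tg.T)
        assert area == pytest.approx(18.0, rel=5e-3)

    @pytest.mark.parametrize("asym", [-3.0, 1.5])
    def test_mode_and_fwhm_by_brute_force_scan(self, asym,
                                               clean_endotherm_params):
        # dense evaluation of the noise-free shape: numerical mode and
        # half-height width must equal the requested Tm and FWHM
        T = np.linspace(0.0, 60.0, 60001)
        peak = endotherm_peak_shape(T, 28.1, 12.5, asym)
        i = np.argmax(peak)
        assert T[i] == pytest.approx(28.1, abs=2e-3)
        half = peak[i] / 2
        left = T[:i][np.argmin(np.abs(peak[:i] - half))]
        right = T[i:][np.argmin(np.abs(peak[i:] - half))]
        assert right - left == pytest.approx(12.5, abs=5e-3)

    def test_tiny_enthalpy_conserved(self, wide_T_grid,
                                     clean_endotherm_params):
        params = clean_endotherm_params(dH_true=1e-6,
                                        baseline_intercept=0.0,
                                        baseline_slope=0.0,
                                        T_grid=wide_T_grid)
        tg = gen_thermogram(params)
        assert np.trapezoid(tg.cp_excess, tg.T) == pytest.approx(1e-6,
                                                                 rel=1e-3)
        with pytest.raises(ValueError):
            clean_endotherm_params(dH_true=0.0)

    def test_truncating_grid_rejected(self, clean_endotherm_params):
        with pytest.raises(ValueError, match="truncates"):
            gen_thermogram(clean_endotherm_params(
                T_grid=np.arange(25.0, 40.0, 0.05)))


class TestFluorescenceGenerator:
    def test_equal_traces_at_unit_ratio(self, clean_fluor_params):
        _, mono, exc = gen_fluorescence(clean_fluor_params(eta=1.0))
        np.testing.assert_array_equal(mono.I, exc.I)
        assert np.ptp(mono.I) == 0.0

    def test_trace_means_in_requested_ratio(self, clean_fluor_params):
        _, mono, exc = gen_fluorescence(clean_fluor_params(eta=1.13))
        assert exc.I.mean() / mono.I.mean() == pytest.approx(1.13,
                                                             rel=1e-12)

    def test_spectrum_band_ratio_equals_eta(self, clean_fluor_params):
        spec, _, _ = gen_fluorescence(clean_fluor_params(eta=1.13))
        i376 = spec.I[spec.wavelength == 376.0][0]
        i480 = spec.I[spec.wavelength == 480.0][0]
        assert i480 / i376 == pytest.approx(1.13, rel=1e-9)

    def test_ratio_unbiased_over_many_seeds(self, clean_fluor_params):
        # Monte-Carlo: sample mean of the recovered ratio within 3 SEM
        etas = []
        for seed in range(300):
            _, mono, exc = gen_fluorescence(clean_fluor_params(
                eta=1.13, noise_level=0.02, seed=seed))
            etas.append(exc.I.mean() / mono.I.mean())
        etas = np.asarray(etas)
        sem = etas.std(ddof=1) / np.sqrt(len(etas))
        assert abs(etas.mean() - 1.13) < 3 * sem

    def test_rejects_nonpositive_eta(self):
        with pytest.raises(ValueError):
            FluorescenceParams(eta_true=0.0)


class TestDeterminism:
    def test_equal_seeds_bit_identical(self, clean_sans_params,
                                       clean_lamellar_params,
                                       clean_endotherm_params,
                                       clean_fluor_params):
        for gen, params in (
                (gen_sans_curve, clean_sans_params(noise_level=0.02)),
                (gen_saxs_waxs_pattern,
                 clean_lamellar_params(noise_level=0.03)),
                (gen_thermogram, clean_endotherm_params(noise_level=0.01))):
            a, b = gen(params), gen(params)
            np.testing.assert_array_equal(a.I if hasattr(a, "I")
                                          else a.cp_excess,
                                          b.I if hasattr(b, "I")
                                          else b.cp_excess)
        _, m1, e1 = gen_fluorescence(clean_fluor_params(noise_level=0.02))
        _, m2, e2 = gen_fluorescence(clean_fluor_params(noise_level=0.02))
        np.testing.assert_array_equal(m1.I, m2.I)
        np.testing.assert_array_equal(e1.I, e2.I)

    def test_different_seeds_differ(self, clean_sans_params):
        a = gen_sans_curve(clean_sans_params(noise_level=0.02, seed=1))
        b = gen_sans_curve(clean_sans_params(noise_level=0.02, seed=2))
        assert not np.array_equal(a.I, b.I)
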