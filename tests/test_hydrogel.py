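"""Mesh size, Stokes–Einstein, FRAP fitting and amide-I deconvolution."""

import numpy as np
import pytest

from elphase import hydrogel as hg
from elphase.constants import BOLTZMANN_J_PER_K
from elphase.synthetic import gen_frap_trace, gen_ftir_spectrum


class TestMeshSize:
    @pytest.mark.parametrize(
        "g_prime, xi_nm", [(47440.0, 4.5), (20000.0, 6.0), (38690.0, 4.8)]
    )
    def test_printed_moduli_reproduce_mesh_sizes(self, g_prime, xi_nm):
        assert round(hg.mesh_size_from_modulus(g_prime).xi_nm, 1) == xi_nm

    def test_cube_relation_exact(self):
        est = hg.mesh_size_from_modulus(1300.0, 310.0)
        assert est.xi_m**3 * est.g_prime_pa == pytest.approx(
            BOLTZMANN_J_PER_K * 310.0, rel=1e-9
        )

    def test_doubling_modulus_shrinks_by_cube_root_two(self):
        a = hg.mesh_size_from_modulus(10000.0).xi_nm
        b = hg.mesh_size_from_modulus(20000.0).xi_nm
        assert a / b == pytest.approx(2 ** (1 / 3))

    def test_nonpositive_modulus_rejected(self):
        with pytest.raises(ValueError):
            hg.mesh_size_from_modulus(0.0)


class TestStokesEinstein:
    @pytest.mark.parametrize("r_nm, d0", [(4.5, 73.0), (8.5, 38.6)])
    def test_dextran_probes(self, r_nm, d0):
        assert round(hg.stokes_einstein_d0(r_nm * 1e-9), 1) == d0

    def test_doubling_radius_halves_d0(self):
        assert hg.stokes_einstein_d0(2e-9) == pytest.approx(
            2 * hg.stokes_einstein_d0(4e-9)
        )

    def test_inverse_relation_recovers_thermal_energy(self):
        r, eta, t = 3e-9, 1e-3, 300.0
        d0 = hg.stokes_einstein_d0(r, eta, t) * 1e-12
        assert d0 * 6 * np.pi * eta * r == pytest.approx(
            BOLTZMANN_J_PER_K * t, rel=1e-12
        )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            hg.stokes_einstein_d0(-1e-9)


class TestNormalizeFrap:
    def _step_series(self, n_pre=10, n_post=40):
        times = np.arange(n_pre + n_post, dtype=float)
        roi = np.concatenate([np.full(n_pre, 200.0), np.full(n_post, 80.0)])
        whole = np.full(n_pre + n_post, 1000.0)
        return roi, whole, times

    def test_step_input_maps_to_unit_interval(self):
        roi, whole, times = self._step_series()
        trace = hg.normalize_frap(roi, whole, times)
        assert np.allclose(trace.intensity, 0.0)
        assert trace.times_s[0] == 0.0

    def test_prebleach_mean_is_one(self):
        roi, whole, times = self._step_series()
        roi[10:] = np.linspace(80, 150, 40)
        trace = hg.normalize_frap(roi, whole, times)
        corrected = (roi / whole - roi[10] / whole[10]) / (
            (roi[:10] / whole[:10]).mean() - roi[10] / whole[10]
        )
        assert np.allclose(trace.intensity, corrected[10:])

    def test_whole_field_trend_removed(self):
        times = np.arange(50, dtype=float)
        drift = 1.0 - 0.1 * times / 49.0  # 10 % linear decay
        roi = 100.0 * drift
        roi[10:] = 40.0 * drift[10:]
        trace = hg.normalize_frap(roi, 1000.0 * drift, times)
        assert np.allclose(trace.intensity, 0.0, atol=1e-12)

    def test_zero_whole_field_rejected(self):
        roi, whole, times = self._step_series()
        whole[5] = 0.0
        with pytest.raises(ValueError, match="zero"):
            hg.normalize_frap(roi, whole, times)


class TestFitFrap:
    def test_noiseless_exact_recovery(self):
        trace = gen_frap_trace(plateau=0.8, rate_per_s=0.115, sigma_noise=0.0)
        fit = hg.fit_frap(trace)
        assert fit.plateau == pytest.approx(0.8, abs=1e-6)
        assert fit.rate_per_s == pytest.approx(0.115, abs=1e-6)

    def test_parameter_recovery_under_noise(self):
        errs_a, errs_k = [], []
        for seed in range(50):
            trace = gen_frap_trace(0.8, 0.115, sigma_noise=0.01,
                                   n_points=200, t_max_s=100.0, seed=seed)
            fit = hg.fit_frap(trace)
            errs_a.append(fit.plateau / 0.8 - 1.0)
            errs_k.append(fit.rate_per_s / 0.115 - 1.0)
        assert np.max(np.abs(errs_a)) < 0.05
        assert np.max(np.abs(errs_k)) < 0.05
        # estimator bias stays well below the per-fit scatter
        assert abs(np.mean(errs_a)) < 0.02
        assert abs(np.mean(errs_k)) < 0.02

    def test_all_zero_trace_flagged(self):
        trace = hg.FRAPTrace(times_s=np.arange(20.0), intensity=np.zeros(20))
        with pytest.raises(ValueError, match="zero"):
            hg.fit_frap(trace)

    def test_too_few_points_rejected(self):
        trace = hg.FRAPTrace(times_s=np.arange(5.0), intensity=np.ones(5))
        with pytest.raises(ValueError, match="10"):
            hg.fit_frap(trace)


class TestGelDiffusivity:
    def test_equal_rates_give_d0(self):
        res = hg.gel_diffusivity(0.1, 0.1, 73.0)
        assert res.d_hydrogel_um2_s == pytest.approx(73.0)

    def test_printed_rates_arithmetic(self):
        res = hg.gel_diffusivity(0.115, 0.179, 73.0)
        assert res.d_hydrogel_um2_s == pytest.approx(46.9, abs=0.05)

    def test_linear_in_gel_rate(self):
        a = hg.gel_diffusivity(0.1, 0.2, 50.0).d_hydrogel_um2_s
        b = hg.gel_diffusivity(0.05, 0.2, 50.0).d_hydrogel_um2_s
        assert a == pytest.approx(2 * b)

    def test_rate_ratio_scale_free(self):
        a = hg.gel_diffusivity(0.1, 0.2, 50.0)
        b = hg.gel_diffusivity(0.3, 0.6, 50.0)
        assert a.d_hydrogel_um2_s == pytest.approx(b.d_hydrogel_um2_s)

    def test_zero_solution_rate_rejected(self):
        with pytest.raises(ValueError):
            hg.gel_diffusivity(0.1, 0.0, 50.0)


class TestProbeMeshBound:
    def test_hindered_150kda_probe_bounds_17nm(self):
        assert hg.probe_mesh_bound([8.5e-9], [True]) == pytest.approx(17.0)

    def test_smallest_hindered_probe_wins(self):
        assert hg.probe_mesh_bound([4.5e-9, 8.5e-9], [True, True]) == pytest.approx(9.0)

    def test_no_hindered_probe_gives_null(self):
        assert hg.probe_mesh_bound([4.5e-9, 8.5e-9], [False, False]) is None


class TestAmideI:
    def test_normalize_window_max_is_one(self):
        spec = gen_ftir_spectrum()
        normed = hg.normalize_amide1(spec)
        win = normed.window(*hg.AMIDE_I_WINDOW)
        assert win.absorbance.max() == pytest.approx(1.0)
        again = hg.normalize_amide1(normed)
        assert np.allclose(again.absorbance, normed.absorbance)

    def test_flat_spectrum_rejected(self):
        spec = hg.FTIRSpectrum(np.arange(650.0, 4000.0, 2.0),
                               np.zeros(len(np.arange(650.0, 4000.0, 2.0))))
        with pytest.raises(ValueError):
            hg.normalize_amide1(spec)

    def test_noiseless_round_trip(self):
        amps = np.array([0.3, 0.8, 1.0, 0.6, 0.15])
        sigmas = np.array([8.0, 10.0, 9.0, 9.0, 6.0])
        spec = hg.normalize_amide1(gen_ftir_spectrum(amps, sigmas))
        fit = hg.deconvolve_amide1(spec)
        true_areas = amps * sigmas
        expected = true_areas / true_areas.sum()
        assert np.allclose(fit.area_fractions, expected, atol=1e-4)
        assert fit.area_fractions.sum() == pytest.approx(1.0, abs=1e-6)

    def test_centers_stay_within_allowed_shift(self):
        spec = hg.normalize_amide1(gen_ftir_spectrum(sigma_noise=0.01, seed=2))
        fit = hg.deconvolve_amide1(spec)
        for c, canonical in zip(fit.centers, hg.AMIDE_I_CENTERS):
            assert abs(c - canonical) <= 4.0 + 1e-9

    def test_recovery_under_one_percent_noise(self):
        """Assignment-pooled fractions are the identifiable quantities:
        the three coil/helix sub-bands overlap too strongly for their
        individual areas to be stable, but their pool, the β-sheet band
        and the β-turn band recover within 5 %."""
        amps = np.array([0.3, 0.8, 1.0, 0.6, 0.15])
        sigmas = np.array([8.0, 10.0, 9.0, 9.0, 6.0])
        areas = amps * sigmas
        expected = areas / areas.sum()

        def pooled(f):
            return np.array([f[0], f[1] + f[2] + f[3], f[4]])

        target = pooled(expected)
        for seed in range(20):
            spec = hg.normalize_amide1(
                gen_ftir_spectrum(amps, sigmas, sigma_noise=0.01, seed=seed)
            )
            fit = hg.deconvolve_amide1(spec)
            assert np.all(np.abs(pooled(fit.area_fractions) - target) < 0.05)
            assert abs(fit.ordered_fraction - (expected[0] + expected[4])) < 0.05

    def test_single_sheet_band_gives_full_ordered_fraction(self):
        x = np.arange(650.0, 4000.0, 2.0)
        y = np.exp(-0.5 * ((x - 1620.0) / 8.0) ** 2)
        fit = hg.deconvolve_amide1(hg.FTIRSpectrum(x, y))
        assert fit.ordered_fraction > 0.95

    def test_equal_bands_give_equal_fractions(self):
        spec = hg.normalize_amide1(
            gen_ftir_spectrum(np.full(5, 0.5), np.full(5, 7.0))
        )
        fit = hg.deconvolve_amide1(spec)
        assert np.allclose(fit.area_fractions, 0.2, atol=0.02)
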