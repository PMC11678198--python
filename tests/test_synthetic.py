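"""Tests of the synthetic seven-channel measurement generator."""

import numpy as np
import pytest

from lumisphere.spectra import (
    build_signal_set,
    compute_rt,
    compute_rt_polychromatic,
    extract_pl,
)
from lumisphere.sphere_model import effective_rt
from lumisphere.synthetic import (
    NoiseModel,
    PhantomTruth,
    generate_channels,
    matrix_of_samples,
    truth_spectra,
)


def analytic_engine(mu_a, mu_s_prime):
    """Smooth, monotone stand-in forward map (keeps these tests MC-free)."""
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    r = np.clip(0.3 + 0.05 * mu_s_prime - 0.8 * mu_a, 0.0, 1.0)
    t = np.clip(0.55 - 0.04 * mu_s_prime - 1.2 * mu_a, 0.0, 1.0)
    return r, t


QUIET = NoiseModel(shot_noise=False, dark_rate=0.0)


class TestTruthSpectra:
    def test_flat_scattering_when_power_law_off(self):
        mua, musp = truth_spectra(PhantomTruth(scatter_power_b=0.0), [400.0, 700.0])
        np.testing.assert_allclose(musp, 4.0)

    def test_power_law_anchored_at_600nm(self):
        _, musp = truth_spectra(PhantomTruth(musp_600=6.0, scatter_power_b=1.3), [600.0])
        assert musp[0] == pytest.approx(6.0)

    def test_zero_concentration_leaves_baseline(self):
        mua, _ = truth_spectra(PhantomTruth(dye_concentration=0.0), [525.0, 900.0])
        np.testing.assert_allclose(mua, 2e-3)

    def test_dye_peak_scales_with_printed_concentrations(self):
        concs = [2.66, 4.0, 5.33, 6.66]
        peaks = [
            truth_spectra(PhantomTruth(dye_concentration=c), [525.0])[0][0] - 2e-3
            for c in concs
        ]
        np.testing.assert_allclose(np.array(peaks) / peaks[0], np.array(concs) / concs[0], rtol=1e-12)

    def test_stokes_shift_enforced(self):
        with pytest.raises(ValueError, match="Stokes"):
            PhantomTruth(dye_peak_nm=550.0, pl_peak_nm=540.0)


class TestGenerateChannels:
    def test_noise_free_round_trip_reproduces_effective_rt(self, sphere):
        """The mono pipeline on noise-free output returns the engine's
        effective R, T to floating-point precision."""
        phantom = PhantomTruth(dye_concentration=0.0, pl_yield=0.0)
        scans, rho_cal = generate_channels(phantom, sphere, QUIET, analytic_engine)
        rt = compute_rt(build_signal_set(scans, rho_cal))
        mua, musp = truth_spectra(phantom, rt.wavelength)
        r_raw, t_raw = analytic_engine(mua, musp)
        for k in range(rt.wavelength.size):
            eff = effective_rt(r_raw[k], t_raw[k], sphere, wavelength=rt.wavelength[k])
            assert rt.R[k] == pytest.approx(eff.R_eff, rel=1e-12)
            assert rt.T[k] == pytest.approx(eff.T_eff, rel=1e-12)

    def test_pl_outside_elastic_window_leaves_mono_rt_unchanged(self, sphere):
        """Photoluminescence far from the set-point does not perturb the
        monochromatic analysis away from the PL emission band."""
        quiet = QUIET
        dark = generate_channels(
            PhantomTruth(dye_concentration=4.0, pl_yield=0.0), sphere, quiet, analytic_engine
        )
        lit = generate_channels(
            PhantomTruth(dye_concentration=4.0, pl_yield=0.1), sphere, quiet, analytic_engine
        )
        rt0 = compute_rt(build_signal_set(*dark))
        rt1 = compute_rt(build_signal_set(*lit))
        far = np.abs(rt0.wavelength - 548.0) > 70.0
        np.testing.assert_allclose(rt1.R[far], rt0.R[far], rtol=1e-6)

    def test_pl_band_peaks_at_emission_maximum(self, sphere):
        scans, _ = generate_channels(
            PhantomTruth(dye_concentration=4.0), sphere, QUIET, analytic_engine
        )
        # a wide mask keeps the elastic line's tails out of the PL readout
        pl = extract_pl(scans["SRB"], 520.0, window_nm=36.0)
        em = scans["SRB"].emission_nm
        assert em[np.ma.argmax(pl)] == pytest.approx(548.0, abs=2.0)

    def test_no_pl_when_excited_outside_dye_band(self, sphere):
        scans, _ = generate_channels(
            PhantomTruth(dye_concentration=4.0), sphere, QUIET, analytic_engine
        )
        pl = extract_pl(scans["SRB"], 900.0)
        em = scans["SRB"].emission_nm
        near_pl_band = np.abs(em - 548.0) < 20.0
        assert float(np.ma.max(pl[near_pl_band])) == pytest.approx(0.0, abs=1e-9)

    def test_flat_pl_free_sample_mono_equals_poly(self, sphere):
        """For a spectrally flat, non-luminescent phantom the broadband
        emulation is identical to the monochromatic analysis."""
        phantom = PhantomTruth(dye_concentration=0.0, pl_yield=0.0, scatter_power_b=0.0)
        flat_engine = lambda a, s: (
            np.full(np.shape(a), 0.5),
            np.full(np.shape(a), 0.3),
        )
        scans, rho_cal = generate_channels(phantom, sphere, QUIET, flat_engine)
        mono = compute_rt(build_signal_set(scans, rho_cal))
        poly = compute_rt_polychromatic(scans, rho_cal)
        np.testing.assert_allclose(poly.R, mono.R, rtol=1e-6)
        np.testing.assert_allclose(poly.T, mono.T, rtol=1e-6)

    def test_poly_artifact_grows_with_pl_amplitude(self, sphere):
        """Doubling the injected PL doubles the broadband excess, so the
        artifact magnitude is monotone in the PL yield."""
        excess = []
        for pl_yield in (0.05, 0.1, 0.2):
            scans, rho_cal = generate_channels(
                PhantomTruth(dye_concentration=4.0, pl_yield=pl_yield),
                sphere,
                QUIET,
                analytic_engine,
            )
            mono = compute_rt(build_signal_set(scans, rho_cal))
            poly = compute_rt_polychromatic(scans, rho_cal)
            band = (mono.wavelength >= 540) & (mono.wavelength <= 580)
            excess.append(np.max((poly.R - mono.R)[band]))
        assert excess[0] < excess[1] < excess[2]

    def test_shot_noise_scales_with_acquisition_time(self, sphere):
        """4x the averaging halves the scatter of the recovered R."""
        phantom = PhantomTruth(dye_concentration=0.0, pl_yield=0.0)
        ref_scans, rho_cal = generate_channels(phantom, sphere, QUIET, analytic_engine)
        ref = compute_rt(build_signal_set(ref_scans, rho_cal))

        def spread(n_avg, seeds):
            devs = []
            for seed in seeds:
                scans, _ = generate_channels(
                    phantom,
                    sphere,
                    NoiseModel(shot_noise=True, dark_rate=0.0, seed=seed),
                    analytic_engine,
                    n_averages=n_avg,
                )
                rt = compute_rt(build_signal_set(scans, rho_cal))
                devs.append(rt.R - ref.R)
            return np.std(np.concatenate(devs))

        s1 = spread(10, range(4))
        s4 = spread(40, range(4, 8))
        assert s1 / s4 == pytest.approx(2.0, rel=0.25)

    def test_seeded_noise_reproducible(self, sphere):
        noise = NoiseModel(shot_noise=True, seed=5)
        a, _ = generate_channels(PhantomTruth(), sphere, noise, analytic_engine)
        b, _ = generate_channels(PhantomTruth(), sphere, noise, analytic_engine)
        np.testing.assert_array_equal(a["SRB"].counts, b["SRB"].counts)

    def test_engine_coverage_gap_lists_wavelengths(self, sphere, small_lut):
        # musp_600=9 pushes the blue end far above the table's mu_s' range
        phantom = PhantomTruth(musp_600=9.0)
        with pytest.raises(ValueError, match="nm"):
            generate_channels(phantom, sphere, QUIET, small_lut)


class TestSampleMatrix:
    def test_default_batch_shape(self):
        phantoms = matrix_of_samples()
        assert len(phantoms) == 5 * 3  # (c0 + four concentrations) x 3 loadings
        concs = {p.dye_concentration for p in phantoms}
        assert concs == {0.0, 2.66, 4.0, 5.33, 6.66}

    def test_single_entry_lists(self):
        phantoms = matrix_of_samples([4.0], [2.0], [1.0])
        assert len(phantoms) == 2  # c0 and the one concentration

    def test_every_phantom_valid(self):
        for p in matrix_of_samples(thicknesses=(1.0, 2.0, 4.0)):
            assert p.musp_600 >= 0 and p.thickness_d > 0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            matrix_of_samples(concentrations=[])
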