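"""Tests of spectral preprocessing, elastic integration and two-beam algebra."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import erf

from lumisphere.spectra import (
    SignalSet,
    SpectralScan,
    acquisition_schedule,
    build_signal_set,
    compute_rt,
    dye_absorption,
    extract_pl,
    integrate_elastic,
    integrate_pl,
    preprocess,
)


def make_scan(counts, excitation, emission, t=0.1, n_avg=1, dark=None, units="counts"):
    return SpectralScan(
        channel_id="SRB",
        excitation_nm=excitation,
        emission_nm=emission,
        counts=counts,
        acquisition_time=t,
        n_averages=n_avg,
        dark_rate=dark,
        units=units,
    )


@pytest.fixture()
def gaussian_scan():
    """One excitation row: elastic Gaussian (FWHM 7 nm) + PL band at 548 nm."""
    emission = np.arange(250.0, 1051.0, 2.0)
    excitation = np.array([520.0])
    sigma = 7.0 / (2 * math.sqrt(2 * math.log(2)))
    elastic = 1e5 * np.exp(-0.5 * ((emission - 520.0) / sigma) ** 2)
    pl = 2e3 * np.exp(-0.5 * ((emission - 548.0) / 12.0) ** 2)
    return make_scan((elastic + pl)[None, :], excitation, emission, units="rate")


class TestPreprocess:
    def test_dark_equal_to_data_gives_zero(self):
        emission = np.arange(400.0, 420.0, 2.0)
        rate = np.full((1, emission.size), 70.0)
        scan = make_scan(rate * 0.1, np.array([410.0]), emission, t=0.1, dark=np.full(emission.size, 70.0))
        out = preprocess(scan)
        np.testing.assert_array_equal(out.counts, 0.0)
        assert out.units == "rate"

    def test_time_normalization(self):
        emission = np.arange(400.0, 420.0, 2.0)
        counts = np.full((1, emission.size), 100.0)
        a = preprocess(make_scan(counts, np.array([410.0]), emission, t=0.1))
        b = preprocess(make_scan(counts, np.array([410.0]), emission, t=0.2))
        np.testing.assert_allclose(a.counts, 2 * b.counts)

    def test_averaging_normalization(self):
        emission = np.arange(400.0, 420.0, 2.0)
        counts = np.full((1, emission.size), 100.0)
        a = preprocess(make_scan(counts, np.array([410.0]), emission, n_avg=1))
        b = preprocess(make_scan(counts, np.array([410.0]), emission, n_avg=10))
        np.testing.assert_allclose(a.counts, 10 * b.counts)

    def test_known_rate_recovered_under_shot_noise(self):
        rng = np.random.default_rng(3)
        emission = np.arange(400.0, 440.0, 2.0)
        true_rate = 5_000.0
        dark_rate = 50.0
        t, n_avg = 0.2, 10
        counts = rng.poisson((true_rate + dark_rate) * t * n_avg, size=(1, emission.size))
        scan = make_scan(
            counts.astype(float), np.array([410.0]), emission, t=t, n_avg=n_avg,
            dark=np.full(emission.size, dark_rate),
        )
        out = preprocess(scan)
        se = math.sqrt((true_rate + dark_rate) / (t * n_avg) / emission.size)
        assert abs(out.counts.mean() - true_rate) < 4 * se

    def test_dark_grid_mismatch_rejected(self):
        emission = np.arange(400.0, 420.0, 2.0)
        with pytest.raises(ValueError, match="dark"):
            make_scan(
                np.zeros((1, emission.size)), np.array([410.0]), emission,
                dark=np.zeros(emission.size + 1),
            )

    def test_acquisition_schedule_bands(self):
        t = acquisition_schedule([320.0, 350.0, 610.0, 700.0])
        np.testing.assert_allclose(t, [0.1, 0.05, 0.1, 0.2])


class TestElasticIntegration:
    def test_narrow_peak_fully_captured(self):
        emission = np.arange(500.0, 541.0, 0.5)
        counts = np.zeros((1, emission.size))
        counts[0, np.abs(emission - 520.0) <= 1.0] = 100.0
        scan = make_scan(counts, np.array([520.0]), emission, units="rate")
        total = np.trapezoid(counts[0], emission)
        assert integrate_elastic(scan, 520.0) == pytest.approx(total, rel=1e-12)

    def test_gaussian_window_capture_matches_error_function(self):
        """A FWHM-7 nm line loses the erf-complement outside the 10 nm window."""
        emission = np.arange(480.0, 561.0, 0.25)
        sigma = 7.0 / (2 * math.sqrt(2 * math.log(2)))
        counts = np.exp(-0.5 * ((emission - 520.0) / sigma) ** 2)[None, :]
        scan = make_scan(counts, np.array([520.0]), emission, units="rate")
        captured = integrate_elastic(scan, 520.0) / (sigma * math.sqrt(2 * math.pi))
        expected = erf(5.0 / (sigma * math.sqrt(2.0)))
        assert captured == pytest.approx(expected, abs=5e-4)

    def test_disjoint_pl_band_contributes_nothing(self, gaussian_scan):
        emission = gaussian_scan.emission_nm
        band = 2e3 * np.exp(-0.5 * ((emission - 548.0) / 8.0) ** 2)
        band[np.abs(emission - 548.0) > 18.0] = 0.0  # compactly supported PL
        pl_only = make_scan(band[None, :], np.array([520.0]), emission, units="rate")
        assert integrate_elastic(pl_only, 520.0) == 0.0

    def test_window_outside_grid_rejected(self):
        emission = np.arange(516.0, 525.0, 2.0)
        scan = make_scan(np.ones((1, emission.size)), np.array([520.0]), emission, units="rate")
        with pytest.raises(ValueError, match="window"):
            integrate_elastic(scan, 520.0)

    def test_elastic_plus_pl_partition_is_exact(self, gaussian_scan):
        total = np.trapezoid(gaussian_scan.counts[0], gaussian_scan.emission_nm)
        parts = integrate_elastic(gaussian_scan, 520.0) + integrate_pl(gaussian_scan, 520.0)
        assert parts == pytest.approx(total, rel=1e-12)

    def test_extract_pl_masks_elastic_window(self, gaussian_scan):
        pl = extract_pl(gaussian_scan, 520.0)
        em = gaussian_scan.emission_nm
        assert np.all(pl.mask[(em >= 515.0) & (em <= 525.0)])
        assert not pl.mask[np.argmin(np.abs(em - 548.0))]


def signals(**overrides):
    base = dict(
        excitation_nm=np.array([500.0]),
        SRB=np.array([50.0]),
        SNB=np.array([200.0]),
        STB=np.array([120.0]),
        CRBR=np.array([100.0]),
        CNBR=np.array([180.0]),
        CNBT=np.array([150.0]),
        CTBT=np.array([150.0]),
        rho_cal=np.array([0.95]),
    )
    base.update(overrides)
    return SignalSet(**base)


class TestTwoBeamEquation:
    def test_worked_quotient(self):
        rt = compute_rt(signals())
        assert rt.R[0] == pytest.approx((50 / 200) * (180 / 100) * 0.95, rel=1e-12)
        assert rt.R[0] == pytest.approx(0.4275, rel=1e-12)

    def test_mirror_remeasured_returns_rho_cal(self):
        rt = compute_rt(
            signals(SRB=np.array([100.0]), CRBR=np.array([100.0]),
                    SNB=np.array([180.0]), CNBR=np.array([180.0]),
                    rho_cal=np.array([0.98]))
        )
        assert rt.R[0] == pytest.approx(0.98, rel=1e-12)

    def test_open_port_remeasured_returns_unity(self):
        rt = compute_rt(
            signals(STB=np.array([150.0]), CTBT=np.array([150.0]),
                    SNB=np.array([160.0]), CNBT=np.array([160.0]))
        )
        assert rt.T[0] == pytest.approx(1.0, rel=1e-12)

    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0))
    def test_lamp_drift_cancels(self, sample_drift, cal_drift):
        """Scaling all sample signals and all calibration signals by common
        factors leaves R and T unchanged."""
        base = compute_rt(signals())
        drifted = compute_rt(
            signals(
                SRB=np.array([50.0 * sample_drift]),
                SNB=np.array([200.0 * sample_drift]),
                STB=np.array([120.0 * sample_drift]),
                CRBR=np.array([100.0 * cal_drift]),
                CNBR=np.array([180.0 * cal_drift]),
                CNBT=np.array([150.0 * cal_drift]),
                CTBT=np.array([150.0 * cal_drift]),
            )
        )
        assert drifted.R[0] == pytest.approx(base.R[0], rel=1e-9)
        assert drifted.T[0] == pytest.approx(base.T[0], rel=1e-9)

    def test_zero_denominator_flagged_as_nan(self):
        rt = compute_rt(signals(SNB=np.array([0.0])))
        assert np.isnan(rt.R[0])
        assert np.isnan(rt.T[0])

    def test_missing_channel_rejected(self):
        emission = np.arange(400.0, 420.0, 2.0)
        scan = make_scan(np.ones((1, emission.size)), np.array([410.0]), emission)
        with pytest.raises(ValueError, match="missing channels"):
            build_signal_set({"SRB": scan}, 0.98)


class TestDyeAbsorption:
    def test_baseline_equals_sample_gives_zero(self):
        mua = np.array([0.01, 0.02, 0.05])
        spec, flags = dye_absorption(mua, mua, 4.0)
        np.testing.assert_array_equal(spec, 0.0)
        assert not flags.any()

    def test_linear_concentrations_collapse(self):
        wl_band = np.exp(-0.5 * ((np.arange(450, 600, 10.0) - 525) / 15) ** 2)
        base = np.full(wl_band.size, 0.002)
        a, _ = dye_absorption(base + 2.0 * 0.03 * wl_band, base, 2.0)
        b, _ = dye_absorption(base + 5.0 * 0.03 * wl_band, base, 5.0)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_negative_excursions_flagged_not_clipped(self):
        base = np.array([0.01, 0.01, 0.01])
        sample = np.array([0.02, 0.002, 0.015])
        spec, flags = dye_absorption(sample, base, 1.0, noise_sigma=0.001)
        assert spec[1] < 0  # preserved
        assert flags[1]
        assert not flags[0]

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            dye_absorption(np.zeros(3), np.zeros(4), 1.0)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError, match="concentration"):
            dye_absorption(np.zeros(3), np.zeros(3), 0.0)
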