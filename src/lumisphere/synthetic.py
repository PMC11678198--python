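"""Synthetic seven-channel measurement sets for photoluminescent phantoms.

Stands in for the physical instrument: given a phantom ground truth (a
silicone slab loaded with zirconia scatterers and Rhodamine 6G dye), a
sphere geometry, a noise model and a forward radiative-transfer engine, it
produces the seven channel scans exactly as the measurement routine records
them, so the full processing pipeline (dark subtraction, elastic
integration, two-beam algebra, LUT inversion) can be exercised end to end
with a known answer.

Spectral model of the phantom:

- mu_s'(lambda) = musp_600 * (lambda/600)^(-b), the usual scatter power law;
- mu_a(lambda) = baseline + dye band, a Gaussian at 525 nm whose amplitude
  is linear in the dye concentration (wt%);
- photoluminescence: a Gaussian emission band at 548 nm injected at the
  *signal* level (not transported through the Monte Carlo), with amplitude
  proportional to the excitation power absorbed by the dye times an
  effective yield.  This is sufficient to reproduce the broadband-analysis
  artifact, which is a bookkeeping error in the analysis, not a transport
  effect.

Channel expectations satisfy the two-beam equation exactly in the noise-free
limit: running the monochromatic pipeline on noise-free output returns the
engine's effective R and T to floating-point precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mc_slab import BeamGeometry, OpticalProperties, simulate_rt
from .sphere_model import SphereGeometry, channel_signals
from .spectra import SpectralScan, acquisition_schedule

__all__ = [
    "PhantomTruth",
    "NoiseModel",
    "truth_spectra",
    "generate_channels",
    "matrix_of_samples",
    "MonteCarloEngine",
    "default_excitation_grid",
    "default_emission_grid",
]


def default_excitation_grid() -> np.ndarray:
    """320-1000 nm in 10 nm steps (69 excitation wavelengths)."""
    return np.arange(320.0, 1001.0, 10.0)


def default_emission_grid() -> np.ndarray:
    """Spectrometer emission grid, 250-1050 nm in 2 nm steps."""
    return np.arange(250.0, 1051.0, 2.0)


def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth description of one photoluminescent scattering phantom.

    Scattering follows mu_s'(lambda) = musp_600 (lambda/600)^-b.  The dye
    absorption band is a Gaussian at ``dye_peak_nm`` with
    ``dye_mua_per_wt`` mm^-1 of peak absorption per wt% of dye; emission is
    a Gaussian at ``pl_peak_nm``.  ``pl_yield`` is the effective
    emitted-per-absorbed fraction reaching the detector channels (quantum
    yield folded with collection efficiency) - a fixture parameter, the
    instrument it emulates does not report one.
    """

    musp_600: float = 4.0  # mm^-1 at 600 nm
    scatter_power_b: float = 1.0
    dye_concentration: float = 0.0  # wt%
    dye_peak_nm: float = 525.0
    dye_bandwidth_nm: float = 35.0  # FWHM
    dye_mua_per_wt: float = 0.03  # mm^-1 peak absorption per wt%
    baseline_mua: object = 2e-3  # mm^-1, constant or (wl, value) table
    pl_peak_nm: float = 548.0
    pl_bandwidth_nm: float = 30.0  # FWHM
    pl_yield: float = 0.1
    thickness_d: float = 2.0  # mm
    n_sample: float = 1.41
    g: float = 0.75

    def __post_init__(self) -> None:
        for name in (
            "musp_600",
            "dye_concentration",
            "dye_bandwidth_nm",
            "pl_bandwidth_nm",
            "pl_yield",
            "dye_mua_per_wt",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.thickness_d <= 0:
            raise ValueError("thickness_d must be > 0")
        if self.pl_peak_nm <= self.dye_peak_nm:
            raise ValueError(
                "pl_peak_nm must exceed dye_peak_nm (Stokes shift); got "
                f"{self.pl_peak_nm} <= {self.dye_peak_nm}"
            )
        if self.n_sample < 1:
            raise ValueError("n_sample must be >= 1")
        if not -1 < self.g < 1:
            raise ValueError("|g| must be < 1")

    def baseline_at(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        if np.isscalar(self.baseline_mua):
            return np.full(wl.shape, float(self.baseline_mua))
        wl_tab, mua_tab = self.baseline_mua
        return np.interp(wl, np.asarray(wl_tab, float), np.asarray(mua_tab, float))

    def dye_mua(self, wavelengths: np.ndarray) -> np.ndarray:
        """Dye-only absorption band, mm^-1 (linear in concentration)."""
        wl = np.asarray(wavelengths, dtype=float)
        sigma = _fwhm_to_sigma(self.dye_bandwidth_nm)
        return (
            self.dye_mua_per_wt
            * self.dye_concentration
            * np.exp(-0.5 * ((wl - self.dye_peak_nm) / sigma) ** 2)
        )


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: Poisson shot noise on expected counts plus dark rate."""

    shot_noise: bool = True
    dark_rate: float = 50.0  # counts/s per emission bin
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dark_rate < 0:
            raise ValueError("dark_rate must be >= 0")


def truth_spectra(phantom: PhantomTruth, wavelengths: Sequence[float]):
    """Ground-truth (mu_a(lambda), mu_s'(lambda)) of the phantom, mm^-1."""
    wl = np.asarray(wavelengths, dtype=float)
    musp = phantom.musp_600 * (wl / 600.0) ** (-phantom.scatter_power_b)
    mua = phantom.baseline_at(wl) + phantom.dye_mua(wl)
    return mua, musp


@dataclass(frozen=True)
class MonteCarloEngine:
    """Forward engine running the slab Monte Carlo per wavelength."""

    beam: BeamGeometry = field(default_factory=BeamGeometry)
    n_photons: int = 100_000
    seed: int = 0

    def forward_for(self, phantom: PhantomTruth, mu_a, mu_s_prime):
        r = np.empty(np.asarray(mu_a).shape)
        t = np.empty_like(r)
        for k, (a, s) in enumerate(zip(np.atleast_1d(mu_a), np.atleast_1d(mu_s_prime))):
            props = OpticalProperties(
                mu_a=float(a),
                mu_s_prime=float(s),
                g=phantom.g,
                n_sample=phantom.n_sample,
                thickness_d=phantom.thickness_d,
            )
            ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(k,))
            res = simulate_rt(props, self.beam, self.n_photons, int(ss.generate_state(1)[0]))
            r[k] = res.R_total
            t[k] = res.T_total
        return r, t


def _forward_raw(engine, phantom: PhantomTruth, mu_a, mu_s_prime):
    """Dispatch to whatever forward engine was provided (LUT, MC, callable)."""
    if hasattr(engine, "forward_for"):
        return engine.forward_for(phantom, mu_a, mu_s_prime)
    if hasattr(engine, "forward"):
        return engine.forward(mu_a, mu_s_prime)
    return engine(mu_a, mu_s_prime)


def _lamp_rate(wavelengths: np.ndarray) -> np.ndarray:
    """Source spectral brightness proxy (detector counts/s of beam power).

    A smooth laser-pumped-plasma-like curve peaking in the visible.  The
    absolute scale is chosen so that, after the sphere gain (~20x) and the
    default 10-average acquisition schedule, the two-beam R carries ~0.5%
    relative shot noise at mid-band - the photometric precision class the
    emulated instrument's acquisition-time schedule aims at.
    """
    wl = np.asarray(wavelengths, dtype=float)
    return 3e4 * (0.35 + 0.65 * np.exp(-0.5 * ((wl - 560.0) / 260.0) ** 2))


def generate_channels(
    phantom: PhantomTruth,
    sphere: SphereGeometry,
    noise: NoiseModel,
    engine,
    excitation_nm: np.ndarray | None = None,
    emission_nm: np.ndarray | None = None,
    rho_cal: float = 0.98,
    n_averages: int = 10,
):
    """Generate the seven channel scans for one phantom.

    ``engine`` supplies the raw slab forward map: a
    :class:`lumisphere.lut.LookupTable` (its ``forward`` method), a
    :class:`MonteCarloEngine`, or any callable ``(mu_a, mu_s') -> (R, T)``.
    Returns ``(scans, rho_cal_table)`` where ``scans`` maps channel ids to
    :class:`SpectralScan` (raw counts, dark rate attached) and
    ``rho_cal_table`` is the mirror-reflectance table the processing needs.

    Raises if the engine cannot cover the truth spectra (e.g. LUT grid gaps),
    listing the offending wavelengths.
    """
    exc = default_excitation_grid() if excitation_nm is None else np.asarray(excitation_nm, float)
    em = default_emission_grid() if emission_nm is None else np.asarray(emission_nm, float)
    mua, musp = truth_spectra(phantom, exc)
    try:
        r_true, t_true = _forward_raw(engine, phantom, mua, musp)
    except ValueError as err:
        bad = []
        for k in range(exc.size):
            try:
                _forward_raw(engine, phantom, mua[k : k + 1], musp[k : k + 1])
            except ValueError:
                bad.append(f"{exc[k]:g}")
        raise ValueError(
            "forward engine does not cover the phantom truth at "
            f"{', '.join(bad) or 'unknown'} nm: {err}"
        ) from err

    rng = np.random.default_rng(noise.seed)
    t_acq = acquisition_schedule(exc)
    lamp = _lamp_rate(exc)
    rho_w = np.array([sphere.wall_reflectance_at(w) for w in exc])
    df = sphere.direct_view_fraction

    # per-excitation channel expectations (fractions of the beam power)
    sig = {c: np.empty(exc.size) for c in ("SRB", "SNB", "STB", "CRBR", "CNBR", "CNBT", "CTBT")}
    for k, wl in enumerate(exc):
        s = channel_signals(
            float(np.clip(r_true[k], 0.0, 1.0)),
            float(np.clip(t_true[k], 0.0, 1.0)),
            sphere,
            rho_cal=rho_cal,
            wavelength=float(wl),
        )
        for c, v in s.items():
            sig[c][k] = v

    # photoluminescence amplitude per excitation: power absorbed by the dye
    # (Beer along the slab thickness, dye band only) times the effective
    # yield, split evenly between the reflection and transmission channels,
    # entering the sphere with the same factors as the sample's elastic light
    dye_abs = 1.0 - np.exp(-phantom.dye_mua(exc) * phantom.thickness_d)
    m_sample = np.array(
        [
            1.0
            / (
                1.0
                - rho_w[k] * (1.0 - sphere.total_port_fraction)
                - np.clip(r_true[k], 0.0, 1.0) * sphere.sample_port_fraction
            )
            for k in range(exc.size)
        ]
    )
    pl_amp = 0.5 * phantom.pl_yield * dye_abs * (rho_w * m_sample + df)

    sigma_line = _fwhm_to_sigma(7.0)  # monochromator line width
    sigma_pl = _fwhm_to_sigma(phantom.pl_bandwidth_nm)
    line = np.exp(-0.5 * ((em[None, :] - exc[:, None]) / sigma_line) ** 2) / (
        sigma_line * math.sqrt(2.0 * math.pi)
    )
    pl_shape = np.exp(-0.5 * ((em - phantom.pl_peak_nm) / sigma_pl) ** 2) / (
        sigma_pl * math.sqrt(2.0 * math.pi)
    )

    dark = np.full(em.shape, float(noise.dark_rate))
    scans = {}
    for c in sig:
        rate = lamp[:, None] * sig[c][:, None] * line
        if c in ("SRB", "STB"):
            rate = rate + (lamp * pl_amp)[:, None] * pl_shape[None, :]
        expected = (rate + dark[None, :]) * (t_acq[:, None] * n_averages)
        counts = rng.poisson(expected).astype(float) if noise.shot_noise else expected
        scans[c] = SpectralScan(
            channel_id=c,
            excitation_nm=exc,
            emission_nm=em,
            counts=counts,
            acquisition_time=t_acq,
            n_averages=n_averages,
            dark_rate=dark,
            units="counts",
        )
    rho_cal_table = (np.array([exc[0], exc[-1]]), np.array([rho_cal, rho_cal]))
    return scans, rho_cal_table


def matrix_of_samples(
    concentrations: Sequence[float] = (2.66, 4.0, 5.33, 6.66),
    particle_levels: Sequence[float] = (2.0, 4.0, 6.0),
    thicknesses: Sequence[float] = (2.0,),
    **phantom_kwargs,
) -> list:
    """Cartesian sample matrix: dye concentrations x scattering levels.

    ``particle_levels`` are mu_s' values at 600 nm (mm^-1).  A dye-free c0
    phantom is included for every particle level, mirroring the 5 x 3 batch
    of calibration phantoms (four dye concentrations plus c0, three
    scatterer loadings).
    """
    if not len(concentrations) or not len(particle_levels) or not len(thicknesses):
        raise ValueError("concentration/particle/thickness lists must be non-empty")
    phantoms = []
    for musp in particle_levels:
        for d in thicknesses:
            for c in (0.0, *concentrations):
                phantoms.append(
                    PhantomTruth(
                        musp_600=float(musp),
                        dye_concentration=float(c),
                        thickness_d=float(d),
                        **phantom_kwargs,
                    )
                )
    return phantoms
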