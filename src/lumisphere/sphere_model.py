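"""Analytic single-integrating-sphere radiation-exchange model.

Converts the true hemispherical reflectance/transmittance of a slab mounted
at the sample port into the effective, sphere-referred signals of the seven
measurement channels, and provides the correction applied when building the
lookup table.

Model (first-order radiation exchange, Jacquez-Kuppenheim style).  A
Lambertian source anywhere on the sphere wall irradiates the rest of the
sphere uniformly, so the average wall reflectance seen per bounce is

    rho_bar(Rs) = rho_w * (1 - f) + Rs * f_s

with ``f`` the total open-port area fraction, ``f_s`` the sample-port
fraction and ``Rs`` the reflectance of whatever occupies the sample port
(sample, calibration mirror, or 0 for an open port).  The sphere multiplier
is the geometric series M(Rs) = 1 / (1 - rho_bar(Rs)); because a Lambertian
source anywhere on a sphere irradiates the whole interior uniformly, this
series books port losses on every flight, including the first (a property
the discrete radiosity oracle in the test-suite confirms exactly).  The
detector views a wall spot, so a diffuse source of power P at the sample
port produces the detected radiance proportional to ``rho_w * P * M(Rs)``;
a collimated beam first reflecting off the wall produces
``rho_w^2 * P * M(Rs)``.  In the unbaffled sphere a fraction
``direct_fraction`` of the sample-borne first flight lands directly on the
viewed spot and is added to the signal.

The seven channels (reflection/normalization/transmission beams, sample "S"
or calibration "C" configuration) are composed from these elements; the
classical two-beam equation R = (SRB/SNB)(CNBR/CRBR) rho_cal applied to the
modelled signals defines the *effective* R and T the lookup table must be
built in, which is exactly what :func:`effective_rt` returns.  With the
normalization beam measured while the sample is mounted, the sample-
dependent gains cancel in the ratios, which is precisely why the instrument
carries that beam; the residual direct-view term is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SphereGeometry",
    "EffectiveRT",
    "sphere_gain",
    "effective_rt",
    "channel_signals",
    "CHANNELS",
]

#: the seven measurement channels
CHANNELS = ("SRB", "SNB", "STB", "CRBR", "CNBR", "CNBT", "CTBT")


def _default_ports() -> dict:
    return {
        "sample": 25.0,
        "reflection": 20.0,
        "normalization": 20.0,
        "detection": 20.0,
    }


@dataclass(frozen=True)
class SphereGeometry:
    """Single integrating sphere with sample port in the equatorial plane.

    The defaults describe a 150 mm sphere with a 25 mm sample port, three
    20 mm auxiliary ports, a 6 mm detector view spot and a flat barium-
    sulfate wall reflectance of 0.97.  ``wall_reflectance`` may be a float or
    a ``(wavelength_nm, reflectance)`` table.
    """

    sphere_diameter: float = 150.0  # mm
    wall_reflectance: object = 0.97
    port_diameters: dict = field(default_factory=_default_ports)
    detector_view_diameter: float = 6.0  # mm
    baffled: bool = False

    def __post_init__(self) -> None:
        if self.sphere_diameter <= 0:
            raise ValueError("sphere_diameter must be > 0")
        if "sample" not in self.port_diameters:
            raise ValueError("port_diameters must include a 'sample' port")
        for name, dia in self.port_diameters.items():
            if not 0 < dia < self.sphere_diameter:
                raise ValueError(
                    f"port '{name}' diameter {dia} must be in (0, sphere_diameter)"
                )
        if self.total_port_fraction >= 0.2:
            raise ValueError(
                "total port area fraction must stay below 0.2 for the "
                f"first-order sphere model, got {self.total_port_fraction:.3f}"
            )
        rho = np.atleast_1d(np.asarray(self.wall_reflectance_at(None)))
        if np.any(rho <= 0) or np.any(rho >= 1):
            raise ValueError("wall_reflectance must lie in (0, 1)")

    # -- geometry fractions -------------------------------------------------
    @property
    def sphere_area(self) -> float:
        return float(np.pi * self.sphere_diameter**2)

    def _port_fraction(self, diameter: float) -> float:
        return float(np.pi * (diameter / 2.0) ** 2 / self.sphere_area)

    @property
    def total_port_fraction(self) -> float:
        """f: summed open-port area as a fraction of the sphere area."""
        return sum(self._port_fraction(d) for d in self.port_diameters.values())

    @property
    def sample_port_fraction(self) -> float:
        """f_s: sample-port area fraction."""
        return self._port_fraction(self.port_diameters["sample"])

    @property
    def direct_view_fraction(self) -> float:
        """Unbaffled direct first-bounce view of the detector spot."""
        if self.baffled:
            return 0.0
        return self._port_fraction(self.detector_view_diameter)

    def wall_reflectance_at(self, wavelength: float | None) -> float:
        """Wall reflectance, interpolated if tabulated."""
        if np.isscalar(self.wall_reflectance):
            return float(self.wall_reflectance)
        wl_tab, rho_tab = self.wall_reflectance
        if wavelength is None:
            return float(np.asarray(rho_tab, dtype=float).mean())
        return float(np.interp(float(wavelength), np.asarray(wl_tab, float),
                               np.asarray(rho_tab, float)))


@dataclass(frozen=True)
class EffectiveRT:
    """Sphere-referred effective reflectance/transmittance signals."""

    R_eff: float
    T_eff: float
    multiplier_cal: float
    multiplier_sample: float


def sphere_gain(geom: SphereGeometry, sample_R: float, wavelength: float | None = None) -> float:
    """Sphere multiplier M = 1/(1 - rho_w (1-f) - sample_R f_s).

    ``sample_R`` is the reflectance of whatever occupies the sample port.
    """
    if not 0.0 <= sample_R <= 1.0:
        raise ValueError(f"sample_R must be in [0, 1], got {sample_R}")
    rho_w = geom.wall_reflectance_at(wavelength)
    f = geom.total_port_fraction
    f_s = geom.sample_port_fraction
    denom = 1.0 - rho_w * (1.0 - f) - sample_R * f_s
    if denom <= 0.0:
        raise ValueError(
            f"nonphysical sphere configuration: multiplier denominator {denom:.3g} <= 0"
        )
    return 1.0 / denom


def channel_signals(
    true_R: float,
    true_T: float,
    geom: SphereGeometry,
    rho_cal: float = 0.98,
    wavelength: float | None = None,
    direct_fraction: float | None = None,
) -> dict:
    """Modelled detector signals of the seven channels, per unit beam power.

    Sample channels are measured with the sample mounted (gain M(true_R)),
    calibration channels with the mirror (M(rho_cal)) or the port open
    (M(0)).  Diffuse sample-borne light contributes ``rho_w * P * M`` to the
    viewed wall radiance plus the unbaffled direct-view term; beam-on-wall
    channels pick up one extra wall reflection, ``rho_w^2 * P * M``.
    """
    for name, v in (("true_R", true_R), ("true_T", true_T)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if not 0.0 < rho_cal <= 1.0:
        raise ValueError(f"rho_cal must be in (0, 1], got {rho_cal}")
    df = geom.direct_view_fraction if direct_fraction is None else float(direct_fraction)
    rho_w = geom.wall_reflectance_at(wavelength)
    m_sample = sphere_gain(geom, true_R, wavelength)
    m_cal = sphere_gain(geom, rho_cal, wavelength)
    m_open = sphere_gain(geom, 0.0, wavelength)
    return {
        # sample mounted; diffuse reflected/transmitted light is the source
        "SRB": true_R * (rho_w * m_sample + df),
        "STB": true_T * (rho_w * m_sample + df),
        "SNB": rho_w * rho_w * m_sample,
        # calibration mirror mounted (specular lobe lands on the wall)
        "CRBR": rho_cal * rho_w * rho_w * m_cal,
        "CNBR": rho_w * rho_w * m_cal,
        # open sample port
        "CNBT": rho_w * rho_w * m_open,
        "CTBT": rho_w * rho_w * m_open,
    }


def effective_rt(
    true_R: float,
    true_T: float,
    geom: SphereGeometry,
    rho_cal: float = 0.98,
    wavelength: float | None = None,
    direct_fraction: float | None = None,
) -> EffectiveRT:
    """Effective (sphere-referred) R and T for a slab with true R, T.

    These are the values the two-beam analysis produces on the modelled
    channel signals; building the lookup table in this effective space is
    the analytic sphere correction.  The composed maps are strictly
    increasing in ``true_R`` and ``true_T`` respectively, and reduce to the
    identity for an ideal sphere (no open ports, no direct view).
    """
    s = channel_signals(true_R, true_T, geom, rho_cal, wavelength, direct_fraction)
    r_eff = s["SRB"] / s["SNB"] * s["CNBR"] / s["CRBR"] * rho_cal
    t_eff = s["STB"] / s["SNB"] * s["CNBT"] / s["CTBT"]
    return EffectiveRT(
        R_eff=float(r_eff),
        T_eff=float(t_eff),
        multiplier_cal=sphere_gain(geom, rho_cal, wavelength),
        multiplier_sample=sphere_gain(geom, true_R, wavelength),
    )
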