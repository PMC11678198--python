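"""Photon-packet Monte Carlo transport in a plane-parallel turbid slab.

Solves the radiative transfer equation for a homogeneous slab characterised
by an absorption coefficient ``mu_a``, a reduced scattering coefficient
``mu_s_prime``, a Henyey-Greenstein anisotropy ``g``, a refractive index and
a thickness, returning total hemispherical reflectance and transmittance.
The slab is illuminated through the sample port of an integrating sphere, so
packets that leave the slab face outside the port radius (or that wander past
a lateral boundary) are booked as lost rather than detected.

Transport is the standard MCML-style weighted-packet scheme: exponential
step sampling at mu_t = mu_a + mu_s, absorption by weight deposition at each
interaction, Henyey-Greenstein direction sampling, probabilistic unpolarized
Fresnel reflection at the faces and Russian roulette for low weights.  The
coordinate convention puts z = 0 at the illuminated face and z = d at the
exit face; "reflectance" means leaving with a direction cosine into z < 0.
Specular reflection at the entry face is tallied into R_total (the sphere
collects the specular lobe of the 8 degree beam).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "OpticalProperties",
    "BeamGeometry",
    "RTResult",
    "simulate_rt",
    "sample_hg",
    "fresnel_unpolarized",
    "roulette",
]

#: weight below which Russian roulette is played, and the survival probability
WEIGHT_THRESHOLD = 1e-4
SURVIVAL_P = 0.1

_MAX_SEED = 2**32


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one homogeneous slab at one wavelength.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1.
    mu_s_prime : float
        Reduced scattering coefficient mu_s * (1 - g), mm^-1.
    g : float
        Scattering anisotropy (mean cosine), in (-1, 1).
    n_sample : float
        Refractive index of the slab (>= 1).
    thickness_d : float
        Slab thickness, mm.
    """

    mu_a: float
    mu_s_prime: float
    g: float = 0.75
    n_sample: float = 1.41
    thickness_d: float = 2.0

    def __post_init__(self) -> None:
        if _require_finite("mu_a", self.mu_a) < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if _require_finite("mu_s_prime", self.mu_s_prime) < 0:
            raise ValueError(f"mu_s_prime must be >= 0, got {self.mu_s_prime}")
        if abs(_require_finite("g", self.g)) >= 1:
            raise ValueError(f"|g| must be < 1, got {self.g}")
        if _require_finite("n_sample", self.n_sample) < 1:
            raise ValueError(f"n_sample must be >= 1, got {self.n_sample}")
        if _require_finite("thickness_d", self.thickness_d) <= 0:
            raise ValueError(f"thickness_d must be > 0, got {self.thickness_d}")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient mu_s = mu_s_prime / (1 - g), mm^-1."""
        return self.mu_s_prime / (1.0 - self.g)


@dataclass(frozen=True)
class BeamGeometry:
    """Illumination and detection-aperture geometry.

    The defaults model the instrument this package emulates: a 5 mm diameter
    beam at 8 degrees incidence on a 25 mm diameter sample port.  Set
    ``beam_radius=0`` for a pencil beam and ``port_radius=inf`` to disable
    port-loss accounting (useful for comparison with plane-parallel oracles).
    ``lateral_limit`` is an optional hard radial boundary inside the slab;
    packets beyond it are booked as lost.
    """

    incidence_angle: float = 8.0  # degrees from surface normal
    beam_radius: float = 2.5  # mm
    port_radius: float = 12.5  # mm
    n_ambient: float = 1.0
    lateral_limit: float = math.inf  # mm

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence_angle < 90.0:
            raise ValueError(
                f"incidence_angle must be in [0, 90), got {self.incidence_angle}"
            )
        if self.beam_radius < 0:
            raise ValueError(f"beam_radius must be >= 0, got {self.beam_radius}")
        if self.beam_radius > self.port_radius:
            raise ValueError(
                f"beam_radius ({self.beam_radius}) must not exceed "
                f"port_radius ({self.port_radius})"
            )
        if _require_finite("n_ambient", self.n_ambient) < 1:
            raise ValueError(f"n_ambient must be >= 1, got {self.n_ambient}")
        if self.lateral_limit <= 0:
            raise ValueError(f"lateral_limit must be > 0, got {self.lateral_limit}")


@dataclass(frozen=True)
class RTResult:
    """Tallies of one Monte Carlo run, as fractions of the launched weight.

    ``R_total + T_total + A_total + L_lateral`` equals 1 to within floating
    point bookkeeping (not merely within sampling noise).  ``A_total``
    contains the zero-expectation Russian-roulette ledger in addition to true
    absorption, which is what makes the closure exact on every run.
    """

    R_total: float
    T_total: float
    A_total: float
    L_lateral: float
    se_R: float
    se_T: float
    n_photons: int
    seed: int

    @property
    def closure(self) -> float:
        """R + T + A + L; equals 1 up to floating-point bookkeeping."""
        return self.R_total + self.T_total + self.A_total + self.L_lateral


# ----------------------------------------------------------------------------
# elementary samplers (exposed pure functions + numba twins used in the kernel)
# ----------------------------------------------------------------------------


def fresnel_unpolarized(n_i: float, n_t: float, cos_theta_i: float):
    """Unpolarized Fresnel reflectance and transmitted cosine.

    Returns ``(reflectance, cos_theta_t)``; beyond the critical angle the
    reflectance is 1 and the transmitted cosine 0.
    """
    if n_i < 1 or n_t < 1:
        raise ValueError(f"refractive indices must be >= 1, got {n_i}, {n_t}")
    if not 0.0 < cos_theta_i <= 1.0:
        raise ValueError(f"cos_theta_i must be in (0, 1], got {cos_theta_i}")
    return _fresnel(n_i, n_t, cos_theta_i)


def sample_hg(g: float, u: float) -> float:
    """Henyey-Greenstein inverse-CDF sample of the scattering cosine.

    ``u`` is a uniform deviate in [0, 1).  For g = 0 the isotropic formula
    ``2u - 1`` is used (the HG inversion divides by g).
    """
    if abs(g) >= 1:
        raise ValueError(f"|g| must be < 1, got {g}")
    if not 0.0 <= u < 1.0:
        raise ValueError(f"u must be in [0, 1), got {u}")
    return _sample_hg(g, u)


def roulette(
    weight: float,
    threshold: float = WEIGHT_THRESHOLD,
    survival_p: float = SURVIVAL_P,
    u: float | None = None,
) -> float:
    """Russian roulette: unbiased termination of low-weight packets.

    Packets at or above ``threshold`` pass through unchanged.  Below it, the
    packet survives with probability ``survival_p`` carrying
    ``weight / survival_p``, else it dies (returns 0).  The expectation of the
    returned weight equals the input weight.
    """
    if not 0.0 < survival_p <= 1.0:
        raise ValueError(f"survival_p must be in (0, 1], got {survival_p}")
    if weight >= threshold:
        return weight
    if u is None:
        u = float(np.random.random())
    return weight / survival_p if u < survival_p else 0.0


@njit(cache=True)
def _fresnel(n_i, n_t, cos_i):
    if n_i == n_t:
        return 0.0, cos_i
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n_i * sin_i / n_t
    if sin_t >= 1.0:
        return 1.0, 0.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n_i * cos_i - n_t * cos_t) / (n_i * cos_i + n_t * cos_t)
    rp = (n_i * cos_t - n_t * cos_i) / (n_i * cos_t + n_t * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True, inline="always")
def _splitmix64(z):
    """One splitmix64 step; used to seed and decorrelate the stream."""
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _xorshift(state):
    """xorshift64* step: returns (uniform in [0,1), new state).

    Pure integer arithmetic, so sequences are bit-identical across platforms.
    """
    state ^= state >> np.uint64(12)
    state ^= (state << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    state ^= state >> np.uint64(27)
    out = (state * np.uint64(0x2545F4914F6CDD1D)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return (out >> np.uint64(11)) * 1.1102230246251565e-16, state


@njit(cache=True)
def _sample_hg(g, u):
    if abs(g) < 1e-12:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - t * t) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, fastmath=True)
def _mc_kernel(
    mu_a,
    mu_s,
    g,
    n_in,
    n_out,
    d,
    sin0,
    cos0,
    beam_r,
    port_r,
    lat_max,
    n_photons,
    seed,
):
    """Trace ``n_photons`` packets; return per-run tallies and second moments.

    Returns (sum_R, sum_T, sum_A, sum_L, sum_R2, sum_T2) where the sums run
    over per-photon contributions (each photon's pieces add to exactly 1).
    """
    st = _splitmix64(np.uint64(seed))
    st = _splitmix64(st)
    if st == np.uint64(0):
        st = np.uint64(0x9E3779B97F4A7C15)
    mu_t = mu_a + mu_s
    frac_a = mu_a / mu_t if mu_t > 0.0 else 0.0
    lat2 = lat_max * lat_max

    # entry interface: shared specular reflection and refracted direction
    r_sp, cos_in = _fresnel(n_out, n_in, cos0)
    sin_in = n_out * sin0 / n_in if n_in != n_out else sin0

    sum_r = 0.0
    sum_t = 0.0
    sum_a = 0.0
    sum_l = 0.0
    sum_r2 = 0.0
    sum_t2 = 0.0

    for _ in range(n_photons):
        if beam_r > 0.0:
            u1, st = _xorshift(st)
            u2, st = _xorshift(st)
            rr = beam_r * math.sqrt(u1)
            phi = 2.0 * math.pi * u2
            x = rr * math.cos(phi)
            y = rr * math.sin(phi)
        else:
            x = 0.0
            y = 0.0
        z = 0.0
        ux = sin_in
        uy = 0.0
        uz = cos_in
        cr = r_sp  # specular lobe lands inside the port (beam_r <= port_r)
        ct = 0.0
        ca = 0.0
        cl = 0.0
        w = 1.0 - r_sp

        while w > 0.0:
            if mu_t > 0.0:
                u1, st = _xorshift(st)
                s = -math.log(1.0 - u1) / mu_t
            else:
                s = 1e30
            if uz > 1e-12:
                db = (d - z) / uz
            elif uz < -1e-12:
                db = -z / uz
            else:
                db = 1e30

            if db <= s:
                # boundary hit
                x += db * ux
                y += db * uy
                going_down = uz > 0.0
                z = d if going_down else 0.0
                rf, _cos_t = _fresnel(n_in, n_out, abs(uz))
                u1, st = _xorshift(st)
                if u1 < rf:
                    uz = -uz
                    continue
                if x * x + y * y <= port_r * port_r:
                    if going_down:
                        ct += w
                    else:
                        cr += w
                else:
                    cl += w
                break

            # interaction inside the slab
            x += s * ux
            y += s * uy
            z += s * uz
            if x * x + y * y > lat2:
                cl += w
                break
            dw = w * frac_a
            ca += dw
            w -= dw
            if w <= 0.0:
                break
            u1, st = _xorshift(st)
            cth = _sample_hg(g, u1)
            sth = math.sqrt(max(0.0, 1.0 - cth * cth))
            # azimuth via rejection on the unit disk (avoids cos/sin calls)
            while True:
                u1, st = _xorshift(st)
                u2, st = _xorshift(st)
                pa = 2.0 * u1 - 1.0
                pb = 2.0 * u2 - 1.0
                pr2 = pa * pa + pb * pb
                if 1e-12 < pr2 <= 1.0:
                    break
            inv = 1.0 / pr2
            cp = (pa * pa - pb * pb) * inv
            sp = 2.0 * pa * pb * inv
            if abs(uz) > 0.99999:
                ux = sth * cp
                uy = sth * sp
                uz = cth if uz > 0.0 else -cth
            else:
                den = math.sqrt(1.0 - uz * uz)
                nux = sth * (ux * uz * cp - uy * sp) / den + ux * cth
                nuy = sth * (uy * uz * cp + ux * sp) / den + uy * cth
                nuz = -den * sth * cp + uz * cth
                ux = nux
                uy = nuy
                uz = nuz
            if w < WEIGHT_THRESHOLD:
                # Russian roulette; the ledger keeps the closure exact while
                # the expectation of the adjustment is zero.
                u1, st = _xorshift(st)
                if u1 < SURVIVAL_P:
                    boost = w * (1.0 / SURVIVAL_P - 1.0)
                    w += boost
                    ca -= boost
                else:
                    ca += w
                    break

        sum_r += cr
        sum_t += ct
        sum_a += ca
        sum_l += cl
        sum_r2 += cr * cr
        sum_t2 += ct * ct

    return sum_r, sum_t, sum_a, sum_l, sum_r2, sum_t2


def simulate_rt(
    props: OpticalProperties,
    beam: BeamGeometry,
    n_photons: int,
    seed: int,
) -> RTResult:
    """Run the slab Monte Carlo and return hemispherical R, T with errors.

    Identical ``(props, beam, n_photons, seed)`` reproduce bit-identical
    tallies.  Standard errors are estimated from the variance of per-photon
    contributions.
    """
    if not isinstance(props, OpticalProperties):
        props = OpticalProperties(*props)
    if not isinstance(beam, BeamGeometry):
        beam = BeamGeometry(*beam)
    n_photons = int(n_photons)
    if n_photons < 1:
        raise ValueError(f"n_photons must be >= 1, got {n_photons}")
    seed = int(seed)
    if not 0 <= seed < _MAX_SEED:
        raise ValueError(f"seed must be in [0, 2^32), got {seed}")

    theta = math.radians(beam.incidence_angle)
    sum_r, sum_t, sum_a, sum_l, sum_r2, sum_t2 = _mc_kernel(
        props.mu_a,
        props.mu_s,
        props.g,
        props.n_sample,
        beam.n_ambient,
        props.thickness_d,
        math.sin(theta),
        math.cos(theta),
        beam.beam_radius,
        beam.port_radius,
        beam.lateral_limit,
        n_photons,
        seed,
    )
    n = float(n_photons)
    mean_r = sum_r / n
    mean_t = sum_t / n
    var_r = max(sum_r2 / n - mean_r * mean_r, 0.0)
    var_t = max(sum_t2 / n - mean_t * mean_t, 0.0)
    return RTResult(
        R_total=mean_r,
        T_total=mean_t,
        A_total=sum_a / n,
        L_lateral=sum_l / n,
        se_R=math.sqrt(var_r / n),
        se_T=math.sqrt(var_t / n),
        n_photons=n_photons,
        seed=seed,
    )
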