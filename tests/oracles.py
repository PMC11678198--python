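"""Independent oracles used by the test-suite.

These are deliberately separate implementations from the package:

- :func:`adding_doubling_rt`: a plane-parallel adding-doubling solver
  (van de Hulst doubling with infinitesimal-generator initialization,
  Henyey-Greenstein redistribution from the Legendre addition theorem,
  Fresnel boundary layers, Gauss + Radau quadrature with a node at mu = 1
  so collimated normal incidence is exact).
- :func:`mie_bessel`: Mie coefficients straight from the Bohren-Huffman
  closed formulas using scipy's spherical Bessel functions (the package uses
  the logarithmic-derivative recursion instead).
- :func:`radiosity_sphere_signal`: a discrete radiosity solution of the
  integrating-sphere cavity; on a sphere interior all patch-to-patch view
  factors equal the area fraction, which makes the linear system exact.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import eval_legendre, roots_jacobi, spherical_jn, spherical_yn

# ---------------------------------------------------------------------------
# quadrature
# ---------------------------------------------------------------------------


def radau_right(n: int):
    """Gauss-Radau nodes/weights on [-1, 1] with a fixed node at +1.

    Built from the left-Radau rule (fixed node at -1, interior nodes the
    roots of (P_{n-1} + P_n)/(1 + x)) by the reflection x -> -x.
    """
    xj, wj = roots_jacobi(n - 1, 0.0, 1.0)  # interior nodes of left-Radau
    x = np.concatenate(([-1.0], xj))
    w = np.concatenate(([2.0 / n**2], wj / (1.0 + xj)))
    return -x[::-1], w[::-1]


def slab_quadrature(n_low: int, n_high: int, mu_split: float):
    """Composite cosine quadrature on (0, 1] with a node at mu = 1.

    Gauss-Legendre on [0, mu_split] (below the critical cone) and right-
    Radau on [mu_split, 1] so the collimated direction is a genuine node.
    """
    xg, wg = np.polynomial.legendre.leggauss(n_low)
    mu1 = 0.5 * mu_split * (xg + 1.0)
    w1 = 0.5 * mu_split * wg
    xr, wr = radau_right(n_high)
    mu2 = mu_split + 0.5 * (1.0 - mu_split) * (xr + 1.0)
    w2 = 0.5 * (1.0 - mu_split) * wr
    return np.concatenate([mu1, mu2]), np.concatenate([w1, w2])


# ---------------------------------------------------------------------------
# adding-doubling
# ---------------------------------------------------------------------------


def _hg_redistribution(mu: np.ndarray, g: float, tol: float = 1e-12):
    """Azimuth-averaged HG phase matrices h(+mu_i, mu_j), h(-mu_i, mu_j)."""
    if g == 0.0:
        n = mu.size
        return np.ones((n, n)), np.ones((n, n))
    l_max = max(10, int(math.log(tol) / math.log(abs(g))) + 1)
    h_plus = np.zeros((mu.size, mu.size))
    h_minus = np.zeros((mu.size, mu.size))
    for l in range(l_max + 1):
        chi = (2 * l + 1) * g**l
        p = eval_legendre(l, mu)
        outer = np.outer(p, p)
        h_plus += chi * outer
        h_minus += chi * ((-1.0) ** l) * outer
    return h_plus, h_minus


def _unpolarized_fresnel(n_i: float, n_t: float, mu: np.ndarray) -> np.ndarray:
    sin_t2 = (n_i / n_t) ** 2 * (1.0 - mu**2)
    r = np.ones_like(mu)
    ok = sin_t2 < 1.0
    mu_t = np.sqrt(1.0 - sin_t2[ok])
    mu_i = mu[ok]
    rs = ((n_i * mu_i - n_t * mu_t) / (n_i * mu_i + n_t * mu_t)) ** 2
    rp = ((n_i * mu_t - n_t * mu_i) / (n_i * mu_t + n_t * mu_i)) ** 2
    r[ok] = 0.5 * (rs + rp)
    return r


def _add_layers(a, b):
    """Compose layer a on top of layer b; layers are (Rtop, Rbot, Tdown, Tup)."""
    rt_a, rb_a, td_a, tu_a = a
    rt_b, rb_b, td_b, tu_b = b
    eye = np.eye(rt_a.shape[0])
    d_down = np.linalg.solve(eye - rb_a @ rt_b, td_a)
    rt = rt_a + tu_a @ rt_b @ d_down
    td = td_b @ d_down
    d_up = np.linalg.solve(eye - rt_b @ rb_a, tu_b)
    rb = rb_b + td_b @ rb_a @ d_up
    tu = tu_a @ d_up
    return rt, rb, td, tu


def adding_doubling_rt(
    mu_a: float,
    mu_s: float,
    g: float,
    n_slab: float,
    d: float,
    n_outside: float = 1.0,
    n_low: int = 24,
    n_high: int = 24,
):
    """Total hemispherical R and T of a slab for collimated normal incidence.

    The slab interior is solved by doubling at internal angles; smooth
    Fresnel interfaces are added as diagonal boundary layers.  Specular
    (unscattered) reflection and transmission are included, matching the
    Monte Carlo tallies.
    """
    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t if mu_t > 0 else 0.0
    tau = mu_t * d

    if n_slab > n_outside:
        mu_c = math.sqrt(1.0 - (n_outside / n_slab) ** 2)
    else:
        mu_c = 0.5
    mu, w = slab_quadrature(n_low, n_high, mu_c)
    n = mu.size
    c = 2.0 * mu * w  # star-product metric
    eye = np.eye(n)

    n_doublings = 0
    if tau == 0.0:
        r_slab = np.zeros((n, n))
        t_slab = np.diag(1.0 / c)  # star identity
    else:
        n_doublings = max(0, math.ceil(math.log2(tau / 1e-6)))
        tau0 = tau / 2**n_doublings
        h_plus, h_minus = _hg_redistribution(mu, g)
        denom = 4.0 * np.outer(mu, mu)
        r_slab = albedo * tau0 * h_minus / denom
        t_slab = albedo * tau0 * h_plus / denom + np.diag(
            (1.0 - tau0 / mu) / (2.0 * mu * w)
        )
    # convert to flux-coupled ("bold") operators and double up
    r_b = r_slab * c[None, :]
    t_b = t_slab * c[None, :]
    for _ in range(n_doublings):
        d_mat = np.linalg.solve(eye - r_b @ r_b, t_b)
        r_b = r_b + t_b @ r_b @ d_mat
        t_b = t_b @ d_mat

    slab = (r_b, r_b, t_b, t_b)
    if n_slab != n_outside:
        # clamp total internal reflection marginally below 1 so the
        # interface-interface geometric series stays invertible (its limit
        # is finite; the clamp changes R/T by < 1e-9)
        r_f = np.minimum(_unpolarized_fresnel(n_slab, n_outside, mu), 1.0 - 1e-9)
        boundary = (np.diag(r_f), np.diag(r_f), np.diag(1.0 - r_f), np.diag(1.0 - r_f))
        stack = _add_layers(boundary, _add_layers(slab, boundary))
    else:
        stack = slab
    rt, _, td, _ = stack

    k = n - 1  # the mu = 1 Radau node
    assert abs(mu[k] - 1.0) < 1e-12
    flux = 2.0 * mu * w
    r_tot = float(flux @ rt[:, k] / flux[k])
    t_tot = float(flux @ td[:, k] / flux[k])
    return r_tot, t_tot


# ---------------------------------------------------------------------------
# Mie via scipy Bessel functions (Bohren-Huffman closed formulas)
# ---------------------------------------------------------------------------


def mie_bessel(x: float, m: float, n_max: int):
    """Mie a_n, b_n from psi/xi Riccati-Bessel functions (no recursion tricks)."""
    n = np.arange(1, n_max + 1)
    jx = spherical_jn(n, x)
    jxp = spherical_jn(n, x, derivative=True)
    yx = spherical_yn(n, x)
    yxp = spherical_yn(n, x, derivative=True)
    jm = spherical_jn(n, m * x)
    jmp = spherical_jn(n, m * x, derivative=True)
    psi = x * jx
    psip = jx + x * jxp
    chi = -x * yx
    chip = -(yx + x * yxp)
    xi = psi - 1j * chi
    xip = psip - 1j * chip
    psim = m * x * jm
    psimp = jm + m * x * jmp
    a = (m * psim * psip - psi * psimp) / (m * psim * xip - xi * psimp)
    b = (psim * psip - m * psi * psimp) / (psim * xip - m * xi * psimp)
    return a, b


def mie_efficiencies_bessel(x: float, m: float, n_max: int | None = None):
    """(q_ext, q_sca, g) from :func:`mie_bessel` coefficients."""
    if n_max is None:
        n_max = int(x + 4.05 * x ** (1 / 3) + 10)
    a, b = mie_bessel(x, m, n_max)
    n = np.arange(1, n_max + 1, dtype=float)
    t = 2 * n + 1
    q_ext = 2 / x**2 * np.sum(t * np.real(a + b))
    q_sca = 2 / x**2 * np.sum(t * (np.abs(a) ** 2 + np.abs(b) ** 2))
    g_q = (
        4
        / x**2
        * (
            np.sum(
                n[:-1]
                * (n[:-1] + 2)
                / (n[:-1] + 1)
                * np.real(a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:]))
            )
            + np.sum(t / (n * (n + 1)) * np.real(a * np.conj(b)))
        )
    )
    return q_ext, q_sca, g_q / q_sca


# ---------------------------------------------------------------------------
# discrete radiosity of the integrating-sphere cavity
# ---------------------------------------------------------------------------


def radiosity_sphere_signal(
    area_fractions: dict,
    reflectances: dict,
    source_patch: str,
    view_patch: str,
    source_power: float = 1.0,
):
    """Viewed-patch radiosity in a sphere cavity by discrete radiosity.

    ``area_fractions`` maps patch name -> area fraction (must sum to 1);
    ``reflectances`` maps patch name -> diffuse reflectance.
    ``source_power`` leaves ``source_patch`` diffusely (emitted radiosity).
    Because every interior view factor of a sphere equals the target's area
    fraction (uniform-irradiance property), the linear system
    B_i = B0_i + rho_i * sum_j f_j B_j is exact, not an approximation.
    The detector signal is the radiosity of the patch it views.
    """
    names = list(area_fractions)
    f = np.array([area_fractions[k] for k in names])
    if abs(f.sum() - 1.0) > 1e-12:
        raise ValueError("area fractions must sum to 1")
    rho = np.array([reflectances[k] for k in names])
    b0 = np.zeros(len(names))
    i_src = names.index(source_patch)
    b0[i_src] = source_power / f[i_src]  # emitted radiosity (per unit area)
    a_mat = np.eye(len(names)) - np.outer(rho, f)
    b = np.linalg.solve(a_mat, b0 + 0.0)
    # solve B = B0 + rho * (f @ B):  (I - rho f^T) B = B0
    return float(b[names.index(view_patch)])
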