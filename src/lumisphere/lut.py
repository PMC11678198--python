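"""Monte Carlo lookup tables R(mu_a, mu_s') / T(mu_a, mu_s') and their inversion.

A :class:`LookupTable` stores, for fixed (g, n, d) and a fixed sphere/beam
geometry, the forward map from the optical-property grid to hemispherical
reflectance and transmittance, both raw (slab only) and sphere-corrected
(effective signals, the space measured values live in).  Inversion finds the
(mu_a, mu_s') whose interpolated effective (R, T) is closest to a measured
pair: a coarse scan on a refined mesh, followed by bounded least-squares
(Newton-type) refinement on the smooth interpolant.  The mu_a axis is
log-spaced because the measurable absorption spans several decades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import least_squares

from .mc_slab import BeamGeometry, OpticalProperties, simulate_rt
from .sphere_model import SphereGeometry, effective_rt

__all__ = [
    "LookupTable",
    "InversionResult",
    "build_lut",
    "invert_rt",
    "invert_spectrum",
    "default_mua_grid",
    "default_musp_grid",
]

LUT_VERSION = 1


def default_mua_grid(n: int = 40, lo: float = 1e-4, hi: float = 1.0) -> np.ndarray:
    """Log-spaced absorption grid, mm^-1."""
    return np.logspace(math.log10(lo), math.log10(hi), n)


def default_musp_grid(n: int = 40, lo: float = 0.1, hi: float = 10.0) -> np.ndarray:
    """Linear reduced-scattering grid, mm^-1."""
    return np.linspace(lo, hi, n)


@dataclass
class LookupTable:
    """Forward tables over a (mu_a, mu_s') grid for fixed (g, n, d).

    ``R_table``/``T_table`` are the sphere-corrected effective values used
    for inversion; ``R_raw``/``T_raw`` are the slab-only values (identical
    when no sphere is attached).  ``mc_meta`` records photons and master
    seed so any cell can be regenerated.
    """

    mua_grid: np.ndarray
    musp_grid: np.ndarray
    R_table: np.ndarray  # sphere-corrected, shape (n_mua, n_musp)
    T_table: np.ndarray
    R_raw: np.ndarray
    T_raw: np.ndarray
    se_R: np.ndarray
    se_T: np.ndarray
    g: float
    n_sample: float
    thickness_d: float
    beam: BeamGeometry = field(default_factory=BeamGeometry)
    sphere: SphereGeometry | None = None
    rho_cal: float = 0.98
    n_photons: int = 0
    seed: int = 0
    version: int = LUT_VERSION

    def __post_init__(self) -> None:
        self.mua_grid = np.asarray(self.mua_grid, dtype=float)
        self.musp_grid = np.asarray(self.musp_grid, dtype=float)
        for name in ("R_table", "T_table", "R_raw", "T_raw", "se_R", "se_T"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name, grid in (("mua_grid", self.mua_grid), ("musp_grid", self.musp_grid)):
            if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
                raise ValueError(f"{name} must be 1-D strictly ascending")
        shape = (self.mua_grid.size, self.musp_grid.size)
        for name in ("R_table", "T_table", "R_raw", "T_raw"):
            tab = getattr(self, name)
            if tab.shape != shape:
                raise ValueError(f"{name} has shape {tab.shape}, expected {shape}")
            if not np.all(np.isfinite(tab)) or tab.min() < 0 or tab.max() > 1:
                raise ValueError(f"{name} must be finite and within [0, 1]")
        self._interp_cache: dict = {}

    # -- interpolation ------------------------------------------------------
    @property
    def _log_mua(self) -> np.ndarray:
        return np.log10(self.mua_grid)

    def _interpolator(self, name: str) -> RegularGridInterpolator:
        if name not in self._interp_cache:
            method = (
                "cubic"
                if self.mua_grid.size >= 4 and self.musp_grid.size >= 4
                else "linear"
            )
            self._interp_cache[name] = RegularGridInterpolator(
                (self._log_mua, self.musp_grid),
                getattr(self, name),
                method=method,
                bounds_error=True,
            )
        return self._interp_cache[name]

    def _eval(self, names, mu_a, mu_s_prime):
        pts = np.column_stack(
            [np.log10(np.atleast_1d(mu_a)), np.atleast_1d(mu_s_prime)]
        )
        return tuple(self._interpolator(n)(pts) for n in names)

    def forward(self, mu_a, mu_s_prime):
        """Interpolated raw slab (R, T) at arbitrary in-grid properties."""
        r, t = self._eval(("R_raw", "T_raw"), mu_a, mu_s_prime)
        return r, t

    def forward_effective(self, mu_a, mu_s_prime):
        """Interpolated sphere-corrected effective (R, T)."""
        r, t = self._eval(("R_table", "T_table"), mu_a, mu_s_prime)
        return r, t

    def jacobian_determinant(self, mu_a: float, mu_s_prime: float, rel_step: float = 1e-4):
        """|det J| of effective (R, T) w.r.t. (log10 mu_a, mu_s'), by central differences."""
        lx = math.log10(mu_a)
        dy = max(rel_step * (self.musp_grid[-1] - self.musp_grid[0]), 1e-6)
        dx = rel_step * (self._log_mua[-1] - self._log_mua[0])
        f = lambda l, m: np.array(self.forward_effective(10.0**l, m)).ravel()
        j = np.column_stack(
            [
                (f(lx + dx, mu_s_prime) - f(lx - dx, mu_s_prime)) / (2 * dx),
                (f(lx, mu_s_prime + dy) - f(lx, mu_s_prime - dy)) / (2 * dy),
            ]
        )
        return abs(np.linalg.det(j))


@dataclass(frozen=True)
class InversionResult:
    """One inverted (mu_a, mu_s') estimate with its (R, T)-space residual."""

    mu_a: float
    mu_s_prime: float
    residual: float
    flags: tuple = ()

    @property
    def in_grid(self) -> bool:
        return "extrapolated" not in self.flags


def _cell_seed(master: int, i: int, j: int) -> int:
    """Deterministic per-cell seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=(i, j))
    return int(ss.generate_state(1)[0])


def build_lut(
    mua_grid,
    musp_grid,
    fixed_params: tuple,
    beam: BeamGeometry | None = None,
    sphere: SphereGeometry | None = None,
    n_photons: int = 10_000,
    seed: int = 0,
    rho_cal: float = 0.98,
) -> LookupTable:
    """Build the forward lookup table cell by cell.

    ``fixed_params`` is (g, n_sample, thickness_d).  Every cell is one
    :func:`lumisphere.mc_slab.simulate_rt` run (with a per-cell seed derived
    deterministically from ``seed``) followed by the sphere correction when a
    geometry is given.
    """
    mua_grid = np.asarray(mua_grid, dtype=float)
    musp_grid = np.asarray(musp_grid, dtype=float)
    if n_photons < 1_000:
        raise ValueError(f"n_photons must be >= 1000, got {n_photons}")
    g, n_sample, thickness_d = (float(v) for v in fixed_params)
    beam = beam or BeamGeometry()

    shape = (mua_grid.size, musp_grid.size)
    r_raw = np.zeros(shape)
    t_raw = np.zeros(shape)
    se_r = np.zeros(shape)
    se_t = np.zeros(shape)
    r_eff = np.zeros(shape)
    t_eff = np.zeros(shape)
    for i, mua in enumerate(mua_grid):
        for j, musp in enumerate(musp_grid):
            props = OpticalProperties(
                mu_a=mua, mu_s_prime=musp, g=g, n_sample=n_sample, thickness_d=thickness_d
            )
            try:
                res = simulate_rt(props, beam, n_photons, _cell_seed(seed, i, j))
            except Exception as err:  # annotate the failing cell
                raise RuntimeError(
                    f"LUT cell (mu_a={mua:g}, mu_s'={musp:g}) failed: {err}"
                ) from err
            r_raw[i, j] = res.R_total
            t_raw[i, j] = res.T_total
            se_r[i, j] = res.se_R
            se_t[i, j] = res.se_T
            if sphere is not None:
                eff = effective_rt(res.R_total, res.T_total, sphere, rho_cal)
                r_eff[i, j] = eff.R_eff
                t_eff[i, j] = eff.T_eff
            else:
                r_eff[i, j] = res.R_total
                t_eff[i, j] = res.T_total

    return LookupTable(
        mua_grid=mua_grid,
        musp_grid=musp_grid,
        R_table=r_eff,
        T_table=t_eff,
        R_raw=r_raw,
        T_raw=t_raw,
        se_R=se_r,
        se_T=se_t,
        g=g,
        n_sample=n_sample,
        thickness_d=thickness_d,
        beam=beam,
        sphere=sphere,
        rho_cal=rho_cal,
        n_photons=int(n_photons),
        seed=int(seed),
    )


def _coarse_scan(lut: LookupTable, r_meas: float, t_meas: float, refine: int = 6):
    """Objective on a refined mesh; returns mesh axes and the misfit surface."""
    lx = np.linspace(lut._log_mua[0], lut._log_mua[-1], refine * (lut.mua_grid.size - 1) + 1)
    my = np.linspace(lut.musp_grid[0], lut.musp_grid[-1], refine * (lut.musp_grid.size - 1) + 1)
    gx, gy = np.meshgrid(lx, my, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    r = lut._interpolator("R_table")(pts).reshape(gx.shape)
    t = lut._interpolator("T_table")(pts).reshape(gx.shape)
    obj = (r - r_meas) ** 2 + (t - t_meas) ** 2
    return lx, my, obj


def _local_minima(obj: np.ndarray):
    """Indices of strict-or-plateau local minima of a 2-D surface (4-neighbour)."""
    padded = np.pad(obj, 1, constant_values=np.inf)
    c = padded[1:-1, 1:-1]
    is_min = (
        (c <= padded[:-2, 1:-1])
        & (c <= padded[2:, 1:-1])
        & (c <= padded[1:-1, :-2])
        & (c <= padded[1:-1, 2:])
    )
    return np.argwhere(is_min)


def invert_rt(
    r_meas: float,
    t_meas: float,
    lut: LookupTable,
    extrapolation_tol: float = 5e-3,
    ambiguity_tol: float = 1e-4,
) -> InversionResult:
    """Invert one measured (R, T) pair to (mu_a, mu_s').

    Returns the grid-interior minimizer of the Euclidean (R, T) misfit,
    refined by bounded least squares on the interpolant.  Flags:

    - ``extrapolated``: the measured pair is not attainable inside the grid
      (final residual above ``extrapolation_tol``, e.g. R + T > 1); the
      nearest-boundary estimate is still returned.
    - ``ambiguous``: a second local minimum matches the best residual within
      ``ambiguity_tol`` but lies more than one grid cell away.
    """
    r_meas = float(r_meas)
    t_meas = float(t_meas)
    lx, my, obj = _coarse_scan(lut, r_meas, t_meas)
    mins = _local_minima(obj)
    order = np.argsort(obj[mins[:, 0], mins[:, 1]])
    best = mins[order[0]]

    flags = []
    # ambiguity: competing minimum farther than one original grid cell
    dlx = lut._log_mua[1] - lut._log_mua[0]
    dmy = lut.musp_grid[1] - lut.musp_grid[0]
    best_res = math.sqrt(obj[best[0], best[1]])
    for k in order[1:]:
        cand = mins[k]
        res = math.sqrt(obj[cand[0], cand[1]])
        if res - best_res > ambiguity_tol:
            break
        far = (
            abs(lx[cand[0]] - lx[best[0]]) > dlx
            or abs(my[cand[1]] - my[best[1]]) > dmy
        )
        if far:
            flags.append("ambiguous")
            break

    x0 = np.array([lx[best[0]], my[best[1]]])
    lo = np.array([lut._log_mua[0], lut.musp_grid[0]])
    hi = np.array([lut._log_mua[-1], lut.musp_grid[-1]])

    def residuals(p):
        pt = np.array([[p[0], p[1]]])
        return np.array(
            [
                float(lut._interpolator("R_table")(pt)[0]) - r_meas,
                float(lut._interpolator("T_table")(pt)[0]) - t_meas,
            ]
        )

    sol = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-14, gtol=None)
    mu_a = 10.0 ** sol.x[0]
    mu_s_prime = float(sol.x[1])
    residual = float(np.linalg.norm(sol.fun))

    on_edge = np.any(np.isclose(sol.x, lo)) or np.any(np.isclose(sol.x, hi))
    if residual > extrapolation_tol and on_edge:
        flags.append("extrapolated")
    elif residual > extrapolation_tol:
        flags.append("poor_fit")
    return InversionResult(
        mu_a=float(mu_a),
        mu_s_prime=mu_s_prime,
        residual=residual,
        flags=tuple(flags),
    )


def invert_spectrum(rt, lut) -> "pandas.DataFrame":
    """Invert a whole R/T spectrum wavelength by wavelength.

    ``rt`` is an :class:`lumisphere.spectra.RTSpectrum`; ``lut`` is a single
    :class:`LookupTable` or a callable ``wavelength -> LookupTable`` (for
    thickness- or dispersion-matched tables).  Failures at single
    wavelengths are recorded in the ``flags`` column, never fatal.
    """
    import pandas as pd

    rows = []
    for k, wl in enumerate(np.asarray(rt.wavelength, dtype=float)):
        table = lut(wl) if callable(lut) else lut
        try:
            inv = invert_rt(float(rt.R[k]), float(rt.T[k]), table)
            rows.append(
                {
                    "wavelength_nm": wl,
                    "mu_a": inv.mu_a,
                    "mu_s_prime": inv.mu_s_prime,
                    "residual": inv.residual,
                    "flags": ";".join(inv.flags),
                }
            )
        except Exception as err:
            rows.append(
                {
                    "wavelength_nm": wl,
                    "mu_a": np.nan,
                    "mu_s_prime": np.nan,
                    "residual": np.nan,
                    "flags": f"error:{err}",
                }
            )
    return pd.DataFrame(rows)
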