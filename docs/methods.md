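# Methods

`lumisphere` estimates the absorption coefficient μa(λ) and reduced
scattering coefficient μs′(λ) of a homogeneous, photoluminescent turbid slab
from single-integrating-sphere measurements, and ships a synthetic
instrument that generates complete measurement sets for testing the
estimation chain end to end.  This note records the models, the tunable
parameters, the numerical choices, and what the synthetic data do and do not
demonstrate.

## Radiative transfer: photon-packet Monte Carlo (`mc_slab`)

The slab is parameterised by (μa, μs′, g, n, d); transport runs at
μs = μs′/(1−g) with explicit Henyey–Greenstein anisotropy, so the lookup
table can keep the (μa, μs′) axes the downstream analysis uses while the
transport itself stays physically anisotropic.  The scheme is the standard
weighted-packet one: step lengths s = −ln(1−u)/(μa+μs); a fraction μa/(μa+μs)
of the packet weight is deposited at each interaction; directions are
updated with the closed-form HG inverse CDF (the isotropic formula at g = 0,
where the inversion would divide by zero); azimuths are uniform, sampled by
rejection on the unit disk; unpolarized Fresnel reflection at the faces is
decided probabilistically, except the entry-face specular reflection, which
is split off deterministically and tallied into R (the sphere collects the
8° specular lobe — it lands on the wall, not back out of a port).

Loss accounting: packets exiting a face at radial distance beyond the
port radius (12.5 mm default), or crossing an optional lateral boundary,
are tallied as `L_lateral`, because the sphere exchanges light with the
sample only through the 25 mm port.  The default beam is a uniform 5 mm
diameter disk at 8° incidence; a pencil-beam/no-port mode exists for
comparison against plane-parallel reference solvers, which assume laterally
infinite slabs.

Russian roulette (threshold 1e−4, survival 1/10) terminates low weights
without bias.  The tallies R + T + A + L close to the launched weight to
1e−10 on every run because the roulette's zero-expectation weight
adjustments are booked into `A_total`; `A_total` is therefore "absorbed
weight plus roulette ledger", exactly absorption in expectation.

The RNG is an inline xorshift64* generator seeded through splitmix64 —
pure integer arithmetic, so a fixed seed reproduces tallies bit-identically
across platforms.  Standard errors for R and T come from the variance of
per-photon contributions.

Validation: closed-form limits (Fresnel multiple-reflection sum
R = 2r/(1+r) for a clear slab; Beer–Lambert ballistic transmission), a
similarity-relation check (g = 0.75 vs g = 0 at equal μs′), monotonicity
scans, and agreement with an independently written adding–doubling solver
(Gauss+Radau quadrature with a node at μ = 1, Legendre redistribution,
Fresnel boundary layers; in `tests/oracles.py`) to better than 0.005 in R
and T over the full parameter range of interest (observed ≤ 0.0011 at
2×10⁵ photons).

## Mie theory (`mie`)

Coefficients aₙ, bₙ by the logarithmic-derivative algorithm (downward
recursion for Dₙ, 15 orders above the Wiscombe truncation; upward
Riccati–Bessel recursion), real relative indices only.  Q_ext, Q_sca and
the asymmetry factor g come from the analytic moment sums of the
coefficients, not from quadrature of the phase function.  Size-distribution
averaging uses a ±3σ-truncated normal with 21 nodes and scattering-cross-
section weighting: g_ens = ⟨σ_sca g⟩/⟨σ_sca⟩, and
μs′ = N(⟨σ_sca⟩ − ⟨σ_sca g⟩) for number density N.

Defaults describe the scattering phantoms the package emulates: 800 nm
zirconia spheres (n = 2.15) in silicone (n = 1.41), both constant over
320–1000 nm and overridable by tabulated dispersion.  With these defaults
the unweighted spectral mean of g over 320–1000 nm computes to 0.65
(q_sca-weighted: 0.68); the result is insensitive to plausible literature
dispersion curves and to polydispersity up to σ = 240 nm (≤ 0.66 in all
variants we computed).  The downstream analysis nevertheless fixes
g = 0.75 per lookup table, the value the emulated instrument class uses for
these phantoms; the discrepancy presumably reflects unpublished measured
dispersion and size-distribution details of the real particles, and the
recovered (μa, μs′) are conditional on the chosen g either way.

Cross-checks: a second, independent route to aₙ, bₙ (direct Bohren–Huffman
formulas on scipy's spherical Bessel functions) agrees to 1e−7; the
classical worked example Q_ext(x = 5.213, m = 1.55) reproduces the printed
3.10543 to 4×10⁻⁴; results are stable to 1e−8 under five extra series terms.

## Integrating sphere (`sphere_model`)

First-order radiation-exchange model of the unbaffled single sphere
(150 mm diameter; 25 mm sample port; three 20 mm ports; barium-sulfate wall,
flat ρ_w = 0.97 default, tabulated spectra accepted).  On a sphere interior
every patch-to-patch view factor equals the target's area fraction, so the
average reflectance per bounce is ρ̄(Rs) = ρ_w(1−f) + Rs·f_s (f: open-port
area fraction, f_s: sample-port fraction, Rs: reflectance of whatever is in
the sample port) and the multiplier is M(Rs) = 1/(1−ρ̄).  This uniformity
also means port losses are booked on every flight including the first; a
discrete radiosity solve of the cavity (test oracle) reproduces the channel
model to machine precision, which is how we caught and removed an earlier
explicit "first-pass loss" factor that double-counted them.

The detector views a wall spot, so a diffuse source of power P at the
sample port is detected as ρ_w·P·M(Rs); a collimated beam that first hits
the wall as ρ_w²·P·M(Rs).  The seven channels are composed from these
elements; with the normalization beam recorded while the sample is mounted,
the sample-dependent gain M(R) cancels exactly in the two-beam ratios
(which is what that beam is for), leaving R_eff ≈ (R/ρ_w)(1 + df/(ρ_w M)),
T_eff ≈ T/ρ_w — the mirror's specular lobe takes one extra wall bounce
relative to the sample's diffuse light, and an unbaffled direct-view term
df (default: view-spot area fraction, 4×10⁻⁴) remains.  Building the
lookup table in this *effective* space is the analytic sphere correction;
inversion of measured two-beam values then needs no further algebra.

## Lookup table and inversion (`lut`)

Forward tables R(μa, μs′), T(μa, μs′) for fixed (g, n, d): one Monte Carlo
run per cell (per-cell seeds derived deterministically from the master seed
via `SeedSequence`), then the sphere mapping.  μa is log-spaced (the
measurable range spans ~2×10⁻³–2×10⁻¹ mm⁻¹, two decades), μs′ linear.  The
package default grid is 40×40 over [10⁻⁴, 1]×[0.1, 10] mm⁻¹; the test
suite and the worked examples use a reduced 20×20 grid over
[10⁻³, 0.3]×[1, 8] mm⁻¹ at 10⁵ photons/cell, which keeps a full build in
the minutes range while the round-trip recovery error stays well inside
the acceptance bounds (median ≈ 0.5% at 10⁶-photon forward simulations).

Inversion: cubic tensor interpolation on (log₁₀ μa, μs′) (bilinear when the
grid is too small), a coarse scan on a 6×-refined mesh to locate the global
misfit minimum, then bounded least squares on the interpolant.  Flags:
`extrapolated` when the measured pair is unattainable in-grid (residual
above 5×10⁻³ at a grid boundary, e.g. R + T > 1), `poor_fit` for interior
misfits above the same bound, `ambiguous` when a second local minimum
matches the best residual within 10⁻⁴ but lies more than one grid cell
away.  A Jacobian-determinant probe reports conditioning of the forward
map.  Serialization is a single versioned JSON document (grids, tables,
uncertainties, geometry, seeds) — text-based and diffable; the tables are
small enough that a binary container buys nothing.

## Spectral processing (`spectra`)

Scans hold one emission spectrum per excitation step (320–1000 nm, 10 nm
steps; acquisition times 100/50/100/200 ms by band; 10 averages; dark
spectra subtracted, negative residuals clipped with a logged count).  The
elastic peak is integrated over a ±5 nm window around the set-point
(trapezoid with interpolated window edges).  With the monochromator line at
7 nm FWHM, erf(5/σ√2) ≈ 90.7% of the line falls inside the window; the
missing tail fraction is identical across the seven channels and cancels
exactly in the two-beam ratios

    R = (SRB/SNB)·(CNBR/CRBR)·ρ_cal,   T = (STB/SNB)·(CNBT/CTBT).

Everything outside the window is photoluminescence; extraction masks the
elastic window rather than zeroing it, and the PL integral is defined as
total minus elastic so the partition is exact.

The deliberately wrong "polychromatic" mode emulates a broadband-lamp
instrument: all excitation rows are superposed into one spectrum per
channel (a lamp is the superposition of the monochromatic steps) and the
same window integration is applied per wavelength.  Elastic scattering and
PL are then indistinguishable, and R, T acquire an excess in the PL
emission band — the artifact this mode exists to reproduce.  For a
spectrally flat, PL-free sample the superposition identity is exact
(mono ≡ poly to machine precision); for smoothly varying spectra
second-order line-leak terms of order 10⁻⁴ relative remain, far below the
shot-noise level at which the artifact comparisons are made.

## Synthetic phantoms (`synthetic`)

The generator emulates silicone slabs loaded with zirconia scatterers and
Rhodamine 6G: μs′(λ) = μs′(600)·(λ/600)⁻ᵇ with b = 1 by default and
μs′(600) ∈ {2, 4, 6} mm⁻¹; μa(λ) = flat baseline 2×10⁻³ mm⁻¹ plus a
Gaussian dye band at 525 nm (FWHM 35 nm — only the peak position of the
real dye is fixed by the emulated experiment; the shape is a fixture
choice) with 0.03 mm⁻¹ peak absorption per wt%, linear in concentration
(batch concentrations 2.66/4/5.33/6.66 wt% plus a dye-free c0); thicknesses
1/2/4 mm, n = 1.41.

Photoluminescence is injected at the *signal* level: a Gaussian emission
band at 548 nm (FWHM 30 nm) whose amplitude is pl_yield × the beam fraction
absorbed by the dye (Beer along the thickness, dye band only), split evenly
between reflection and transmission channels and entering the sphere with
the same gain factors as the sample's elastic light.  pl_yield defaults to
0.1 — an *effective* detected-emission fraction (quantum yield folded with
collection geometry), a free fixture parameter since the emulated
instrument reports none.  PL photons are not transported through the Monte
Carlo; the broadband artifact is an analysis bookkeeping error, and
reproducing its mechanism requires only that PL light reach the detector
channels, not that its spatial migration be modelled.  Consequently the
synthetic data cannot validate reabsorption/inner-filter effects, PL
spatial profiles, or quantum-yield recovery — only the separation and
contamination bookkeeping of the two analysis modes.

Counts: expected rate × acquisition time × averages, Poisson-sampled per
bin when shot noise is on, plus a flat dark rate (50 counts/s default)
whose known rate is subtracted in preprocessing.  The lamp curve is a
smooth visible-peaked profile scaled so that the two-beam R carries ~0.5%
relative shot noise at mid-band under the default acquisition schedule —
the photometric precision class the staged acquisition times aim at.  All
randomness flows from one seeded generator per dataset.

In the noise-free limit the generated channels satisfy the two-beam
equation exactly (the pipeline returns the forward engine's effective R, T
to 1e−12 relative), so end-to-end tests separate pipeline bookkeeping
errors from Monte Carlo noise cleanly.

## Statistical conventions in the end-to-end tests

The artifact and linearity studies run 6–12 noise realizations per
condition at 33 excitation wavelengths.  Per-wavelength standard errors are
variance-smoothed over three adjacent wavelengths to stabilise small-sample
estimates.  Detection claims ("the artifact exceeds noise") use 3σ;
"consistent with truth/each other" claims are asserted at 4σ, a
multiplicity-corrected bound for the ~100 simultaneous per-wavelength
comparisons (Šidák z ≈ 3.5 at family α = 0.05, padded for the smoothed-SE
approximation).  The artifact's localisation is asserted against the
support of the injected emission band (|λ − 548| ≤ 3σ_PL + window/2), the
generator-defined meaning of "only in the PL band".

## Known limitations

- Two observables (R, T) cannot determine g or n; both are fixed inputs per
  table, and errors in them bias (μa, μs′) systematically.
- The sphere model is first-order (uniform Lambertian exchange): no
  specular wall behaviour, no coating fluorescence, no non-uniform
  illumination corrections beyond the direct-view term.
- The fixed-g tables inherit whatever mismatch exists between the assumed
  g = 0.75 and the Mie-computed ensemble asymmetry of the actual particles
  (see the Mie section above).
- Absorbing (complex-index) particles, layered samples, polarization, and
  time/space-resolved quantities are out of scope.
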