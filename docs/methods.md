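# Methods

This note documents the models inside `lampspec`: what is computed, the
parameter values and why, the numerical choices, and what the synthetic test
fixtures do and do not establish about real lamps.

## Spectral grid and quadrature

All curves live on a canonical 1 nm grid spanning 380–730 nm (351 samples).
The band limits follow the spectral extent of the photosynthesis action
spectrum, the narrowest of the biological weights; water-vapor absorption,
which matters only beyond ~755 nm, is therefore irrelevant and omitted.
Inputs are linearly interpolated onto the grid; outside an input's sampled
support the value is zero (edge-hold extrapolation would invent power a lamp
does not emit). Inputs covering less than half the band are rejected.
Integrals are trapezoidal. The 1 nm step is finer than every bundled
tabulation (5–10 nm), and the suite verifies that band-interior smooth
features keep their integral to 1e-6 relative and that 5 nm-sampled features
wider than ~5 nm keep theirs to 1%.

## Constant-lumen normalization

Lamps are compared at equal luminous output: each SPD is divided by its
photopic-weighted integral, making that integral exactly 1. The photopic
curve used here is the Judd–Vos corrected V(λ) (the correction raises the
blue lobe below 460 nm, where the 1924 curve is known to be too low). The
normalization constant is 1 rather than a physical lumen figure: every
downstream index is a ratio of two equally normalized spectra, so any fixed
constant cancels, and no radiometric calibration is needed anywhere.

For translating the photopic-vision luminance threshold (0.6 cd·m⁻²) into
illuminance the package provides the Lambertian relation E = πL/ρ: ~23.6 lux
over summer asphalt (ρ = 0.08), ~1.9 lux over snow (ρ = 0.98).

## The three indices

Each index is the ratio of the action-weighted constant-lumen lamp spectrum
to the equally processed CIE D65 reference over 380–730 nm. D65 therefore
scores exactly 1 on all indices; typical lamps fall in [0, ~1], but values
above 1 are possible and are not clipped — a source richer than daylight in
the weight's band (e.g. a red-heavy incandescent lamp against the red peak of
the photosynthesis action spectrum) legitimately exceeds 1.

Weights:

- **Melatonin suppression action spectrum (MSAS).** Evaluated from a
  two-component asymmetric-lognormal (Fraser–Suzuki) model,
  f(λ) = Σᵢ hᵢ·exp(−ln2·[ln(1 + 2bᵢ(λ−λᵢ)/wᵢ)/bᵢ]²), with
  (h, λ, w, b) = (1.017, 444.7 nm, 111.9 nm, −0.5785) and
  (0.5239, 509.3 nm, 30.18 nm, 0.6666). The broad first component carries
  the blue peak at 444.7 nm; the narrow second component produces the slope
  breakdown near 507 nm. The fitted form is extrapolated below 425 nm, where
  the underlying human response data end; the functional form is isolated in
  one function (`weights.asymmetric_lognormal`) so it can be revised without
  touching anything else.
- **Photosynthesis action spectrum (PAS).** A generic, species-averaged
  curve with the canonical blue (~450 nm) and red (~660 nm) peaks, green
  minimum, and steep far-red cutoff. The bundled tabulation is a
  hand-constructed synthetic stand-in with exactly those features (see the
  file header); it is *not* a standards-body transcription, so absolute IPI
  values for measured lamps depend on this choice even though all
  qualitative behaviors do not. Species-specific pigment spectra
  (chlorophyll d, carotenes, …) are deliberately out of scope.
- **Scotopic sensitivity.** CIE 1951 V′(λ), peak 507 nm, as the proxy for
  star-visibility and dark-adapted-vision intrusion.

## Colorimetry

Chromaticity uses the unmodified CIE 1931 2° color-matching functions — a
deliberately separate tabulation from the Judd–Vos photopic curve used for
normalization, since the two serve different standards. CCT is McCamy's
cubic in n = (x−0.3320)/(0.1858−y), applied unconditionally; results outside
2000–12500 K are flagged advisory rather than rejected (sodium lamps
legitimately report ~1700–1800 K). CRI follows the CIE test-color method
(CIE 1960 UCS, von Kries adaptation, U\*V\*W\* color differences,
Ra = mean(100 − 4.6·ΔE) over eight samples) with two documented deviations:
the eight test-color reflectances are synthetic smooth Gaussian-band
stand-ins spanning the hue circle (the standard sample tabulations are not
bundled), and the daylight-phase reference for CCT ≥ 5000 K is represented
by the bundled D65 tabulation (exact at 6504 K) instead of the
reconstructed CIE daylight model. Both deviations preserve the structural
properties the suite relies on — a source equal to its reference scores
Ra = 100 exactly, and quasi-monochromatic sources score strongly negative —
but individual Ra values for real lamps depend on the sample set.

## Atmospheric transfer

Single-scattering radiative transfer in a plane-parallel stratified
atmosphere produces a spectral transfer function T(λ) per (distance, sky
condition). Components:

- **Molecular atmosphere.** Ground-level Rayleigh optical thickness from the
  standard dispersion formula τ_R = 0.008569·λ⁻⁴(1+0.0113λ⁻²+0.00013λ⁻⁴)
  (λ in µm; ~0.097 at 550 nm), exponential profile with scale height 8 km,
  conservative scattering with phase function (3/16π)(1+cos²θ).
- **Aerosols.** Ångström power law τ_a = 0.2·(500 nm/λ)^1.0 — with this
  reference wavelength the molecular column exceeds the aerosol column by
  ~44% at 400 nm and falls ~3× below it at 650 nm, the clear-urban regime
  the model targets. Exponential profile with scale height 1.2 km (a typical
  boundary-layer value; the choice matters little because index ratios
  compare two spectra through the same atmosphere), single-scattering albedo
  0.9, Henyey–Greenstein phase function with g = 0.8 standing in for the
  full Mie computation (standard practice; no particle-size distribution is
  needed).
- **Mixture.** At each altitude the phase functions are combined with
  weights proportional to the local *scattering* coefficients (molecular
  conservative, aerosol ×ω_a), so the mixture integrates to 1 over the
  sphere everywhere.
- **Geometry.** Source at the origin emitting isotropically into the upward
  hemisphere (a cosⁿ pattern is available; smooth gray patterns cancel in
  index ratios). The observer at ground distance d receives, by default, the
  radiance integrated over the sky dome with solid-angle weighting, capped
  at 80° zenith angle — the validity limit of the secant (plane-parallel,
  refraction-free) slant-path treatment used throughout. The dome view
  matters: at large distances the received light is dominated by
  low-elevation, long-path beams scattered in the strong aerosol forward
  lobe, which a single zenith ray misses entirely. A zenith-ray mode (cheap)
  and a cosine-weighted irradiance mode are also provided. Direct
  source-to-observer light is always excluded (obstacles are assumed to
  block the sightline), and the lowest scattering altitude is 0.05 km,
  standing in for that obstacle height and regularizing the colocated
  geometry at d = 0.
- **Clear sky.** Altitude integration to 50 km with 100 log-spaced steps per
  view ray; doubling the step count changes T(λ) by < 0.5% everywhere
  (< 0.21% measured at the worst case d = 0).
- **Cloudy sky.** The scattering column is capped at the cloud base
  (default 1.5 km, a stratus overcast) and a cloud-reflection term is added:
  each view ray's intersection with the cloud underside is illuminated
  directly by the source, reflects Lambertianly with reflectance 0.46, and
  is attenuated to the observer. This single-bounce term replaces the full
  overcast radiance computation; cloud–ground inter-reflections and
  in-cloud multiple scattering are out of scope.

Slant transmissions use the closed-form vertical optical thickness scaled by
the path secant — exact for straight rays in a plane-parallel atmosphere; a
general numerical path-transmission routine is provided and agrees with the
closed form to 1e-4.

### Scattered indices

The transfer is applied to the constant-lumen lamp and reference spectra and
the weighted ratio is taken directly — the comparison is between sources of
equal *emitted* lumen seen through the same sky. Under this convention the
scattered indices drop below their direct values near the source (Rayleigh
backscatter enriches the blue, inflating the D65 denominator for every
redder-than-daylight lamp) and converge back toward the direct values with
distance as extinction removes the excess blue; a spectrum with a strong
deep-violet line (the metal-halide archetype's 405 nm line) is the
exception, with scattered MSI above direct at short range. An alternative
convention comparing at equal *received* lumen (renormalizing the
transferred spectra) is available via `equal_received_lumen=True`; it makes
the photopic-weighted index exactly 1 through any atmosphere — the exact
end-to-end consistency check used in the test suite — at the cost of
distorting the large-distance behavior of the emitted-lumen comparison.

### Known limitation: overcast distance profile

Under the cloudy sky this single-scatter + single-bounce model produces
index-vs-distance curves that rise monotonically toward (and past) the
direct values: the red cloud-bounce share of the received light grows
monotonically with distance. It does not reproduce an interior maximum a few
kilometres from the source followed by a decline; producing that shape
evidently requires the full overcast radiance term (diffuse cloud–ground
inter-reflection) that this model deliberately omits. The corresponding
acceptance test is left failing rather than weakened, and the clear-sky
behaviors are unaffected.

## Synthetic fixtures

`lampspec.fixtures` generates deterministic, closed-form spectra: Planckian
blackbodies (1000–20000 K), Gaussian line spectra with specified
center/FWHM/area, and seven lamp archetypes (LPS sodium doublet, HPS
broadened sodium + lines, metal halide continuum + lines including a strong
405 nm line, cool/warm phosphor-converted white LEDs, broad amber LED,
2600 K incandescent). Archetypes are caricatures tuned only for construction
fidelity (nominal CCT class, characteristic features), *not* calibrated to
measured commercial spectra. Consequently the suite asserts orderings, signs
and qualitative distance behavior — never published per-lamp decimals — and
passing tests demonstrate that the pipeline ranks and transforms technology
classes correctly, not that it reproduces any specific product's indices.
Measured spectra in two-column text can be run through the identical
pipeline via `read_spd`.

## Problem sizes

The default test and acceptance runs use the 351-point grid, 100 altitude
steps per ray, a 12×12 dome quadrature, and distance sweeps of 31 points
(0–30 km at 1 km); a full 7-archetype clear+cloudy sweep completes in well
under a minute on one core. These sizes are converged for the quantities
reported (step-doubling changes transfers by < 0.5%).
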