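# lampspec

Spectral impact indices for artificial light at night.

Outdoor lighting affects far more than visibility: blue-rich light suppresses
nocturnal melatonin production in humans, drives photosynthesis in plants at
night, and scatters efficiently in the atmosphere, brightening the night sky
and erasing stars. How strongly a given lamp does each of these depends on the
*shape* of its spectral power distribution (SPD), not on its brightness alone.
`lampspec` computes three dimensionless indices that isolate that spectral
shape, for lighting engineers, dark-sky planners and environmental
researchers comparing lamp technologies:

- **MSI** — Melatonin Suppression Index,
- **IPI** — Induced Photosynthesis Index,
- **SLI** — Star Light Index (scotopic / dark-adapted vision intrusion).

## The indices

Every lamp SPD `S(λ)` is first normalized to **constant lumen output**,

    S_cl(λ) = S(λ) / ∫ S(λ) V(λ) dλ ,

with `V(λ)` the (Judd–Vos corrected) photopic luminous efficiency function,
so that all lamps are compared at equal perceived brightness. Each index is
then the ratio of the action-weighted lamp spectrum to the equally processed
CIE D65 daylight reference, over 380–730 nm:

    MSI = ∫ S_cl(λ) M(λ) dλ / ∫ D65_cl(λ) M(λ) dλ

and likewise IPI with the generic photosynthesis action spectrum `P(λ)`
(blue peak ≈450 nm, red peak ≈660 nm) and SLI with the CIE 1951 scotopic
sensitivity `V′(λ)`. `M(λ)` is the melatonin suppression action spectrum,
evaluated from a two-component asymmetric-lognormal fit peaking near 445 nm.
Daylight (D65) scores exactly 1.000 on all three indices by construction; an
HPS street lamp scores MSI ≈ 0.1 — a tenth of daylight's melatonin impact
per lumen. Multiplying an index by the delivered illuminance (lux) gives a
global impact figure for an actual installation.

The package also reports the standard colorimetric descriptors per lamp:
CIE 1931 chromaticity (x, y), correlated color temperature (McCamy's
approximation) and the general color rendering index Ra.

## Skyglow: indices at a distance

When the lamp is seen only indirectly — its light scattered back down by the
atmosphere — the indices transform with distance. `lampspec` implements a
single-scattering radiative transfer model (plane-parallel atmosphere,
Rayleigh molecular scattering + Henyey–Greenstein aerosol scattering with
τ_a = 0.2 at 500 nm, Ångström exponent 1.0, g = 0.8, ω_a = 0.9) that yields a
spectral transfer function T(λ) for any lamp–observer ground distance, under
clear skies or under an overcast cloud deck (Lambertian cloud-base
reflection, reflectance 0.46). The same T(λ) is applied to the lamp and to
the D65 reference, so the scattered indices remain fair shape comparisons.
Near the source the sky scatters blue preferentially (scattered light is
*bluer* than the lamp); far away, accumulated extinction removes blue and the
scattered indices return toward their direct values.

## Worked example

```python
from lampspec.io import RunConfig, run_pipeline, results_frame

cfg = RunConfig(archetypes=["hps", "led_white_5000", "lps"], sky="direct")
print(results_frame(run_pipeline(cfg)).to_string(index=False))
```

```
          lamp    sky distance_km      x      y    cct   cri   msi   ipi   sli cct_advisory
           hps direct        None 0.5348 0.4386 2083.0   2.9 0.101 0.523 0.240          NaN
led_white_5000 direct        None 0.3430 0.3460 5069.0  66.9 0.619 0.710 0.733          NaN
           lps direct        None 0.5700 0.4293 1799.0 -56.9 0.018 0.460 0.093         True
```

Reading the rows: the cool-white LED archetype suppresses melatonin about six
times more strongly per lumen than high-pressure sodium (MSI 0.619 vs 0.101)
and brightens the scotopic night sky three times more (SLI 0.733 vs 0.240);
low-pressure sodium is almost invisible to the circadian system (MSI 0.018).
The low-pressure sodium row carries a `cct_advisory` flag: a CCT of ~1800 K
from a quasi-monochromatic source is outside the nominal validity of the
McCamy approximation, and its strongly negative CRI is expected for a lamp
that renders every surface orange. These archetypes are synthetic caricatures
of the technology classes — orderings and signs are meaningful, individual
decimals are not calibrated to any commercial product.

The same computation through 5 and 30 km of clear atmosphere:

```
lamp   sky  distance_km      x      y    cct  cri   msi   ipi   sli
 hps clear          0.0 0.5095 0.4373 2303.0 10.4 0.079 0.363 0.189
 hps clear          5.0 0.5274 0.4393 2150.0  5.0 0.093 0.479 0.222
 hps clear         30.0 0.5324 0.4401 2113.0  3.4 0.103 0.528 0.237
```

Close to the source the blue-enriched scattered light dilutes the orange
lamp's relative impact (MSI drops from 0.101 direct to 0.079); with distance
the indices climb back toward the direct values. For scattered rows the
colorimetric descriptors describe the transferred spectrum (the skyglow's
color), not the lamp's.

Equivalent command line:

```
lampspec indices --archetype hps --archetype lps --sky clear --distances 0:30:5 --out results.csv
lampspec synth --archetype metal_halide --out mh.txt
lampspec transfer --distance 10 --sky cloudy --out transfer.txt
```

Measured lamp spectra are read from plain two-column text
(wavelength-nm / relative power, `#` comments, comma or whitespace
separated) via `--spd file.txt` or `lampspec.read_spd`.

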