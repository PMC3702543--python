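"""Biological and visual weighting functions, and the daylight reference SPD.

Four weights drive the impact indices:

* ``msas`` -- melatonin suppression action spectrum, evaluated from a
  two-component asymmetric-lognormal fit to the published human
  melatonin-suppression response (peak in the blue near 445 nm).
* ``pas`` -- generic species-averaged photosynthesis action spectrum
  (blue peak ~450 nm, red peak ~660 nm).
* ``scotopic`` -- CIE 1951 rod sensitivity V'(lambda), peak 507 nm, used as
  the proxy for star-visibility / dark-adapted vision impact.
* ``photopic`` -- Judd-Vos corrected cone sensitivity V(lambda), peak 555 nm,
  used only for the constant-lumen normalization.

The reference spectrum against which every lamp is compared is the CIE D65
daylight illuminant: biological action spectra evolved under daylight, so a
lamp's index is its weighted output relative to equally bright daylight.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .core import GRID, SpectralCurve, canonicalize, normalize_constant_lumen

WEIGHT_NAMES = ("msas", "pas", "scotopic", "photopic")

_DATA_FILES = {
    "pas": "pas_generic_synthetic.txt",
    "scotopic": "scotopic_cie1951.txt",
    "photopic": "photopic_judd_vos.txt",
    "d65": "cie_d65.txt",
    "cmf": "cie_1931_cmf.txt",
}


def load_tabulation(name: str) -> np.ndarray:
    """Load a bundled whitespace-separated tabulation as a 2-D array."""
    fname = _DATA_FILES[name]
    with resources.files("lampspec.data").joinpath(fname).open("r") as fh:
        rows = [
            [float(tok) for tok in line.split()]
            for line in fh
            if line.strip() and not line.lstrip().startswith("#")
        ]
    return np.asarray(rows, dtype=float)


@dataclass(frozen=True)
class LognormalComponent:
    """One asymmetric-lognormal peak: height h, center lam0 (nm), width w (nm),
    asymmetry b (dimensionless; b -> 0 recovers a Gaussian of FWHM w)."""

    h: float
    lam0: float
    w: float
    b: float

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("component height h must be >= 0")
        if self.w <= 0:
            raise ValueError("component width w must be > 0")
        if not 380 <= self.lam0 <= 730:
            raise ValueError("component center must lie in 380-730 nm")


@dataclass(frozen=True)
class MsasModel:
    """Two-component asymmetric-lognormal parameterization of the melatonin
    suppression action spectrum."""

    components: tuple[LognormalComponent, ...]


#: Fitted parameters of the two lognormal components of the melatonin
#: suppression action spectrum (broad blue peak + narrow green shoulder).
MSAS_MODEL = MsasModel(
    components=(
        LognormalComponent(h=1.017, lam0=444.7, w=111.9, b=-0.5785),
        LognormalComponent(h=0.5239, lam0=509.3, w=30.18, b=0.6666),
    )
)

_LN2 = float(np.log(2.0))


def asymmetric_lognormal(lam, h: float, lam0: float, w: float, b: float):
    """Asymmetric lognormal peak function (Fraser-Suzuki form).

    f(lam) = h * exp(-ln2 * [ln(1 + 2 b (lam - lam0) / w) / b]^2)

    for 1 + 2 b (lam - lam0)/w > 0, and 0 beyond that point (the function and
    all its derivatives tend smoothly to zero there).  The sign of ``b`` sets
    which flank is stretched; |b| -> 0 recovers a Gaussian of FWHM ``w``.

    This functional form is the package's reading of the published
    two-lognormal fit: it is the standard asymmetric-lognormal peak used for
    skewed spectral bands, and with the tabulated parameters it reproduces the
    documented curve shape (single blue maximum near 445 nm, shoulder
    breakpoint near 507 nm, negligible response in the red).  It is isolated
    here so it can be corrected in one place if needed.
    """
    if w <= 0:
        raise ValueError("width w must be > 0")
    lam = np.asarray(lam, dtype=float)
    if abs(b) < 1e-9:
        out = h * np.exp(-_LN2 * (2.0 * (lam - lam0) / w) ** 2)
    else:
        arg = 1.0 + 2.0 * b * (lam - lam0) / w
        out = np.zeros_like(lam)
        ok = arg > 0
        out[ok] = h * np.exp(-_LN2 * (np.log(arg[ok]) / b) ** 2)
    return out


def evaluate_msas(lam, model: MsasModel = MSAS_MODEL):
    """Melatonin suppression action spectrum at wavelength(s) ``lam`` (nm)."""
    lam = np.asarray(lam, dtype=float)
    total = np.zeros_like(lam)
    for c in model.components:
        total = total + asymmetric_lognormal(lam, c.h, c.lam0, c.w, c.b)
    return total if total.ndim else float(total)


@lru_cache(maxsize=None)
def get_weight(name: str) -> SpectralCurve:
    """Return one of the four weighting functions on the canonical grid."""
    if name not in WEIGHT_NAMES:
        raise ValueError(f"unknown weight {name!r}; valid names: {', '.join(WEIGHT_NAMES)}")
    if name == "msas":
        return SpectralCurve(GRID.copy(), evaluate_msas(GRID), kind="sensitivity")
    table = load_tabulation(name)
    curve = SpectralCurve(table[:, 0], table[:, 1], kind="sensitivity")
    return canonicalize(curve)


def peak_normalized(curve: SpectralCurve) -> SpectralCurve:
    """Scale a curve so its maximum is exactly 1 (display convenience only;
    never used inside index ratios, which are scale invariant anyway)."""
    peak = float(curve.values.max())
    if peak <= 0:
        raise ValueError("cannot peak-normalize an all-zero curve")
    return curve.scaled(1.0 / peak)


@lru_cache(maxsize=None)
def get_reference_spd(constant_lumen: bool = False) -> SpectralCurve:
    """The CIE D65 daylight reference SPD on the canonical grid.

    With ``constant_lumen=True`` the curve is normalized so its
    photopic-weighted integral is 1, ready for index denominators.
    """
    table = load_tabulation("d65")
    curve = canonicalize(SpectralCurve(table[:, 0], table[:, 1], kind="spd"))
    if constant_lumen:
        curve = normalize_constant_lumen(curve)
    return curve
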