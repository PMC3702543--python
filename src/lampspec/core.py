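"""Wavelength-grid spectral curves and the photometric primitives built on them.

Every quantity in this package lives on a canonical 1 nm wavelength grid
spanning 380-730 nm.  The band limits are set by the spectral extent of the
photosynthesis action spectrum, which is the narrowest of the biological
weighting functions used by the impact indices; the 1 nm step is finer than
any of the bundled tabulations, so resampling error is negligible for real
lamp spectra.  Integrals are trapezoidal on that grid.

All spectra are relative: the constant-lumen normalization fixes the
photopic-weighted integral of an SPD to exactly 1, so every downstream index
is a ratio and the absolute radiometric scale never matters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical wavelength grid, nm (inclusive endpoints, 1 nm step, 351 samples).
GRID_MIN = 380.0
GRID_MAX = 730.0
GRID = np.arange(GRID_MIN, GRID_MAX + 0.5, 1.0)

_VALID_KINDS = ("spd", "sensitivity", "transfer")


class CoverageError(ValueError):
    """Input spectrum does not cover enough of the 380-730 nm band."""


@dataclass(frozen=True)
class SpectralCurve:
    """A sampled spectral quantity: SPD, sensitivity weight, or transfer weight.

    ``wavelengths`` must be strictly increasing and ``values`` non-negative;
    readers are responsible for clipping small negative spectrometer noise
    before construction (see :func:`lampspec.io.read_spd`).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "spd"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"kind must be one of {_VALID_KINDS}, got {self.kind!r}")
        if wl.ndim != 1 or wl.shape != vals.shape:
            raise ValueError("wavelengths and values must be 1-D arrays of equal length")
        if wl.size < 2:
            raise ValueError("a spectral curve needs at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise ValueError("values must be finite")
        if np.any(vals < 0):
            raise ValueError("values must be non-negative (clip noise before construction)")

    @property
    def is_canonical(self) -> bool:
        return self.wavelengths.size == GRID.size and bool(
            np.array_equal(self.wavelengths, GRID)
        )

    def value_at(self, wavelength: float) -> float:
        """Linearly interpolated value; zero outside the sampled support."""
        return float(np.interp(wavelength, self.wavelengths, self.values, left=0.0, right=0.0))

    def scaled(self, factor: float) -> "SpectralCurve":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return SpectralCurve(self.wavelengths, self.values * factor, self.kind)


@dataclass(frozen=True)
class PhotometricScalars:
    """Luminance (cd/m^2), surface reflectance, and the implied illuminance (lux)."""

    luminance: float
    reflectance: float
    illuminance: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.reflectance <= 1:
            raise ValueError("reflectance must lie in (0, 1]")
        if self.luminance < 0:
            raise ValueError("luminance must be >= 0")
        object.__setattr__(
            self,
            "illuminance",
            illuminance_from_luminance(self.luminance, self.reflectance),
        )


def canonicalize(curve: SpectralCurve) -> SpectralCurve:
    """Resample a curve onto the canonical 1 nm, 380-730 nm grid.

    Linear interpolation between samples; outside the input's sampled support
    the value is zero (lamps emit nothing where nothing was measured; edge-hold
    extrapolation would invent power).  A curve already on the canonical grid
    is returned unchanged.

    Raises
    ------
    CoverageError
        If the input covers less than half of the 380-730 nm band.
    """
    if curve.is_canonical:
        return curve
    lo = max(float(curve.wavelengths[0]), GRID_MIN)
    hi = min(float(curve.wavelengths[-1]), GRID_MAX)
    overlap = hi - lo
    if overlap < 0.5 * (GRID_MAX - GRID_MIN):
        raise CoverageError(
            f"input covers only {max(overlap, 0):.0f} nm of the {GRID_MAX - GRID_MIN:.0f} nm "
            f"band {GRID_MIN:.0f}-{GRID_MAX:.0f} nm (need at least 50%)"
        )
    vals = np.interp(GRID, curve.wavelengths, curve.values, left=0.0, right=0.0)
    if float(curve.wavelengths[0]) > GRID_MIN or float(curve.wavelengths[-1]) < GRID_MAX:
        logger.debug(
            "curve support %.0f-%.0f nm narrower than canonical band; zero-extended",
            curve.wavelengths[0],
            curve.wavelengths[-1],
        )
    return SpectralCurve(GRID.copy(), vals, curve.kind)


def _require_canonical(curve: SpectralCurve, name: str) -> None:
    if not curve.is_canonical:
        raise ValueError(f"{name} must be canonicalized first (call canonicalize)")


def weighted_integral(curve: SpectralCurve, weight: SpectralCurve) -> float:
    """Trapezoidal integral of ``curve * weight`` over 380-730 nm."""
    _require_canonical(curve, "curve")
    _require_canonical(weight, "weight")
    return float(np.trapezoid(curve.values * weight.values, GRID))


def multiply(curve: SpectralCurve, other: SpectralCurve, kind: str = "spd") -> SpectralCurve:
    """Pointwise product of two canonical curves (e.g. SPD x transfer)."""
    _require_canonical(curve, "curve")
    _require_canonical(other, "other")
    return SpectralCurve(GRID.copy(), curve.values * other.values, kind)


def normalize_constant_lumen(
    spd: SpectralCurve, photopic: SpectralCurve | None = None
) -> SpectralCurve:
    """Rescale an SPD so its photopic-weighted integral is exactly 1.

    This is the constant-lumen normalization: all lamps are compared at equal
    luminous output.  The normalization constant is 1 rather than a lumen
    figure in physical units -- the impact indices are ratios of two equally
    normalized spectra, so any fixed constant cancels.
    """
    if photopic is None:
        from .weights import get_weight

        photopic = get_weight("photopic")
    spd = canonicalize(spd)
    lum = weighted_integral(spd, photopic)
    if lum <= 0:
        raise ValueError(
            "SPD has zero photopic content (no power inside the visual sensitivity band); "
            "constant-lumen normalization is undefined"
        )
    return SpectralCurve(spd.wavelengths, spd.values / lum, spd.kind)


def illuminance_from_luminance(luminance: float, reflectance: float) -> float:
    """Illuminance (lux) that produces a given luminance off a Lambertian surface.

    For an ideal diffuse reflector, E = pi * L / rho.  With the photopic-vision
    luminance threshold of 0.6 cd/m^2, asphalt (rho = 0.08) needs about 23 lux
    while snow (rho = 0.98) needs about 2 lux.
    """
    if reflectance <= 0 or reflectance > 1:
        raise ValueError("reflectance must lie in (0, 1]")
    if luminance < 0:
        raise ValueError("luminance must be >= 0")
    return math.pi * luminance / reflectance
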