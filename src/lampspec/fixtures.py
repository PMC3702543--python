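"""Deterministic synthetic lamp spectra: blackbodies, line spectra, archetypes.

The archetypes mimic the broad classes of outdoor lighting technology --
quasi-monochromatic sodium discharge, line-plus-continuum metal halide,
blue-pump-plus-phosphor white LEDs, broad amber LEDs, thermal sources.  They
are caricatures built from Gaussian lines and Planckian continua, NOT
calibrated reproductions of any measured commercial spectrum: comparisons
against published per-lamp index values are meaningful in ordering and sign
only.  All fixtures are closed-form and bit-for-bit reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .color import planck_spd
from .core import GRID, SpectralCurve

ARCHETYPE_NAMES = (
    "lps",
    "hps",
    "metal_halide",
    "led_white_5000",
    "led_white_2700",
    "amber_led",
    "incandescent",
)

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class LineSpec:
    """One Gaussian emission line: center (nm), FWHM (nm), integrated power."""

    center: float
    fwhm: float
    power: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.power < 0:
            raise ValueError("power must be >= 0")
        if not 360 <= self.center <= 750:
            raise ValueError("line center must lie in 360-750 nm")


def blackbody_spd(temperature: float) -> SpectralCurve:
    """Planckian relative SPD on the canonical grid, 1000-20000 K."""
    if not 1000 <= temperature <= 20000:
        raise ValueError("temperature must lie in 1000-20000 K")
    return planck_spd(temperature)


def line_spectrum(lines: list[LineSpec], continuum: float = 0.0) -> SpectralCurve:
    """Sum of Gaussian lines (area = power) over a flat continuum."""
    if not lines and continuum <= 0:
        raise ValueError("need at least one line or a nonzero continuum")
    vals = np.full_like(GRID, float(continuum))
    for line in lines:
        sigma = line.fwhm * _FWHM_TO_SIGMA
        vals = vals + line.power / (sigma * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((GRID - line.center) / sigma) ** 2
        )
    return SpectralCurve(GRID.copy(), vals, kind="spd")


def _gaussian(center: float, fwhm: float, area: float) -> np.ndarray:
    sigma = fwhm * _FWHM_TO_SIGMA
    return area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
        -0.5 * ((GRID - center) / sigma) ** 2
    )


def lamp_archetype(name: str) -> SpectralCurve:
    """A deterministic synthetic SPD for one lamp technology class.

    lps
        The 589.0/589.6 nm sodium doublet, nothing else.
    hps
        Pressure-broadened sodium resonance plus the weaker discharge lines
        and a faint continuum.
    metal_halide
        Cool-white continuum with superimposed mercury/halide lines,
        including a strong deep-violet 405 nm line.
    led_white_5000 / led_white_2700
        Narrow 450 nm pump plus a broad phosphor band; the warm variant has a
        weaker pump and a redder, stronger phosphor hump.
    amber_led
        Single broad phosphor-converted band near 600 nm.
    incandescent
        2600 K Planckian continuum.
    """
    if name == "lps":
        return line_spectrum(
            [LineSpec(589.0, 2.0, 2.0), LineSpec(589.6, 2.0, 1.0)]
        )
    if name == "hps":
        lines = [
            LineSpec(589.2, 30.0, 10.0),
            LineSpec(569.0, 6.0, 1.5),
            LineSpec(616.0, 8.0, 2.0),
            LineSpec(498.0, 5.0, 0.5),
            LineSpec(515.0, 5.0, 0.4),
        ]
        return line_spectrum(lines, continuum=0.004)
    if name == "metal_halide":
        # Continuum and line system carry comparable power, as in real
        # quartz metal-halide discharges; the 405 nm line is deliberately
        # prominent (deep-violet mercury/halide emission).
        cont = 0.9 * planck_spd(3400.0).values  # warm continuum; lines pull the
        # composite chromaticity up to a cool-white ~4500 K
        lines = (
            _gaussian(405.0, 6.0, 22.0)
            + _gaussian(436.0, 6.0, 24.0)
            + _gaussian(546.0, 6.0, 22.0)
            + _gaussian(578.0, 8.0, 20.0)
        )
        return SpectralCurve(GRID.copy(), cont + lines, kind="spd")
    if name == "led_white_5000":
        vals = _gaussian(450.0, 22.0, 1.0) + _gaussian(572.0, 120.0, 3.4)
        return SpectralCurve(GRID.copy(), vals, kind="spd")
    if name == "led_white_2700":
        vals = _gaussian(450.0, 22.0, 0.4) + _gaussian(600.0, 125.0, 4.0)
        return SpectralCurve(GRID.copy(), vals, kind="spd")
    if name == "amber_led":
        return line_spectrum([LineSpec(602.0, 70.0, 1.0)])
    if name == "incandescent":
        return blackbody_spd(2600.0)
    raise ValueError(
        f"unknown archetype {name!r}; valid names: {', '.join(ARCHETYPE_NAMES)}"
    )
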