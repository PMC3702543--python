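"""Colorimetry: chromaticity, correlated color temperature, color rendering.

Chromaticity uses the unmodified CIE 1931 2-degree color-matching functions
(the colorimetric standard), while the constant-lumen normalization elsewhere
uses the Judd-Vos corrected photopic curve; the two roles are deliberately
distinct tabulations.

CCT is McCamy's cubic approximation in n = (x - 0.3320)/(0.1858 - y).  It is
applied unconditionally, even for sources far outside its nominal validity
(quasi-monochromatic sodium lamps land near 1700 K); results outside
2000-12500 K carry an advisory flag rather than being rejected.

CRI follows the CIE test-color method: eight test samples rendered under the
test source and under a reference illuminant of the same CCT (Planckian
radiator below 5000 K, daylight at or above), von Kries chromatic adaptation
in the CIE 1960 uv diagram, color differences in U*V*W* space, and
Ra = mean(100 - 4.6 dE_i).  The general index can be negative for strongly
color-distorting sources.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .core import GRID, SpectralCurve, canonicalize, weighted_integral
from .weights import get_reference_spd, load_tabulation

# Planck radiation constants: c2 in nm*K for exp(c2 / (lambda T)).
_C2_NM_K = 1.4388e7

#: McCamy validity advisory band, kelvin.
CCT_RELIABLE_RANGE = (2000.0, 12500.0)


@dataclass(frozen=True)
class Chromaticity:
    """CIE 1931 (x, y) chromaticity coordinates."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (0 < self.x < 1 and 0 < self.y < 1 and self.x + self.y < 1):
            raise ValueError(f"chromaticity ({self.x}, {self.y}) outside the unit diagram")


@lru_cache(maxsize=None)
def _cmf() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    table = load_tabulation("cmf")
    curves = []
    for col in (1, 2, 3):
        c = SpectralCurve(table[:, 0], table[:, col], kind="sensitivity")
        curves.append(canonicalize(c).values)
    return tuple(curves)  # type: ignore[return-value]


def tristimulus(spd: SpectralCurve) -> tuple[float, float, float]:
    """CIE 1931 X, Y, Z integrals of a canonical SPD (relative units)."""
    spd = canonicalize(spd)
    xbar, ybar, zbar = _cmf()
    X = float(np.trapezoid(spd.values * xbar, GRID))
    Y = float(np.trapezoid(spd.values * ybar, GRID))
    Z = float(np.trapezoid(spd.values * zbar, GRID))
    return X, Y, Z


def chromaticity(spd: SpectralCurve) -> Chromaticity:
    """CIE 1931 (x, y) chromaticity of an SPD; scale invariant."""
    X, Y, Z = tristimulus(spd)
    s = X + Y + Z
    if s <= 0:
        raise ValueError("SPD has no visual content; chromaticity undefined")
    return Chromaticity(X / s, Y / s)


def cct_mccamy(c: Chromaticity) -> float:
    """Correlated color temperature via McCamy's cubic approximation (kelvin)."""
    if abs(0.1858 - c.y) < 1e-12:
        raise ValueError("chromaticity y = 0.1858 is a pole of McCamy's formula")
    n = (c.x - 0.3320) / (0.1858 - c.y)
    return 449.0 * n**3 + 3525.0 * n**2 + 6823.3 * n + 5520.33


def cct_is_reliable(cct: float) -> bool:
    """Advisory: False when McCamy's approximation was used outside its
    nominal validity range."""
    lo, hi = CCT_RELIABLE_RANGE
    return lo <= cct <= hi


def planck_spd(temperature: float) -> SpectralCurve:
    """Blackbody (Planckian) relative SPD on the canonical grid, peak-scaled."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    lam = GRID  # nm
    vals = (1.0 / lam**5) / np.expm1(_C2_NM_K / (lam * temperature))
    return SpectralCurve(GRID.copy(), vals / vals.max(), kind="spd")


# --- CIE test-color method -------------------------------------------------

#: Centers (nm) and widths (nm) of the synthetic moderate-chroma test-color
#: reflectance set.  These are smooth Gaussian-band stand-ins spanning the hue
#: circle, built in-code because the standard sample tabulations are not
#: bundled; they preserve the structure of the method (Ra = 100 exactly when
#: test equals reference, strongly negative for quasi-monochromatic sources)
#: but individual Ra values for real lamps depend on the sample set.
_TCS_BANDS = (
    (440.0, 55.0),
    (480.0, 55.0),
    (520.0, 55.0),
    (560.0, 55.0),
    (600.0, 55.0),
    (640.0, 55.0),
    (680.0, 60.0),
    (410.0, 60.0),
)


@lru_cache(maxsize=None)
def _tcs_reflectances() -> np.ndarray:
    """Synthetic test-color sample reflectances, shape (8, n_grid)."""
    refl = []
    for center, width in _TCS_BANDS:
        r = 0.25 + 0.45 * np.exp(-0.5 * ((GRID - center) / width) ** 2)
        refl.append(r)
    return np.vstack(refl)


def _uv_1960(X: float, Y: float, Z: float) -> tuple[float, float]:
    den = X + 15.0 * Y + 3.0 * Z
    return 4.0 * X / den, 6.0 * Y / den


def _cd(u: float, v: float) -> tuple[float, float]:
    # Auxiliary von Kries adaptation coordinates of the CIE test-color method.
    c = (4.0 - u - 10.0 * v) / v
    d = (1.708 * v + 0.404 - 1.481 * u) / v
    return c, d


def _sample_uvY(illum: SpectralCurve, refl: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xbar, ybar, zbar = _cmf()
    norm = 100.0 / float(np.trapezoid(illum.values * ybar, GRID))
    us, vs, Ys = [], [], []
    for r in refl:
        s = illum.values * r
        X = norm * float(np.trapezoid(s * xbar, GRID))
        Y = norm * float(np.trapezoid(s * ybar, GRID))
        Z = norm * float(np.trapezoid(s * zbar, GRID))
        u, v = _uv_1960(X, Y, Z)
        us.append(u)
        vs.append(v)
        Ys.append(Y)
    return np.array(us), np.array(vs), np.array(Ys)


def reference_illuminant(cct: float) -> SpectralCurve:
    """Reference illuminant of the test-color method for a given CCT.

    A Planckian radiator below 5000 K; at or above 5000 K, a daylight-phase
    illuminant, represented here by the bundled D65 tabulation (exact at D65's
    own CCT of ~6504 K, an approximation at other daylight temperatures --
    documented limitation, and irrelevant below 5000 K where most discharge
    and LED street sources sit).
    """
    if cct < 5000.0:
        return planck_spd(max(cct, 1000.0))
    return get_reference_spd()


def cri(spd: SpectralCurve) -> float:
    """General color rendering index Ra of an SPD (may be negative)."""
    spd = canonicalize(spd)
    test_cct = cct_mccamy(chromaticity(spd))
    ref = reference_illuminant(test_cct)

    refl = _tcs_reflectances()
    Xt, Yt, Zt = tristimulus(spd)
    ut, vt = _uv_1960(Xt, Yt, Zt)
    Xr, Yr, Zr = tristimulus(ref)
    ur, vr = _uv_1960(Xr, Yr, Zr)

    u_k, v_k, Y_k = _sample_uvY(spd, refl)
    u_ri, v_ri, Y_ri = _sample_uvY(ref, refl)

    # Von Kries adaptation of the test-source sample coordinates onto the
    # reference illuminant's adaptation state.
    c_t, d_t = _cd(ut, vt)
    c_r, d_r = _cd(ur, vr)
    adapted_u = np.empty_like(u_k)
    adapted_v = np.empty_like(v_k)
    for i, (u, v) in enumerate(zip(u_k, v_k)):
        c_i, d_i = _cd(u, v)
        num_c = (c_r / c_t) * c_i
        num_d = (d_r / d_t) * d_i
        den = 16.518 + 1.481 * num_c - num_d
        adapted_u[i] = (10.872 + 0.404 * num_c - 4.0 * num_d) / den
        adapted_v[i] = 5.520 / den

    W_t = 25.0 * np.cbrt(Y_k) - 17.0
    U_t = 13.0 * W_t * (adapted_u - ur)
    V_t = 13.0 * W_t * (adapted_v - vr)
    W_r = 25.0 * np.cbrt(Y_ri) - 17.0
    U_r = 13.0 * W_r * (u_ri - ur)
    V_r = 13.0 * W_r * (v_ri - vr)

    dE = np.sqrt((U_t - U_r) ** 2 + (V_t - V_r) ** 2 + (W_t - W_r) ** 2)
    return float(np.mean(100.0 - 4.6 * dE))
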