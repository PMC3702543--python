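"""Single-scattering skyglow: the spectral transfer function T(lambda).

A ground-level lamp sends light upward; molecules and aerosols scatter part of
it back down to an observer a ground distance ``d`` away who cannot see the
lamp directly (obstacles block the direct ray).  The model integrates
single-scattered radiance along the observer's view ray through a
plane-parallel stratified atmosphere:

* molecular (Rayleigh) extinction with optical thickness decaying
  exponentially with altitude (scale height ~8 km), ground value from a
  standard lambda^-4 dispersion formula;
* aerosol extinction with an Angstrom power law in wavelength
  (tau_a = 0.2 at 500 nm, exponent 1.0 -- urban/suburban haze), scale height
  ~1.2 km, single-scattering albedo 0.9, Henyey-Greenstein phase function
  with asymmetry g = 0.8;
* Rayleigh scattering treated as conservative with the (3/16 pi)(1 + cos^2)
  phase function;
* clear sky: altitude integration truncated at 50 km (the column is optically
  negligible beyond); cloudy sky: truncated at the cloud base, plus a single
  Lambertian reflection off the cloud base with reflectance 0.46.

Everything is linear in the source, so T(lambda) is computed once per
(distance, sky) and applied multiplicatively to any SPD.  Units are relative:
the impact indices renormalize transferred spectra, so only the spectral
shape of T matters.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .core import GRID, SpectralCurve

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class AtmosphereConfig:
    """Atmospheric state for the transfer computation.

    tau_a0:
        Aerosol optical thickness at ``lambda_ref`` (clear urban default 0.2).
    lambda_ref:
        Reference wavelength for the aerosol power law, nm.  500 nm makes the
        Rayleigh column exceed the aerosol column by ~50% at 400 nm and fall
        ~3x below it at 650 nm, the regime the model targets.
    angstrom:
        Angstrom exponent of the aerosol power law (urban haze ~1.0).
    aerosol_scale_height / molecular_scale_height:
        Exponential scale heights, km (boundary-layer aerosol ~1.2 km,
        molecular atmosphere 8 km).
    g:
        Henyey-Greenstein asymmetry parameter of the aerosol phase function.
    omega_a:
        Aerosol single-scattering albedo (molecular scattering is
        conservative).
    cloud_base:
        Altitude of the cloud base, km, used only in cloudy mode.
    cloud_reflectance:
        Diffuse reflectance of the cloud underside (average cloud ~0.46).
    ground_reflectance:
        Ground albedo, kept for illuminance conversions (no ground
        inter-reflection term in the transfer).
    z_top:
        Clear-sky truncation altitude, km.
    z_min:
        Lowest scattering altitude, km; stands in for the obstacle height
        that blocks the direct ray (also regularizes the colocated
        source/observer geometry).
    n_steps:
        Log-spaced altitude quadrature points per view ray.
    """

    tau_a0: float = 0.2
    lambda_ref: float = 500.0
    angstrom: float = 1.0
    aerosol_scale_height: float = 1.2
    molecular_scale_height: float = 8.0
    g: float = 0.8
    omega_a: float = 0.9
    cloud_base: float = 1.5
    cloud_reflectance: float = 0.46
    ground_reflectance: float = 0.08
    z_top: float = 50.0
    z_min: float = 0.05
    n_steps: int = 100

    def __post_init__(self) -> None:
        if self.tau_a0 < 0 or self.angstrom < 0:
            raise ValueError("tau_a0 and angstrom must be >= 0")
        if self.aerosol_scale_height <= 0 or self.molecular_scale_height <= 0:
            raise ValueError("scale heights must be > 0")
        if not -1 < self.g < 1:
            raise ValueError("asymmetry parameter g must lie in (-1, 1)")
        if not 0 < self.omega_a <= 1:
            raise ValueError("single-scattering albedo must lie in (0, 1]")
        if not 0 <= self.cloud_reflectance <= 1:
            raise ValueError("cloud reflectance must lie in [0, 1]")
        if not 0 < self.ground_reflectance <= 1:
            raise ValueError("ground reflectance must lie in (0, 1]")
        if self.cloud_base is not None and self.cloud_base <= self.z_min:
            raise ValueError("cloud base must sit above z_min")
        if self.n_steps < 8:
            raise ValueError("n_steps too small for a convergent quadrature")

    def config_hash(self) -> str:
        payload = ",".join(f"{f.name}={getattr(self, f.name)!r}" for f in fields(self))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class SceneGeometry:
    """Source emission pattern and observer viewing mode.

    The source emits into the upward hemisphere, either isotropically
    (``cosine_exponent = 0``) or with a cos^n zenith weighting.  The observer
    modes are:

    ``zenith``
        radiance along the single vertical view ray (cheap; good for
        transfer-shape comparisons at short range);
    ``dome``
        total scattered radiation received at the measuring point: radiance
        integrated over the sky hemisphere with solid-angle weighting only.
        This is the default: at large distances the received light is
        dominated by low-elevation, long-path beams in the strong aerosol
        forward-scattering lobe, which a zenith ray misses entirely -- the
        dome view is what turns the transfer from blue-enhanced at short
        range to red-shifted at long range;
    ``hemisphere``
        cosine-weighted (horizontal-surface irradiance) variant of ``dome``.

    Index ratios are insensitive to smooth gray angular source patterns
    because the identical pattern applies to the lamp and to the D65
    reference.
    """

    cosine_exponent: float = 0.0
    view: str = "dome"
    max_view_zenith: float = 80.0
    n_view_zenith: int = 12
    n_view_azimuth: int = 12

    def __post_init__(self) -> None:
        if self.cosine_exponent < 0:
            raise ValueError("cosine exponent must be >= 0")
        if self.view not in ("zenith", "dome", "hemisphere"):
            raise ValueError("view must be 'zenith', 'dome' or 'hemisphere'")
        if not 0 < self.max_view_zenith < 90:
            raise ValueError("max_view_zenith must lie in (0, 90) degrees")


@dataclass(frozen=True)
class TransferFunction:
    """Distance- and sky-tagged spectral weights applied to lamp and reference."""

    curve: SpectralCurve
    distance: float
    sky: str
    config_hash: str = ""


def rayleigh_tau(lam) -> np.ndarray | float:
    """Ground-level molecular (Rayleigh) optical thickness at wavelength nm.

    Standard molecular-dispersion formula (lambda^-4 with weak correction
    terms), ~0.097 at 550 nm for a sea-level column.
    """
    lam_um = np.asarray(lam, dtype=float) / 1000.0
    tau = 0.008569 * lam_um**-4 * (1.0 + 0.0113 * lam_um**-2 + 0.00013 * lam_um**-4)
    return tau if tau.ndim else float(tau)


def aerosol_tau(lam, cfg: AtmosphereConfig) -> np.ndarray | float:
    """Ground-level aerosol optical thickness: Angstrom power law."""
    lam = np.asarray(lam, dtype=float)
    tau = cfg.tau_a0 * (cfg.lambda_ref / lam) ** cfg.angstrom
    return tau if tau.ndim else float(tau)


def extinction_profile(lam, z, cfg: AtmosphereConfig):
    """Total extinction coefficient k(lambda, z) in km^-1 at altitude z (km)."""
    lam = np.asarray(lam, dtype=float)
    z = np.asarray(z, dtype=float)
    k_m = rayleigh_tau(lam) / cfg.molecular_scale_height * np.exp(-z / cfg.molecular_scale_height)
    k_a = aerosol_tau(lam, cfg) / cfg.aerosol_scale_height * np.exp(-z / cfg.aerosol_scale_height)
    out = k_m + k_a
    return out if np.ndim(out) else float(out)


def _tau_vertical(lam, z, cfg: AtmosphereConfig):
    """Vertical optical thickness from the ground to altitude z (closed form)."""
    z = np.asarray(z, dtype=float)
    t_m = rayleigh_tau(lam) * (1.0 - np.exp(-z / cfg.molecular_scale_height))
    t_a = aerosol_tau(lam, cfg) * (1.0 - np.exp(-z / cfg.aerosol_scale_height))
    return t_m + t_a


def path_transmission(lam, p1, p2, cfg: AtmosphereConfig, n_samples: int = 2000) -> float:
    """Transmission exp(-integral of k ds) along the straight segment p1 -> p2.

    Points are (x, y, z) in km with z the altitude.  Numerical trapezoidal
    quadrature along the segment; the stratified closed form used internally
    by :func:`sky_transfer` is its exact limit.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1[2] < 0 or p2[2] < 0:
        raise ValueError("path endpoints must lie at altitude >= 0")
    length = float(np.linalg.norm(p2 - p1))
    if length == 0.0:
        return 1.0
    t = np.linspace(0.0, 1.0, n_samples)
    z = p1[2] + t * (p2[2] - p1[2])
    k = extinction_profile(lam, z, cfg)
    return float(np.exp(-np.trapezoid(k, t * length)))


def scattering_angle(z, A, zp, Ap) -> float:
    """Angle (degrees) between directions (zenith z, azimuth A) and (zp, Ap)."""
    z, A, zp, Ap = (np.asarray(v, dtype=float) * _DEG for v in (z, A, zp, Ap))
    cos_t = np.cos(z) * np.cos(zp) + np.sin(z) * np.sin(zp) * np.cos(A - Ap)
    out = np.arccos(np.clip(cos_t, -1.0, 1.0)) / _DEG
    return out if np.ndim(out) else float(out)


def rayleigh_phase(theta_deg) -> np.ndarray | float:
    """Rayleigh phase function (3/16 pi)(1 + cos^2 theta), per steradian."""
    ct = np.cos(np.asarray(theta_deg, dtype=float) * _DEG)
    out = 3.0 / (16.0 * math.pi) * (1.0 + ct**2)
    return out if np.ndim(out) else float(out)


def hg_phase(theta_deg, g: float) -> np.ndarray | float:
    """Henyey-Greenstein phase function, per steradian, normalized to 1."""
    if not -1 < g < 1:
        raise ValueError("asymmetry parameter g must lie in (-1, 1)")
    ct = np.cos(np.asarray(theta_deg, dtype=float) * _DEG)
    out = (1.0 - g * g) / (4.0 * math.pi * (1.0 + g * g - 2.0 * g * ct) ** 1.5)
    return out if np.ndim(out) else float(out)


def combined_phase(lam, theta_deg, z, cfg: AtmosphereConfig):
    """Molecular/aerosol mixture phase function at altitude z, per steradian.

    Weights are the local *scattering* (not extinction) coefficients: the
    molecular part is conservative, the aerosol part carries omega_a.  The
    mixture therefore integrates to 1 over the sphere for every lambda and z.
    """
    lam = np.asarray(lam, dtype=float)
    z = np.asarray(z, dtype=float)
    k_m = rayleigh_tau(lam) / cfg.molecular_scale_height * np.exp(-z / cfg.molecular_scale_height)
    k_a = (
        aerosol_tau(lam, cfg) / cfg.aerosol_scale_height * np.exp(-z / cfg.aerosol_scale_height)
    )
    sca_m = k_m
    sca_a = cfg.omega_a * k_a
    out = (sca_m * rayleigh_phase(theta_deg) + sca_a * hg_phase(theta_deg, cfg.g)) / (
        sca_m + sca_a
    )
    return out if np.ndim(out) else float(out)


def _ray_radiance(
    distance: float,
    z_max: float,
    cfg: AtmosphereConfig,
    geom: SceneGeometry,
    view_zenith: float = 0.0,
    view_azimuth: float = 0.0,
    n_steps: int | None = None,
) -> np.ndarray:
    """Single-scattered spectral radiance along one observer view ray.

    Source at the origin, observer at ground distance ``distance`` along +x.
    Returns the radiance spectrum on the canonical grid (relative units).
    """
    n = n_steps or cfg.n_steps
    mu = math.cos(view_zenith * _DEG)
    if mu <= 0:
        raise ValueError("view ray must point above the horizon")
    # Log-spaced altitudes resolve the steep low-altitude aerosol layer.
    z = np.geomspace(cfg.z_min, z_max, n)  # (nz,)
    sin_v = math.sin(view_zenith * _DEG)
    px = distance + (z / mu) * sin_v * math.cos(view_azimuth * _DEG)
    py = (z / mu) * sin_v * math.sin(view_azimuth * _DEG)
    r_sv = np.sqrt(px**2 + py**2 + z**2)  # source -> volume range, km

    lam = GRID[None, :]  # (1, nl)
    zc = z[:, None]  # (nz, 1)

    tau_v = _tau_vertical(lam, zc, cfg)  # vertical tau to each altitude
    # Straight-line slant paths in a plane-parallel atmosphere: secant scaling
    # of the vertical column (exact for straight rays; refraction neglected).
    trans_up = np.exp(-(r_sv / z)[:, None] * tau_v)  # source -> volume
    trans_down = np.exp(-tau_v / mu)  # volume -> observer

    # Source emission pattern over the upward hemisphere.
    cos_emit = z / r_sv
    pattern = cos_emit**geom.cosine_exponent if geom.cosine_exponent else np.ones_like(cos_emit)

    # Scattering angle between the source->volume ray and the volume->observer
    # ray (propagation directions).
    u_out = np.array([-sin_v * math.cos(view_azimuth * _DEG),
                      -sin_v * math.sin(view_azimuth * _DEG),
                      -mu])
    cos_theta = (px * u_out[0] + py * u_out[1] + z * u_out[2]) / r_sv
    theta = np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0)))  # (nz,)

    k_m = rayleigh_tau(lam) / cfg.molecular_scale_height * np.exp(
        -zc / cfg.molecular_scale_height
    )
    k_a = aerosol_tau(lam, cfg) / cfg.aerosol_scale_height * np.exp(
        -zc / cfg.aerosol_scale_height
    )
    sca = k_m * rayleigh_phase(theta)[:, None] + cfg.omega_a * k_a * hg_phase(
        theta, cfg.g
    )[:, None]  # scattering coefficient x phase, (nz, nl)

    integrand = pattern[:, None] * trans_up * sca * trans_down / (r_sv**2)[:, None]
    # Path element along the view ray: ds = dz / mu.
    return np.trapezoid(integrand, z, axis=0) / mu


def _cloud_bounce(
    distance: float, cfg: AtmosphereConfig, geom: SceneGeometry, view_zenith: float = 0.0,
    view_azimuth: float = 0.0,
) -> np.ndarray:
    """Radiance from a single Lambertian reflection off the cloud base.

    The observer's view ray meets the cloud underside at one point; that point
    is illuminated directly by the source (attenuated along the slant path),
    reflects diffusely with the configured cloud reflectance, and the
    reflected radiance is attenuated down to the observer.  This replaces the
    full overcast radiance term with its dominant contribution.
    """
    zc = cfg.cloud_base
    mu = math.cos(view_zenith * _DEG)
    sin_v = math.sin(view_zenith * _DEG)
    px = distance + (zc / mu) * sin_v * math.cos(view_azimuth * _DEG)
    py = (zc / mu) * sin_v * math.sin(view_azimuth * _DEG)
    r = math.sqrt(px**2 + py**2 + zc**2)
    tau_c = _tau_vertical(GRID, zc, cfg)
    cos_emit = zc / r
    pattern = cos_emit**geom.cosine_exponent if geom.cosine_exponent else 1.0
    illum = pattern * np.exp(-(r / zc) * tau_c) * (zc / r) / r**2
    return illum * (cfg.cloud_reflectance / math.pi) * np.exp(-tau_c / mu)


def sky_transfer(
    distance: float,
    sky: str,
    cfg: AtmosphereConfig | None = None,
    geom: SceneGeometry | None = None,
    n_steps: int | None = None,
) -> TransferFunction:
    """Spectral transfer function T(lambda) for a lamp-observer separation.

    ``sky='clear'`` integrates single scattering up to ``cfg.z_top``;
    ``sky='cloudy'`` caps the column at the cloud base and adds the
    cloud-reflected term.  The same T applies to the lamp SPD and to the D65
    reference, so any overall constant is irrelevant downstream.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if sky not in ("clear", "cloudy"):
        raise ValueError("sky must be 'clear' or 'cloudy'")
    cfg = cfg or AtmosphereConfig()
    geom = geom or SceneGeometry()
    if sky == "cloudy" and cfg.cloud_base is None:
        raise ValueError("cloudy sky requires cloud_base in the configuration")
    z_max = cfg.z_top if sky == "clear" else cfg.cloud_base

    if geom.view == "zenith":
        rays = [(0.0, 0.0, 1.0)]
    else:
        # Midpoint quadrature over the sky dome; 'dome' weights by solid
        # angle only, 'hemisphere' adds the horizontal-detector cosine.
        zen_edges = np.linspace(0.0, geom.max_view_zenith, geom.n_view_zenith + 1)
        az = np.linspace(0.0, 360.0, geom.n_view_azimuth, endpoint=False)
        rays = []
        for i in range(geom.n_view_zenith):
            zv = 0.5 * (zen_edges[i] + zen_edges[i + 1])
            dzen = (zen_edges[i + 1] - zen_edges[i]) * _DEG
            w = math.sin(zv * _DEG) * dzen * (2 * math.pi / geom.n_view_azimuth)
            if geom.view == "hemisphere":
                w *= math.cos(zv * _DEG)
            for a in az:
                rays.append((zv, a, w))

    total = np.zeros_like(GRID)
    for zv, av, w in rays:
        vals = _ray_radiance(distance, z_max, cfg, geom, zv, av, n_steps=n_steps)
        if sky == "cloudy":
            vals = vals + _cloud_bounce(distance, cfg, geom, zv, av)
        total += w * vals

    if not np.all(np.isfinite(total)):
        raise RuntimeError(
            "transfer quadrature did not converge; increase n_steps or raise z_min"
        )
    curve = SpectralCurve(GRID.copy(), total, kind="transfer")
    return TransferFunction(curve=curve, distance=distance, sky=sky, config_hash=cfg.config_hash())


def normalize_at(curve: SpectralCurve, lam0: float = 550.0) -> SpectralCurve:
    """Scale a curve to 1 at ``lam0`` (display/comparison convention only)."""
    v0 = curve.value_at(lam0)
    if v0 <= 0:
        raise ValueError(f"curve is zero at {lam0} nm; cannot normalize there")
    return curve.scaled(1.0 / v0)


def write_transfer(tf: TransferFunction, path) -> None:
    """Export a transfer function as two-column text with a metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# transfer function: distance_km={tf.distance} sky={tf.sky}\n")
        fh.write(f"# config_hash={tf.config_hash}\n")
        fh.write("# wavelength_nm  weight\n")
        for wl, v in zip(tf.curve.wavelengths, tf.curve.values):
            fh.write(f"{wl:.1f} {v:.8e}\n")


def config_from_file(path) -> AtmosphereConfig:
    """Read an AtmosphereConfig from flat ``key = value`` text.

    Keys must be AtmosphereConfig field names; unknown keys are an error.
    """
    known = {f.name: f for f in fields(AtmosphereConfig)}
    overrides: dict[str, float | int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                key, _, val = line.partition("=")
            else:
                parts = line.split(None, 1)
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: cannot parse {raw!r}")
                key, val = parts
            key = key.strip()
            if key not in known:
                raise ValueError(
                    f"{path}:{lineno}: unknown configuration key {key!r}; "
                    f"valid keys: {', '.join(sorted(known))}"
                )
            overrides[key] = int(val) if key == "n_steps" else float(val)
    return replace(AtmosphereConfig(), **overrides)
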