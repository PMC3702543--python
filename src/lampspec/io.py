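"""Readers, writers and the batch pipeline.

Lamp SPDs travel as plain two-column text (wavelength in nm, relative power)
-- the format spectral databases distribute.  Whitespace or comma separated,
``#`` comments, an optional non-numeric header row.  Results are written as
CSV or JSON, one row per lamp x condition, with the descriptor columns in
the order x, y, CCT, CRI, MSI, IPI, SLI.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atmosphere import AtmosphereConfig, SceneGeometry, sky_transfer
from .core import SpectralCurve, canonicalize
from .fixtures import lamp_archetype
from .indices import IndexResult, compute_indices

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["lamp", "sky", "distance_km", "x", "y", "cct", "cri", "msi", "ipi", "sli"]


class SpdParseError(ValueError):
    """A lamp SPD file could not be parsed."""


def read_spd(path) -> SpectralCurve:
    """Read a two-column text SPD and canonicalize it to the 380-730 nm grid.

    Small negative values (spectrometer noise) are clipped to zero with a
    warning.  Wavelengths outside 200-2000 nm are rejected as probable unit
    confusion (micrometres instead of nanometres).
    """
    path = Path(path)
    wavelengths: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) != 2:
                raise SpdParseError(f"{path}:{lineno}: expected 2 columns, got {len(tokens)}")
            try:
                wl, val = float(tokens[0]), float(tokens[1])
            except ValueError:
                if lineno == 1 or not wavelengths:
                    continue  # header row
                raise SpdParseError(f"{path}:{lineno}: cannot parse {raw.strip()!r}") from None
            if not 200 <= wl <= 2000:
                raise SpdParseError(
                    f"{path}:{lineno}: wavelength {wl} outside 200-2000 nm; "
                    "wavelengths must be in nanometres (micrometre input is not converted)"
                )
            wavelengths.append(wl)
            values.append(val)
    if len(wavelengths) < 2:
        raise SpdParseError(f"{path}: found {len(wavelengths)} data rows, need at least 2")
    vals = np.asarray(values)
    if np.any(vals < 0):
        n_neg = int(np.sum(vals < 0))
        logger.warning("%s: clipped %d negative values to 0 (spectrometer noise)", path, n_neg)
        vals = np.clip(vals, 0.0, None)
    return canonicalize(SpectralCurve(np.asarray(wavelengths), vals, kind="spd"))


def write_spd(curve: SpectralCurve, path, header: str = "") -> None:
    """Write a spectral curve as two-column text."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# wavelength_nm  value\n")
        for wl, v in zip(curve.wavelengths, curve.values):
            fh.write(f"{wl:.1f} {v:.9e}\n")


@dataclass
class RunConfig:
    """Batch-run description: which lamps, which skies, which distances."""

    spd_paths: list = field(default_factory=list)
    archetypes: list = field(default_factory=list)
    sky: str = "direct"
    distances: list = field(default_factory=lambda: [0.0])
    atmosphere: AtmosphereConfig = field(default_factory=AtmosphereConfig)
    geometry: SceneGeometry = field(default_factory=SceneGeometry)

    def __post_init__(self) -> None:
        if self.sky not in ("direct", "clear", "cloudy"):
            raise ValueError("sky must be direct, clear or cloudy")
        if not self.spd_paths and not self.archetypes:
            raise ValueError("at least one SPD path or archetype is required")
        if any(d < 0 for d in self.distances):
            raise ValueError("distances must be >= 0")


class PipelineError(RuntimeError):
    """At least one lamp failed during a batch run."""

    def __init__(self, failures: list[tuple[str, str]]):
        self.failures = failures
        msg = "; ".join(f"{lamp}: {err}" for lamp, err in failures)
        super().__init__(f"{len(failures)} lamp(s) failed: {msg}")


def run_pipeline(cfg: RunConfig, strict: bool = False) -> list[IndexResult]:
    """Compute an IndexResult per lamp x distance (x sky mode).

    Transfer functions depend on (distance, sky) only, so they are computed
    once and shared across lamps.  A failing lamp is logged and skipped so the
    remaining lamps still produce results; with ``strict=True`` the collected
    failures are raised afterwards as :class:`PipelineError`.
    """
    lamps: list[tuple[str, SpectralCurve | None, str | None]] = []
    for p in cfg.spd_paths:
        lamps.append((Path(p).stem, None, str(p)))
    for name in cfg.archetypes:
        lamps.append((name, lamp_archetype(name), None))

    logger.info(
        "pipeline: %d lamps, sky=%s, %d distance(s), atmosphere %s",
        len(lamps), cfg.sky, len(cfg.distances), cfg.atmosphere.config_hash(),
    )

    transfers = {}
    if cfg.sky != "direct":
        for d in cfg.distances:
            transfers[d] = sky_transfer(d, cfg.sky, cfg.atmosphere, cfg.geometry)

    results: list[IndexResult] = []
    failures: list[tuple[str, str]] = []
    for lamp_id, curve, path in lamps:
        try:
            if curve is None:
                curve = read_spd(path)
        except Exception as exc:  # noqa: BLE001 - report and continue
            logger.error("lamp %s failed at stage read: %s", lamp_id, exc)
            failures.append((lamp_id, f"read: {exc}"))
            continue
        if cfg.sky == "direct":
            conditions = [None]
        else:
            conditions = [transfers[d] for d in cfg.distances]
        for tf in conditions:
            try:
                results.append(compute_indices(curve, transfer=tf, lamp_id=lamp_id))
            except Exception as exc:  # noqa: BLE001
                logger.error("lamp %s failed at stage indices: %s", lamp_id, exc)
                failures.append((lamp_id, f"indices: {exc}"))
    if failures and strict:
        raise PipelineError(failures)
    return results


def results_frame(results: list[IndexResult]) -> pd.DataFrame:
    """Results as a DataFrame in the standard column order."""
    rows = [r.as_dict() for r in results]
    df = pd.DataFrame(rows)
    extra = [c for c in df.columns if c not in RESULT_COLUMNS]
    return df[RESULT_COLUMNS + extra] if len(df) else df


def write_results(results: list[IndexResult], path, fmt: str = "csv") -> None:
    """Write results as CSV or JSON (one row/object per lamp x condition)."""
    path = Path(path)
    if fmt == "csv":
        results_frame(results).to_csv(path, index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump([r.as_dict() for r in results], fh, indent=1)
    else:
        raise ValueError("format must be 'csv' or 'json'")
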