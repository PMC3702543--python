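"""The three lamp-spectrum impact indices: MSI, IPI and SLI.

Each index is the ratio of the action-spectrum-weighted, constant-lumen lamp
spectrum to the equally processed CIE D65 daylight reference:

    index = int(S_cl * A) / int(D65_cl * A),   380-730 nm,

with A the melatonin suppression action spectrum (MSI), the photosynthesis
action spectrum (IPI) or the scotopic sensitivity (SLI).  Daylight scores
exactly 1 on all three by construction; a lamp's index says how strongly its
light drives the process *per lumen*, relative to daylight of the same
brightness.  Indices typically fall in [0, ~1] but are not clipped: a source
blue-richer than daylight can exceed 1.

When atmospheric scattering is considered, the same spectral transfer
function T(lambda) is applied to the constant-lumen lamp and reference
spectra, and the weighted ratio of the transferred spectra is taken directly:
the comparison is between sources of equal *emitted* luminous output, each
seen through the same sky.  An alternative convention, comparing at equal
*received* luminous content (renormalizing both transferred spectra to
constant lumen), is available via ``equal_received_lumen=True``; under that
convention the photopic-weighted index is identically 1 through any
atmosphere, an exact internal consistency check of the normalization and
ratio machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

from .atmosphere import TransferFunction
from .color import cct_is_reliable, cct_mccamy, chromaticity, cri
from .core import SpectralCurve, canonicalize, multiply, normalize_constant_lumen, weighted_integral
from .weights import get_reference_spd, get_weight


@dataclass(frozen=True)
class IndexResult:
    """Photometric record for one lamp under one viewing condition.

    Mirrors one results row: chromaticity, CCT, CRI, and the three impact
    indices.  ``sky='direct'`` means no atmosphere; for scattered conditions
    (``clear``/``cloudy``) the colorimetric descriptors are computed from the
    transferred spectrum and are informational only (``descriptors_scattered``
    is then True).  ``cct_advisory`` flags CCT values outside the nominal
    validity of the McCamy approximation.
    """

    lamp_id: str
    x: float
    y: float
    cct: float
    cri: float
    msi: float
    ipi: float
    sli: float
    distance: float | None = None
    sky: str = "direct"
    cct_advisory: bool = False
    descriptors_scattered: bool = False

    def as_dict(self) -> dict:
        d = {
            "lamp": self.lamp_id,
            "sky": self.sky,
            "distance_km": self.distance,
            "x": round(self.x, 4),
            "y": round(self.y, 4),
            "cct": round(self.cct, 0),
            "cri": round(self.cri, 1),
            "msi": round(self.msi, 3),
            "ipi": round(self.ipi, 3),
            "sli": round(self.sli, 3),
        }
        if self.cct_advisory:
            d["cct_advisory"] = True
        return d


def _prepare(
    spd: SpectralCurve,
    transfer: TransferFunction | SpectralCurve | None,
    equal_received_lumen: bool,
) -> SpectralCurve:
    spd = normalize_constant_lumen(canonicalize(spd))
    if transfer is not None:
        t_curve = transfer.curve if isinstance(transfer, TransferFunction) else transfer
        spd = multiply(spd, canonicalize(t_curve))
        if equal_received_lumen:
            spd = normalize_constant_lumen(spd)
    return spd


def spectral_index(
    spd: SpectralCurve,
    weight: SpectralCurve,
    transfer: TransferFunction | SpectralCurve | None = None,
    reference: SpectralCurve | None = None,
    equal_received_lumen: bool = False,
) -> float:
    """Weighted constant-lumen ratio of a lamp SPD to the D65 reference.

    ``transfer`` (a spectral transfer function, or None for direct viewing)
    is applied identically to the constant-lumen lamp and reference spectra.
    By default the comparison is at equal emitted lumen: the transferred
    spectra are ratioed as-is.  With ``equal_received_lumen=True`` both
    transferred spectra are renormalized to constant lumen first, comparing
    the sources at equal received luminous content instead; in that
    convention the photopic-weighted index is exactly 1 for any transfer.
    """
    if reference is None:
        reference = get_reference_spd()
    num_spd = _prepare(spd, transfer, equal_received_lumen)
    den_spd = _prepare(reference, transfer, equal_received_lumen)
    weight = canonicalize(weight)
    numerator = weighted_integral(num_spd, weight)
    denominator = weighted_integral(den_spd, weight)
    if denominator <= 0:
        raise ValueError("weight is orthogonal to the transferred reference spectrum")
    return numerator / denominator


def compute_indices(
    spd: SpectralCurve,
    transfer: TransferFunction | None = None,
    lamp_id: str = "",
) -> IndexResult:
    """Full photometric record: chromaticity, CCT, CRI, MSI, IPI, SLI.

    Direct mode (``transfer=None``) computes the colorimetric descriptors from
    the lamp spectrum itself; scattered mode computes them from the
    transferred spectrum (informational -- the sky's hue, not the lamp's).
    """
    spd = canonicalize(spd)
    msi = spectral_index(spd, get_weight("msas"), transfer)
    ipi = spectral_index(spd, get_weight("pas"), transfer)
    sli = spectral_index(spd, get_weight("scotopic"), transfer)

    if transfer is None:
        descriptor_spd = spd
        distance, sky, scattered = None, "direct", False
    else:
        descriptor_spd = multiply(spd, canonicalize(transfer.curve))
        distance, sky, scattered = transfer.distance, transfer.sky, True

    chroma = chromaticity(descriptor_spd)
    cct = cct_mccamy(chroma)
    return IndexResult(
        lamp_id=lamp_id,
        x=chroma.x,
        y=chroma.y,
        cct=cct,
        cri=cri(descriptor_spd),
        msi=msi,
        ipi=ipi,
        sli=sli,
        distance=distance,
        sky=sky,
        cct_advisory=not cct_is_reliable(cct),
        descriptors_scattered=scattered,
    )


def global_impact(index: float, illuminance: float) -> float:
    """Lux-weighted impact: the shape index times the lamp's illuminance.

    The indices deliberately ignore brightness; multiplying by the delivered
    illuminance restores it when comparing actual installations.
    """
    if index < 0 or illuminance < 0:
        raise ValueError("index and illuminance must be >= 0")
    return index * illuminance
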