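import numpy as np
import pytest

from lampspec.atmosphere import sky_transfer
from lampspec.core import GRID, SpectralCurve


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230705)


@pytest.fixture(scope="session")
def random_spd_factory(rng):
    """Random smooth synthetic SPDs: mixtures of Gaussian bands on the grid."""

    def make(n=1):
        out = []
        for _ in range(n):
            k = rng.integers(2, 6)
            centers = rng.uniform(390, 720, k)
            widths = rng.uniform(8, 120, k)
            amps = rng.uniform(0.1, 1.0, k)
            vals = np.zeros_like(GRID)
            for c, w, a in zip(centers, widths, amps):
                vals += a * np.exp(-0.5 * ((GRID - c) / w) ** 2)
            out.append(SpectralCurve(GRID.copy(), vals + 1e-6, kind="spd"))
        return out

    return make


@pytest.fixture(scope="session")
def clear_transfers():
    """Clear-sky transfer functions at the distances the tests revisit."""
    return {d: sky_transfer(float(d), "clear") for d in (0, 5, 10, 30)}
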