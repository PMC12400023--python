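import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hdrskit.protection import ActionWeighting
from hdrskit.spectral import CANONICAL_GRID, Spectrum

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return CANONICAL_GRID.copy()


@pytest.fixture(scope="session")
def weighting(grid):
    return ActionWeighting.default(grid)


@pytest.fixture
def flat_absorbance(grid):
    def _make(level: float) -> Spectrum:
        return Spectrum(grid, np.full_like(grid, level), "absorbance")

    return _make


@pytest.fixture
def smooth_absorbance(grid):
    """Smooth random-ish absorbance built from a few Gaussian bumps."""

    def _make(seed: int = 0, scale: float = 1.5) -> Spectrum:
        rng = np.random.default_rng(seed)
        centers = rng.uniform(295, 395, size=4)
        widths = rng.uniform(10, 35, size=4)
        heights = rng.uniform(0.1, scale, size=4)
        vals = sum(
            h * np.exp(-0.5 * ((grid - c) / w) ** 2)
            for h, c, w in zip(heights, centers, widths)
        )
        return Spectrum(grid, vals, "absorbance")

    return _make
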