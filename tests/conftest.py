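import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from shiftscreen import gen_background, plant_copy  # noqa: E402

# Shared fixture geometry: 100x100 background over 64 levels with a
# planted 20x15 copy from (10, 12) to (55, 48) -> shift (45, 36).
PLANT_SRC = (10, 12, 20, 15)
PLANT_DEST = (55, 48)
PLANT_SHIFT = (45, 36)


def planted_image(seed: int, offset: int = 0, src=PLANT_SRC, dest=PLANT_DEST):
    """100x100 noise background with one planted copy; returns (img, shift)."""
    bg = gen_background(100, 100, 96, 159, seed)
    return plant_copy(bg, src, dest, offset)


def toroidal_trivial_mask(M: int, N: int, radius: int = 5) -> np.ndarray:
    ii = np.minimum(np.arange(M), M - np.arange(M))[:, None]
    jj = np.minimum(np.arange(N), N - np.arange(N))[None, :]
    return np.maximum(ii, jj) <= radius


def best_nontrivial_shift(scores: np.ndarray, radius: int = 5, direction: str = "high"):
    """Arg-best shift outside the trivial zone, for ground-truth checks."""
    masked = np.ma.array(scores, mask=toroidal_trivial_mask(*scores.shape, radius))
    flat = masked.argmax() if direction == "high" else masked.argmin()
    return tuple(int(v) for v in np.unravel_index(flat, scores.shape))


@pytest.fixture
def rng():
    return np.random.default_rng(20160930)
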