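import numpy as np
import pytest

from somaloc.core import CellCenters
from somaloc.phantom import PhantomConfig, generate_slab


@pytest.fixture(scope="session")
def small_phantom():
    """A 64-cube slab with its ground-truth centers (deterministic)."""
    cfg = PhantomConfig(shape=(64, 64, 64), seed=42)
    vol, centers = generate_slab(cfg)
    return cfg, vol, centers


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def lattice_centers(spacing, shape, jitter=0.0, rng=None):
    """Cells on a cubic lattice with optional jitter — guarantees separation."""
    axes = [np.arange(spacing / 2, s - spacing / 4, spacing) for s in shape]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if jitter and rng is not None:
        pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    return CellCenters(pts, space="voxel")
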