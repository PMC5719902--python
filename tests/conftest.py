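import numpy as np
import pytest

from pcsvn.skeleton import VesselMask
from pcsvn.synthetic import TreeSpec, rasterize, sample_tree


def draw_bar(shape=(40, 60), row0=18, width=3, col0=5, col1=55):
    """Horizontal bar of given pixel width."""
    grid = np.zeros(shape, dtype=bool)
    grid[row0 : row0 + width, col0:col1] = True
    return grid


def draw_plus(size=21, arm=9):
    """Two crossing 1-px lines of length 2*arm+1 (a ready-made skeleton)."""
    grid = np.zeros((size, size), dtype=bool)
    c = size // 2
    grid[c, c - arm : c + arm + 1] = True
    grid[c - arm : c + arm + 1, c] = True
    return grid


@pytest.fixture(scope="session")
def clean_tree():
    """A moderate synthetic tree with its rasterization (session-cached)."""
    spec = TreeSpec(mean_branch_points=25, sd_branch_points=0, mean_thickness_cm=0.15, seed=2)
    truth = sample_tree(spec)
    vessel, disc, cord = rasterize(truth)
    mask = VesselMask(grid=vessel, scale_px_per_cm=35.0, cord_xy=cord, boundary=disc)
    return truth, mask
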