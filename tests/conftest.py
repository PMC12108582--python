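"""Shared fixtures and independent oracles for the test suite."""
import numpy as np
import pytest


def brute_force_thickness(mask: np.ndarray) -> np.ndarray:
    """Exhaustive maximal-sphere local thickness (independent oracle).

    For every candidate centre c, the largest sphere inside the structure
    has radius r(c) = (distance to the nearest background voxel centre)
    - 1/2; thickness(x) = max over centres covering x of 2 r(c). Computed
    by explicit pairwise distances — O(n^2), small grids only.
    """
    mask = np.asarray(mask).astype(bool)
    coords = np.argwhere(mask)
    out = np.zeros(mask.shape)
    if coords.size == 0:
        return out
    bg = np.argwhere(~mask)
    if bg.size:
        d2 = ((coords[:, None, :] - bg[None, :, :]) ** 2).sum(-1)
        r = np.sqrt(d2.min(1)) - 0.5
    else:
        r = np.full(len(coords), np.inf)
    dcc = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    covered = dcc <= r[None, :] + 1e-9
    out[tuple(coords.T)] = (covered * (2.0 * r)[None, :]).max(1)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_blob():
    """A smooth random 3D structure on a small grid."""
    from scipy import ndimage
    g = np.random.default_rng(7).random((16, 16, 16))
    sm = ndimage.gaussian_filter(g, 1.8)
    return (sm > np.quantile(sm, 0.6)).astype(np.uint8)
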