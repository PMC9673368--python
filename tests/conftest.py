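import numpy as np
import pytest

from ovus import synthgen


@pytest.fixture(scope="session")
def small_dataset():
    """40 balanced 64x64 phantoms with default speckle."""
    return synthgen.generate_dataset(20, (64, 64), seed=3)


@pytest.fixture(scope="session")
def clean_image():
    """One noise-free benign phantom plus its spec and seed."""
    spec = synthgen.LesionSpec(center=(0.5, 0.5), semi_axes=(0.25, 0.3))
    return synthgen.render_phantom(spec, (96, 128), seed=7,
                                   speckle_variance=0.0), spec, 7


def nn_rotate(a: np.ndarray, deg: float) -> np.ndarray:
    """Independent nearest-neighbour rotation oracle (matches the library's
    direction convention), zero fill outside the canvas."""
    h, w = a.shape
    cy, cx = (h - 1) / 2, (w - 1) / 2
    th = -np.deg2rad(deg)
    yy, xx = np.mgrid[0:h, 0:w]
    ys = cy + np.cos(th) * (yy - cy) - np.sin(th) * (xx - cx)
    xs = cx + np.sin(th) * (yy - cy) + np.cos(th) * (xx - cx)
    yi, xi = np.round(ys).astype(int), np.round(xs).astype(int)
    ok = (yi >= 0) & (yi < h) & (xi >= 0) & (xi < w)
    out = np.zeros_like(a)
    out[ok] = a[yi[ok], xi[ok]]
    return out
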