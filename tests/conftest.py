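import numpy as np
import pytest

from confinequant.morphometry import Contour
from confinequant.synthetic_data import SceneSpec


def circle_contour(radius=20.0, center=(50.0, 50.0), n=1000, pixel_size_um=1.0):
    t = 2 * np.pi * np.arange(n) / n
    v = np.column_stack(
        [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]
    )
    return Contour(v, pixel_size_um=pixel_size_um)


def ellipse_contour(a, b, center=(100.0, 100.0), angle=0.0, n=1000, pixel_size_um=1.0):
    """Ellipse with semi-axes a, b rotated by angle."""
    t = 2 * np.pi * np.arange(n) / n
    x, y = a * np.cos(t), b * np.sin(t)
    ct, st = np.cos(angle), np.sin(angle)
    v = np.column_stack(
        [center[0] + ct * x - st * y, center[1] + st * x + ct * y]
    )
    return Contour(v, pixel_size_um=pixel_size_um)


def square_contour(side, center=(0.0, 0.0), pixel_size_um=1.0, frame=None):
    h = side / 2.0
    v = np.array(
        [
            [center[0] - h, center[1] - h],
            [center[0] + h, center[1] - h],
            [center[0] + h, center[1] + h],
            [center[0] - h, center[1] + h],
        ]
    )
    return Contour(v, pixel_size_um=pixel_size_um, frame=frame)


@pytest.fixture
def noiseless_spec():
    def make(seed=0, shape=(256, 256), pixel_size_um=0.5, background=0.0):
        return SceneSpec(
            seed=seed,
            image_shape=shape,
            pixel_size_um=pixel_size_um,
            noise_sd=0.0,
            background_level=background,
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
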