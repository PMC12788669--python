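import numpy as np
import pytest

from dbmca.io import CTImage, PixelSpacing
from dbmca.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def default_phantom_100():
    """100 slices under the default configuration (128 px, 0.7 mm/px)."""
    return generate_phantom(PhantomConfig(n_samples=100, seed=1))


@pytest.fixture(scope="session")
def default_phantom_300():
    """300 slices for class-coverage and statistics checks."""
    return generate_phantom(PhantomConfig(n_samples=300, seed=2))


@pytest.fixture()
def unit_spacing():
    return PixelSpacing(1.0, 1.0)


def disc_image(radius: float, center=(64, 64), size: int = 128,
               fg: float = 0.8, bg: float = 0.1, spacing_mm: float = 1.0) -> CTImage:
    """Clean bright disc on a dark background (no noise)."""
    rows, cols = np.mgrid[0:size, 0:size]
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    px = np.where(d2 <= radius**2, fg, bg)
    return CTImage(pixels=px, spacing=PixelSpacing(spacing_mm, spacing_mm))


def two_disc_image(r1=12, r2=12, c1=(40, 40), c2=(40, 80), size=128,
                   spacing_mm=1.0) -> CTImage:
    rows, cols = np.mgrid[0:size, 0:size]
    px = np.full((size, size), 0.1)
    px[(rows - c1[0]) ** 2 + (cols - c1[1]) ** 2 <= r1**2] = 0.8
    px[(rows - c2[0]) ** 2 + (cols - c2[1]) ** 2 <= r2**2] = 0.8
    return CTImage(pixels=px, spacing=PixelSpacing(spacing_mm, spacing_mm))
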