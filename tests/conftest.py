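"""Shared fixtures: programmatic synthetic images, no stored data."""

import numpy as np
import pytest

from carposcan import FruitImage


def make_disc_image(
    size: int = 300,
    center: tuple[float, float] = (150.0, 150.0),
    radius: float = 100.0,
    color: tuple[int, int, int] = (200, 60, 80),
    background: tuple[int, int, int] = (10, 10, 12),
) -> tuple[FruitImage, np.ndarray]:
    """Filled disc on a dark background; returns (image, exact boolean mask)."""
    img = np.zeros((size, size, 3), np.uint8)
    img[:] = background
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    img[mask] = color
    return FruitImage(img, image_id="disc"), mask


def make_ellipse_image(
    size: int = 300,
    center: tuple[float, float] = (150.0, 150.0),
    semi_row: float = 50.0,
    semi_col: float = 100.0,
    color: tuple[int, int, int] = (200, 60, 80),
) -> FruitImage:
    img = np.full((size, size, 3), 10, np.uint8)
    yy, xx = np.mgrid[0:size, 0:size]
    inside = ((yy - center[0]) / semi_row) ** 2 + ((xx - center[1]) / semi_col) ** 2 <= 1.0
    img[inside] = color
    return FruitImage(img, image_id="ellipse")


@pytest.fixture
def disc_image():
    return make_disc_image()


@pytest.fixture
def disc_segmented(disc_image):
    from carposcan import radial_map, segment_fruit

    img, _ = disc_image
    return img, radial_map(segment_fruit(img))
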