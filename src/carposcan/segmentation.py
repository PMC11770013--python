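"""Fruit detection and radial geometry for cross-section images.

A transversal fruit section photographed on a contrasting background is
reduced to a binary flesh mask, its area centroid, and a normalized radial
coordinate ``r`` in [0, 1] for every mask pixel (0 at the centroid, 1 at the
fruit boundary).  All downstream regions of interest are expressed in units
of ``r``, which makes the color features insensitive to fruit size.

Two normalizations are available: ``ray`` (default) divides each pixel's
distance from the centroid by the boundary distance along the same ray,
which adapts to non-circular fruit; ``scalar`` divides by the equivalent
radius sqrt(area/pi), mirroring a plain region-properties implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "FruitImage",
    "SegmentationConfig",
    "SegmentedFruit",
    "SegmentationError",
    "NoFruitError",
    "FruitNotInFrameError",
    "NonRadialMaskError",
    "segment_fruit",
    "radial_map",
]

#: ITU-R BT.709 luma weights used for RGB -> gray reduction.
LUMA_709 = np.array([0.2126, 0.7152, 0.0722])


class SegmentationError(ValueError):
    """Base class for segmentation failures."""


class NoFruitError(SegmentationError):
    """No foreground component of sufficient area was found."""


class FruitNotInFrameError(SegmentationError):
    """The foreground touches all four image borders."""


class NonRadialMaskError(SegmentationError):
    """The centroid falls outside the mask; rays are undefined."""


@dataclass
class FruitImage:
    """An 8-bit sRGB image of a single fruit cross-section.

    ``metadata`` carries the experimental identifiers (genotype, year,
    fruit replicate); empty strings are allowed for standalone use.
    """

    pixels: np.ndarray
    image_id: str = ""
    metadata: dict = field(default_factory=lambda: {"genotype": "", "year": "", "fruit": ""})

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("FruitImage requires an H x W x 3 array")
        if self.pixels.shape[0] < 32 or self.pixels.shape[1] < 32:
            raise ValueError("FruitImage requires H >= 32 and W >= 32")
        for key in ("genotype", "year", "fruit"):
            self.metadata.setdefault(key, "")


@dataclass
class SegmentationConfig:
    """Tunable parameters for fruit detection and radial mapping.

    min_area
        Minimum foreground component area in pixels; smaller components are
        treated as debris and a "no fruit detected" error is raised if no
        component reaches it.
    radius_mode
        ``ray`` for per-ray boundary normalization, ``scalar`` for division
        by the equivalent radius.
    peel_erode_frac
        Fraction of the radius stripped from the outer boundary before
        feature extraction (0 keeps skin pixels at r ~ 1).
    n_rays
        Number of discrete ray directions used to sample the boundary.
    """

    min_area: int = 500
    radius_mode: str = "ray"
    peel_erode_frac: float = 0.0
    n_rays: int = 720

    def __post_init__(self) -> None:
        if self.radius_mode not in ("ray", "scalar"):
            raise ValueError("radius_mode must be 'ray' or 'scalar'")
        if not 0.0 <= self.peel_erode_frac < 1.0:
            raise ValueError("peel_erode_frac must be in [0, 1)")
        if self.n_rays < 16:
            raise ValueError("n_rays must be >= 16")


@dataclass
class SegmentedFruit:
    """Binary fruit mask with centroid and normalized radial coordinate.

    ``radial`` is defined (finite) on mask pixels only; elsewhere NaN.
    """

    mask: np.ndarray
    centroid: tuple[float, float]
    equivalent_radius: float
    radial: np.ndarray | None = None


def _to_gray(pixels: np.ndarray) -> np.ndarray:
    return pixels.astype(np.float64) @ LUMA_709


def segment_fruit(image: FruitImage, config: SegmentationConfig | None = None) -> SegmentedFruit:
    """Detect the fruit as the largest thresholded component.

    Otsu's threshold splits the gray image in two; the foreground polarity
    is the class that does *not* dominate the image border (so both light
    fruit on dark background and the converse work).  Holes (carpel
    cavities, specular highlights) are filled and the largest 8-connected
    component kept.

    Raises
    ------
    NoFruitError
        If no component reaches ``config.min_area``.
    FruitNotInFrameError
        If the selected component touches all four image borders.
    """
    config = config or SegmentationConfig()
    gray = _to_gray(image.pixels)
    if gray.max() == gray.min():
        raise NoFruitError(f"no fruit detected in {image.image_id!r}: uniform image")
    thresh = threshold_otsu(gray)
    fg = gray > thresh
    border = np.concatenate([fg[0, :], fg[-1, :], fg[:, 0], fg[:, -1]])
    if border.mean() > 0.5:  # bright class dominates the border -> fruit is the dark class
        fg = ~fg
    fg = ndimage.binary_fill_holes(fg)
    labels = label(fg, connectivity=2)
    if labels.max() == 0:
        raise NoFruitError(f"no fruit detected in {image.image_id!r}")
    props = regionprops(labels)
    props.sort(key=lambda p: p.area, reverse=True)
    best = props[0]
    if best.area < config.min_area:
        raise NoFruitError(
            f"no fruit detected in {image.image_id!r}: largest component "
            f"{best.area} px < min_area {config.min_area}"
        )
    mask = labels == best.label
    touches = (
        mask[0, :].any() and mask[-1, :].any() and mask[:, 0].any() and mask[:, -1].any()
    )
    if touches:
        raise FruitNotInFrameError(f"fruit not fully in frame in {image.image_id!r}")
    centroid = tuple(best.centroid)
    eq_radius = float(np.sqrt(best.area / np.pi))
    return SegmentedFruit(mask=mask, centroid=centroid, equivalent_radius=eq_radius)


def _ray_boundary_distances(
    mask: np.ndarray, centroid: tuple[float, float], n_rays: int
) -> np.ndarray:
    """Boundary distance from the centroid along ``n_rays`` directions.

    Marches outward in 0.5 px steps sampling the filled mask
    (nearest-neighbor); the boundary sits half a step before the first
    sample outside the mask.
    """
    h, w = mask.shape
    cr, cc = centroid
    angles = np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False)
    max_dist = float(np.hypot(max(cr, h - cr), max(cc, w - cc))) + 1.0
    step = 0.5
    t = np.arange(step, max_dist, step)
    rows = cr + np.sin(angles)[:, None] * t[None, :]
    cols = cc + np.cos(angles)[:, None] * t[None, :]
    ri = np.clip(np.rint(rows).astype(int), 0, h - 1)
    ci = np.clip(np.rint(cols).astype(int), 0, w - 1)
    inside = mask[ri, ci]
    inside &= (rows >= -0.5) & (rows < h - 0.5) & (cols >= -0.5) & (cols < w - 0.5)
    # first step outside the mask along each ray; boundary midway back
    first_out = np.argmin(inside, axis=1)
    all_in = inside.all(axis=1)
    dist = t[first_out] - step / 2.0
    dist[all_in] = t[-1]
    return np.maximum(dist, step / 2.0)


def radial_map(seg: SegmentedFruit, config: SegmentationConfig | None = None) -> SegmentedFruit:
    """Populate ``seg.radial`` with the normalized radial coordinate.

    In ``ray`` mode each pixel's distance to the centroid is divided by the
    boundary distance along its ray, linearly interpolated between the
    ``n_rays`` sampled directions.  In ``scalar`` mode the divisor is the
    equivalent radius.  With ``peel_erode_frac`` > 0 the outer band is
    removed from the mask and ``r`` rescaled to the eroded boundary.

    Raises
    ------
    NonRadialMaskError
        If the centroid pixel is outside the mask (pathological,
        non-star-shaped segmentation) — inspect the segmentation.
    """
    config = config or SegmentationConfig()
    mask = seg.mask
    cr, cc = seg.centroid
    ir, ic = int(round(cr)), int(round(cc))
    if not (0 <= ir < mask.shape[0] and 0 <= ic < mask.shape[1]) or not mask[ir, ic]:
        raise NonRadialMaskError(
            "non-radial mask: centroid lies outside the fruit mask; "
            "inspect the segmentation (multiple fruits or crescent-shaped mask?)"
        )
    rows, cols = np.nonzero(mask)
    dr = rows - cr
    dc = cols - cc
    dist = np.hypot(dr, dc)
    if config.radius_mode == "scalar":
        r = dist / seg.equivalent_radius
    else:
        bound = _ray_boundary_distances(mask, seg.centroid, config.n_rays)
        theta = np.mod(np.arctan2(dr, dc), 2 * np.pi)
        # periodic linear interpolation between sampled directions
        angles = np.linspace(0.0, 2 * np.pi, config.n_rays, endpoint=False)
        r_bound = np.interp(
            theta,
            np.concatenate([angles, [2 * np.pi]]),
            np.concatenate([bound, [bound[0]]]),
        )
        r = dist / r_bound
    radial = np.full(mask.shape, np.nan)
    radial[rows, cols] = r
    if config.peel_erode_frac > 0.0:
        keep_below = 1.0 - config.peel_erode_frac
        new_mask = mask & (np.nan_to_num(radial, nan=np.inf) <= keep_below)
        radial = np.where(new_mask, radial / keep_below, np.nan)
        mask = new_mask
    return SegmentedFruit(
        mask=mask,
        centroid=seg.centroid,
        equivalent_radius=seg.equivalent_radius,
        radial=radial,
    )
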