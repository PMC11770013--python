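"""Annular CIELAB a* histogram features.

The flesh annulus (excluding the central carpel zone, r < 0.30) is split
into three size-normalized rings — inner (30–55 % of the radius), medium
(55–75 %) and outer (75–100 %) — and for each ring a normalized histogram
of the CIELAB a* channel with 10 equal bins on [0, 60] is extracted,
giving a 30-value feature vector per fruit.  The a* channel (green to
magenta) is the single color axis carrying flesh redness, so two summary
descriptors, the mean and standard deviation of a* over the whole flesh
annulus, accompany the histograms and are later used to name the PCA axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2lab

from .segmentation import FruitImage, SegmentedFruit

__all__ = [
    "RingSpec",
    "RingFeatureVector",
    "DegenerateRingError",
    "EmptyROIError",
    "ring_masks",
    "rgb_to_lab",
    "a_histogram",
    "extract_features",
    "feature_names",
]

DEFAULT_RINGS = (("inner", 0.30, 0.55), ("medium", 0.55, 0.75), ("outer", 0.75, 1.00))


class DegenerateRingError(ValueError):
    """A ring contains no pixels."""


class EmptyROIError(ValueError):
    """Histogram requested over an empty pixel set."""


@dataclass
class RingSpec:
    """Ring boundaries as fractions of the fruit radius.

    The carpel zone (r < ``carpel_cut``) is excluded from all rings to
    avoid biasing flesh color by seed cavities.  ``n_bins`` equal-width
    bins span ``a_range`` on the a* axis.  ``normalize`` is ``ring``
    (each ring's histogram sums to 1) or ``global`` (the 30 values sum
    to 1 jointly).
    """

    rings: tuple = DEFAULT_RINGS
    carpel_cut: float = 0.30
    n_bins: int = 10
    a_range: tuple[float, float] = (0.0, 60.0)
    normalize: str = "ring"

    def __post_init__(self) -> None:
        bounds = [self.carpel_cut]
        for _, lo, hi in self.rings:
            bounds.extend([lo, hi])
        if any(b2 < b1 for b1, b2 in zip(bounds, bounds[1:])) or not (
            0.0 <= bounds[0] and bounds[-1] <= 1.0
        ):
            raise ValueError("ring fractions must be increasing within [0, 1]")
        if self.normalize not in ("ring", "global"):
            raise ValueError("normalize must be 'ring' or 'global'")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


@dataclass
class RingFeatureVector:
    """Per-fruit color feature: 3 rings x n_bins a* frequencies + descriptors."""

    image_id: str
    ring_histograms: np.ndarray  # (3, n_bins)
    mean_a: float
    sd_a: float
    ring_pixel_counts: tuple[int, ...]
    metadata: dict = field(default_factory=dict)

    @property
    def flattened(self) -> np.ndarray:
        """Feature order: inner bins 1..n, medium, outer."""
        return self.ring_histograms.ravel()


def feature_names(spec: RingSpec | None = None) -> list[str]:
    """Column names ring{label}_bin{01..n} in flattened order."""
    spec = spec or RingSpec()
    return [
        f"ring{label}_bin{b + 1:02d}"
        for label, _, _ in spec.rings
        for b in range(spec.n_bins)
    ]


def ring_masks(seg: SegmentedFruit, spec: RingSpec | None = None) -> list[np.ndarray]:
    """Boolean masks of the three annular ROIs.

    Ring k holds mask pixels with r_low <= r < r_high; the last ring is
    closed above so boundary pixels (r slightly above 1 from
    discretization) belong to the outer ring.  The rings partition the
    flesh annulus r >= carpel_cut.
    """
    spec = spec or RingSpec()
    if seg.radial is None:
        raise ValueError("segmentation has no radial map; call radial_map first")
    r = seg.radial
    masks = []
    n = len(spec.rings)
    for k, (label_, lo, hi) in enumerate(spec.rings):
        if k == n - 1:
            m = seg.mask & (r >= lo)
        else:
            m = seg.mask & (r >= lo) & (r < hi)
        if not m.any():
            raise DegenerateRingError(f"degenerate ring: {label_!r} contains no pixels")
        masks.append(m)
    return masks


def rgb_to_lab(pixels: np.ndarray) -> np.ndarray:
    """sRGB 8-bit triples -> CIELAB (D65), vectorized over any shape (..., 3)."""
    arr = np.asarray(pixels, dtype=np.float64) / 255.0
    return rgb2lab(arr)


def a_histogram(
    a_values: np.ndarray, n_bins: int = 10, a_range: tuple[float, float] = (0.0, 60.0)
) -> np.ndarray:
    """Normalized histogram of a* values over fixed equal bins.

    Values outside the range are clipped into the end bins, so the
    frequencies always sum to 1 over all input pixels.  Bins are
    half-open [lo, hi) except the last, which is closed.
    """
    vals = np.asarray(a_values, dtype=np.float64).ravel()
    if vals.size == 0:
        raise EmptyROIError("empty ROI: no a* values to bin")
    vals = np.clip(vals, a_range[0], a_range[1])
    counts, _ = np.histogram(vals, bins=n_bins, range=a_range)
    return counts / vals.size


def extract_features(
    image: FruitImage, seg: SegmentedFruit, spec: RingSpec | None = None
) -> RingFeatureVector:
    """Full per-fruit feature extraction.

    The ring histograms are binned on clipped a* values; the mean/SD
    descriptors are computed on the unclipped a* values of the whole
    flesh annulus (union of the three rings).
    """
    spec = spec or RingSpec()
    masks = ring_masks(seg, spec)
    flesh = np.zeros_like(seg.mask)
    for m in masks:
        flesh |= m
    lab = rgb_to_lab(image.pixels[flesh])
    a_flesh = lab[:, 1]
    hists = []
    counts = []
    for m in masks:
        a_ring = rgb_to_lab(image.pixels[m])[:, 1]
        counts.append(int(m.sum()))
        hists.append(a_histogram(a_ring, spec.n_bins, spec.a_range))
    hist = np.vstack(hists)
    if spec.normalize == "global":
        total = sum(counts)
        hist = hist * (np.asarray(counts, dtype=float)[:, None] / total)
    return RingFeatureVector(
        image_id=image.image_id,
        ring_histograms=hist,
        mean_a=float(a_flesh.mean()),
        sd_a=float(a_flesh.std()),
        ring_pixel_counts=tuple(counts),
        metadata=dict(image.metadata),
    )
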