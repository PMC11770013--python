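"""Synthetic fruit cross-section generator with quantitative-genetic ground truth.

Each rendered image is a roughly circular fruit on a dark background with a
distinct central carpel zone (r < 0.30) and a flesh whose CIELAB a* channel
follows a radial color-fading profile

    a*(r) = a_white + depth * logistic((r - rho) / w) + noise,

i.e. white-ish inner flesh turning red towards the periphery, the situation
produced by anthocyanin color fading during fruit development.  ``rho`` is
the radial position of the fading boundary and ``depth = a_red - a_white``
the red/white contrast.  L* and b* are held fixed so a* is the only color
axis that varies, matching the analysis pipeline's exclusive use of a*.

A genetic layer drives the profile: the latent value of fruit k of
genotype i in year j is g_i + year_j + e_ijk with g ~ N(0, sigma_g2) and
e ~ N(0, sigma_r2), mapped affinely onto rho (default) or depth.  An
optional independent per-genotype intensity shift moves a_white and a_red
jointly, emulating overall-redness differences between genotypes.  Truth
tables record every latent and realized parameter, keyed by image_id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from skimage.color import lab2rgb, rgb2lab

from .segmentation import FruitImage

__all__ = [
    "FadingProfile",
    "GeneticScenario",
    "SyntheticTruth",
    "render_fruit",
    "simulate_population",
    "iter_population",
]

#: fixed lightness and yellowness during rendering; chosen so the whole
#: working a* range [-15, 60] stays inside the sRGB gamut.
L_FIXED = 60.0
B_FIXED = 15.0
CARPEL_COLOR = (168, 138, 104)  # light brown seed-cavity zone
BACKGROUND_COLOR = (18, 18, 22)
CARPEL_CUT = 0.30


@dataclass
class FadingProfile:
    """Radial a* profile: a_white inside, a_red outside, logistic transition.

    rho : radial fraction where the transition is centered
    w : transition width as a radial fraction
    """

    a_red: float = 40.0
    a_white: float = 5.0
    rho: float = 0.55
    w: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if self.w <= 0.0:
            raise ValueError("transition width w must be > 0")
        if self.a_red < self.a_white:
            raise ValueError("a_red must be >= a_white")

    @property
    def depth(self) -> float:
        return self.a_red - self.a_white

    def a_star(self, r: np.ndarray) -> np.ndarray:
        z = np.clip((r - self.rho) / self.w, -60.0, 60.0)
        return self.a_white + self.depth / (1.0 + np.exp(-z))


@dataclass
class GeneticScenario:
    """Population design and variance structure for the simulator.

    The latent value g_i + year_j + e_ijk maps affinely onto the profile
    parameter named by ``map_target`` (map_intercept + map_slope * latent),
    clipped to the parameter's valid range with clipping events counted.
    ``intensity_sd`` adds an independent per-genotype a* level shift to
    both a_white and a_red (the non-genetic "overall redness" factor).
    """

    n_genotypes: int = 10
    years: tuple = (2021, 2022, 2023)
    fruits_per_genotype_year: int = 4
    sigma_g2: float = 0.56
    sigma_r2: float = 0.44
    year_effects: tuple = (0.0, 0.3, -0.3)
    map_target: str = "rho"
    map_intercept: float = 0.55
    map_slope: float = 0.035
    rho_clip: tuple[float, float] = (0.10, 0.90)
    depth_clip: tuple[float, float] = (0.0, 55.0)
    intensity_sd: float = 3.0
    base_profile: FadingProfile = field(default_factory=FadingProfile)
    radius_px: int = 60
    radius_jitter: float = 0.10
    irregularity: float = 0.03
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_r2 < 0:
            raise ValueError("variances must be >= 0")
        if self.map_target not in ("rho", "depth"):
            raise ValueError("map_target must be 'rho' or 'depth'")
        if len(self.year_effects) != len(self.years):
            raise ValueError("year_effects must match years in length")
        if self.n_genotypes < 1 or self.fruits_per_genotype_year < 1:
            raise ValueError("population counts must be >= 1")


@dataclass
class SyntheticTruth:
    """Generative ground truth joinable 1:1 to images by image_id."""

    per_image: pd.DataFrame  # image_id, genotype, year, fruit, latent, rho, depth, ...
    per_genotype: pd.DataFrame  # genotype, g_true, intensity_shift
    n_clipped: int  # latent-to-parameter clipping events


def render_fruit(
    profile: FadingProfile,
    radius_px: int = 60,
    irregularity: float = 0.03,
    noise_sd: float = 1.0,
    seed: int = 0,
    image_id: str = "",
    metadata: dict | None = None,
) -> tuple[FruitImage, dict]:
    """Render one fruit; returns (image, stats).

    The boundary is radius * (1 + irregularity * smooth periodic
    perturbation) built from low-order harmonics with seeded amplitudes
    and phases.  Flesh pixels get the profile a* plus Gaussian noise;
    Lab is inverted to sRGB with gamut clipping, and ``stats`` reports
    the fraction of flesh pixels whose a* was altered by > 1 unit.
    Rendering is bit-identical for identical seeds.
    """
    if radius_px < 30:
        raise ValueError("radius_px must be >= 30")
    rng = np.random.default_rng(seed)
    half = int(np.ceil(radius_px * (1.0 + abs(irregularity)))) + 4
    size = 2 * half + 1
    rr, cc = np.mgrid[0:size, 0:size]
    dr = rr - half
    dc = cc - half
    dist = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    # smooth periodic boundary perturbation, normalized to unit amplitude
    harmonics = rng.integers(2, 6, size=3)
    amps = rng.normal(size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    pert = np.zeros_like(theta)
    for k, a, ph in zip(harmonics, amps, phases):
        pert += a * np.cos(k * theta + ph)
    scale = np.abs(pert).max()
    if scale > 0:
        pert /= scale
    boundary = radius_px * (1.0 + irregularity * pert)
    r = dist / boundary
    mask = r <= 1.0
    carpel = mask & (r < CARPEL_CUT)
    flesh = mask & ~carpel

    img = np.empty((size, size, 3), dtype=np.uint8)
    img[:] = BACKGROUND_COLOR
    img[carpel] = CARPEL_COLOR
    a_target = profile.a_star(r[flesh]) + rng.normal(0.0, noise_sd, size=int(flesh.sum()))
    lab = np.stack(
        [np.full_like(a_target, L_FIXED), a_target, np.full_like(a_target, B_FIXED)],
        axis=-1,
    )
    rgb = np.clip(lab2rgb(lab[None])[0], 0.0, 1.0)
    flesh_u8 = np.rint(rgb * 255.0).astype(np.uint8)
    img[flesh] = flesh_u8
    a_back = rgb2lab(flesh_u8[None].astype(np.float64) / 255.0)[0, :, 1]
    clipped = int((np.abs(a_back - a_target) > 1.0).sum())
    stats = {
        "n_flesh": int(flesh.sum()),
        "n_clipped": clipped,
        "clip_fraction": clipped / max(int(flesh.sum()), 1),
    }
    fruit = FruitImage(
        pixels=img, image_id=image_id, metadata=metadata or {"genotype": "", "year": "", "fruit": ""}
    )
    return fruit, stats


def _draw_truth(scenario: GeneticScenario) -> SyntheticTruth:
    """Sample the genetic layer and realized profile parameters (no rendering).

    Every draw comes from a keyed substream (seed, tag, genotype[, year,
    fruit]) so enlarging the population never reshuffles existing rows.
    """
    sc = scenario
    g = np.empty(sc.n_genotypes)
    shift = np.zeros(sc.n_genotypes)
    for i in range(sc.n_genotypes):
        rng_i = np.random.default_rng([sc.seed, 1, i])
        g[i] = rng_i.normal(0.0, np.sqrt(sc.sigma_g2))
        if sc.intensity_sd > 0:
            shift[i] = rng_i.normal(0.0, sc.intensity_sd)
    rows = []
    n_clipped = 0
    idx = 0
    for i in range(sc.n_genotypes):
        for j, (year, yeff) in enumerate(zip(sc.years, sc.year_effects)):
            for k in range(sc.fruits_per_genotype_year):
                e = np.random.default_rng([sc.seed, 2, i, j, k]).normal(
                    0.0, np.sqrt(sc.sigma_r2)
                )
                latent = g[i] + yeff + e
                mapped = sc.map_intercept + sc.map_slope * latent
                if sc.map_target == "rho":
                    lo, hi = sc.rho_clip
                    rho = float(np.clip(mapped, lo, hi))
                    if mapped != rho:
                        n_clipped += 1
                    depth = sc.base_profile.depth
                    a_white = sc.base_profile.a_white + shift[i]
                else:
                    lo, hi = sc.depth_clip
                    depth = float(np.clip(mapped, lo, hi))
                    if mapped != depth:
                        n_clipped += 1
                    rho = sc.base_profile.rho
                    a_white = sc.base_profile.a_white + shift[i]
                image_id = f"g{i:04d}_y{year}_f{k}"
                rows.append(
                    (image_id, f"G{i:04d}", year, k, latent, rho, depth, a_white, i, j, k)
                )
                idx += 1
    per_image = pd.DataFrame(
        rows,
        columns=[
            "image_id", "genotype", "year", "fruit",
            "latent", "rho", "depth", "a_white", "gi", "yj", "fk",
        ],
    )
    per_genotype = pd.DataFrame(
        {
            "genotype": [f"G{i:04d}" for i in range(sc.n_genotypes)],
            "g_true": g,
            "intensity_shift": shift,
        }
    )
    return SyntheticTruth(per_image=per_image, per_genotype=per_genotype, n_clipped=n_clipped)


def iter_population(
    scenario: GeneticScenario,
) -> tuple[SyntheticTruth, Iterator[FruitImage]]:
    """Ground truth plus a lazy image stream (memory-friendly).

    Per-image randomness comes from a counter-based substream
    ``default_rng([seed, substream])`` so adding images never reshuffles
    existing ones.
    """
    truth = _draw_truth(scenario)
    sc = scenario

    def gen() -> Iterator[FruitImage]:
        for row in truth.per_image.itertuples():
            rng = np.random.default_rng([sc.seed, 3, row.gi, row.yj, row.fk])
            radius = int(round(sc.radius_px * (1.0 + sc.radius_jitter * rng.uniform(-1, 1))))
            radius = max(radius, 30)
            profile = FadingProfile(
                a_red=row.a_white + row.depth,
                a_white=row.a_white,
                rho=row.rho,
                w=sc.base_profile.w,
            )
            img, _ = render_fruit(
                profile,
                radius_px=radius,
                irregularity=sc.irregularity,
                noise_sd=sc.noise_sd,
                seed=[sc.seed, 4, row.gi, row.yj, row.fk],
                image_id=row.image_id,
                metadata={"genotype": row.genotype, "year": str(row.year), "fruit": str(row.fruit)},
            )
            yield img

    return truth, gen()


def simulate_population(
    scenario: GeneticScenario,
) -> tuple[list[FruitImage], SyntheticTruth]:
    """Materialized population: (images, truth)."""
    truth, stream = iter_population(scenario)
    return list(stream), truth
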