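"""Synthetic brightfield bead images and a bead-counting pipeline.

Monodisperse 2.7 um superparamagnetic beads imaged in brightfield appear as
dark, nearly circular spots on a bright background, so counting reduces to
thresholding, connected components, and an area rule.  The module provides
both halves: a seeded generator of synthetic bead images (anti-aliased dark
disks at random non-overlapping positions plus Gaussian noise) that supplies
ground truth, and the counting pipeline itself.

Coordinate convention: pixel-centred, origin at the top-left corner, x
rightward (columns), y downward (rows).

Merged objects whose area is close to an integer multiple ``k`` of the
single-bead area are counted as ``k`` beads up to a configurable cap
(``cluster_policy="split"``, the default) or as one object
(``cluster_policy="single"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops

from .errors import InvalidInputError, PlacementError


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of a synthetic brightfield bead image.

    Intensities are on the 16-bit scale (0..65535).  ``pixel_size`` is
    um/px (default matches a 20x objective on a typical sCMOS sensor).
    """

    width: int = 512
    height: int = 512
    pixel_size: float = 0.33
    bead_radius: float = 1.35
    n_beads: int = 0
    background_level: float = 40000.0
    bead_contrast: float = 20000.0
    noise_sd: float = 500.0
    min_separation: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise InvalidInputError("image dimensions must be >= 1")
        if self.n_beads < 0:
            raise InvalidInputError("n_beads must be >= 0")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if not self.pixel_size > 0 or not self.bead_radius > 0:
            raise InvalidInputError("pixel_size and bead_radius must be > 0")

    @property
    def radius_px(self) -> float:
        return self.bead_radius / self.pixel_size


@dataclass(frozen=True)
class BeadCountReport:
    """Result of the counting pipeline.

    ``centroids`` holds one (x, y) pixel coordinate per counted bead (the
    shared object centroid is repeated for beads split out of one merged
    object); ``rejected_objects`` maps rejection reasons to object counts.
    """

    count: int
    centroids: np.ndarray
    rejected_objects: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        c = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "centroids", c)
        if self.count != c.shape[0]:
            raise InvalidInputError("count must equal the number of centroids")

    def to_dict(self) -> dict:
        return {
            "count": self.count,
            "centroids_xy_px": self.centroids.tolist(),
            "rejected_objects": dict(self.rejected_objects),
        }


def _place_centers(spec: SyntheticImageSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform non-overlapping centres via grid-accelerated rejection."""
    r_px = spec.radius_px
    sep_px = max(spec.min_separation / spec.pixel_size, 1e-9)
    margin = r_px + 1.0
    lo_x, hi_x = margin, spec.width - margin
    lo_y, hi_y = margin, spec.height - margin
    if spec.n_beads > 0 and (hi_x <= lo_x or hi_y <= lo_y):
        raise PlacementError("image too small for the bead radius")

    cell = sep_px
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 200 * max(spec.n_beads, 1)
    while len(centers) < spec.n_beads:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {len(centers)} of {spec.n_beads} beads at "
                f"min_separation {spec.min_separation} um"
            )
        attempts += 1
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        cx, cy = int(x / cell), int(y / cell)
        ok = True
        for gx in range(cx - 1, cx + 2):
            for gy in range(cy - 1, cy + 2):
                for (px, py) in grid.get((gx, gy), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < sep_px**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            centers.append((x, y))
            grid.setdefault((cx, cy), []).append((x, y))
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def render_beads(
    spec: SyntheticImageSpec, return_centers: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Render a grayscale bead image (float array on the 16-bit scale).

    Beads are dark anti-aliased disks (per-pixel coverage computed from the
    distance to the centre) on a bright background, with additive Gaussian
    noise.  Deterministic for a given spec (the seed is part of the spec).
    """
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(spec, rng)
    img = np.full((spec.height, spec.width), spec.background_level, dtype=float)
    r_px = spec.radius_px
    for x, y in centers:
        x0 = max(int(np.floor(x - r_px - 2)), 0)
        x1 = min(int(np.ceil(x + r_px + 2)) + 1, spec.width)
        y0 = max(int(np.floor(y - r_px - 2)), 0)
        y1 = min(int(np.ceil(y + r_px + 2)) + 1, spec.height)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx - x, yy - y)
        coverage = np.clip(r_px + 0.5 - dist, 0.0, 1.0)
        img[y0:y1, x0:x1] -= spec.bead_contrast * coverage
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 65535.0)
    if return_centers:
        return img, centers
    return img


def save_image(img: np.ndarray, path) -> None:
    """Write a 16-bit grayscale PNG/TIFF."""
    import imageio.v3 as iio

    iio.imwrite(path, np.clip(img, 0, 65535).astype(np.uint16))


def load_image(path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path), dtype=float)


def count_beads(
    image: np.ndarray,
    pixel_size: float,
    expected_radius: float = 1.35,
    tolerance: float = 0.4,
    cluster_cap: int = 3,
    cluster_policy: str = "split",
    smooth_sigma: float = 1.0,
) -> BeadCountReport:
    """Count beads in a single-channel brightfield image.

    Pipeline: Gaussian smoothing -> automatic intensity threshold (Otsu,
    with a robust median/MAD fallback when Otsu would flag an implausibly
    large foreground, as on a bead-free image) -> connected components ->
    area rule: an object of area close to ``k`` times the expected bead
    area counts as ``k`` beads (``k <= cluster_cap``); everything else is
    rejected with a reason.  Counting is invariant to a global intensity
    offset.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise InvalidInputError("image must be a non-empty single-channel array")
    if not np.all(np.isfinite(img)):
        raise InvalidInputError("image contains non-finite values")
    if img.max() == img.min():
        raise InvalidInputError("degenerate image: constant intensity")
    if not pixel_size > 0 or not expected_radius > 0:
        raise InvalidInputError("pixel_size and expected_radius must be > 0")
    if cluster_policy not in ("split", "single"):
        raise InvalidInputError("cluster_policy must be 'split' or 'single'")

    smoothed = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    thr = threshold_otsu(smoothed)
    mask = smoothed < thr  # beads are dark
    if mask.mean() > 0.25:
        # no real foreground class: fall back to a robust outlier threshold
        med = np.median(smoothed)
        mad = np.median(np.abs(smoothed - med))
        mask = smoothed < med - 5.0 * 1.4826 * max(mad, 1e-12)

    expected_area = np.pi * (expected_radius / pixel_size) ** 2
    counted: list[tuple[float, float]] = []
    rejected: dict[str, int] = {}
    total = 0
    for region in regionprops(label(mask, connectivity=2)):
        ratio = region.area / expected_area
        k = int(round(ratio))
        if k < 1:
            rejected["too_small"] = rejected.get("too_small", 0) + 1
            continue
        if k > cluster_cap:
            rejected["too_large"] = rejected.get("too_large", 0) + 1
            continue
        if abs(ratio - k) > tolerance * k:
            rejected["irregular_area"] = rejected.get("irregular_area", 0) + 1
            continue
        row, col = region.centroid
        n = k if cluster_policy == "split" else 1
        counted.extend([(col, row)] * n)
        total += n
    return BeadCountReport(
        count=total,
        centroids=np.asarray(counted, dtype=float).reshape(-1, 2),
        rejected_objects=rejected,
    )
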