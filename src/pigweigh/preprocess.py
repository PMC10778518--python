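"""Filters that isolate a single animal's surface points from a raw scene.

The chain mirrors standard depth-camera livestock preprocessing: a depth band
removes floor and wall points, a planar polygon keeps the region of interest,
Otsu color thresholding drops off-color clutter, and a statistical
outlier filter removes sensor speckle. A seeded random subsample fixes the
cloud at the canonical network input size (1500 points), a deterministic
neck-crop removes the head for volume work, and uniform point jitter provides
training augmentation.

Every filter returns a *subsequence* of its input: order is preserved, colors
travel with their points, and no point is invented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .cloud import PointCloud, PointCloudError

logger = logging.getLogger(__name__)

__all__ = [
    "DepthBand",
    "PlanarPolygon",
    "OutlierParams",
    "DegenerateInputError",
    "depth_band_filter",
    "polygon_roi_filter",
    "otsu_threshold",
    "color_segment",
    "remove_statistical_outliers",
    "random_subsample",
    "crop_head",
    "jitter_points",
]

CANONICAL_N_POINTS = 1500


class DegenerateInputError(ValueError):
    """Input admits no meaningful result (e.g. constant intensities)."""


@dataclass(frozen=True)
class DepthBand:
    """Keep points with z in [z_min, z_max] (camera-frame depth, meters)."""

    z_min: float
    z_max: float

    def __post_init__(self) -> None:
        if not (0.0 < self.z_min < self.z_max):
            raise ValueError(f"need 0 < z_min < z_max, got ({self.z_min}, {self.z_max})")


@dataclass(frozen=True)
class PlanarPolygon:
    """Simple (non-self-intersecting) xy polygon, vertices in meters."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if not Polygon(verts).is_valid:
            raise ValueError("polygon must be simple (non-self-intersecting)")
        object.__setattr__(self, "vertices", verts)

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class OutlierParams:
    """Statistical outlier removal parameters.

    A point is removed when its mean distance to its ``k_neighbors`` nearest
    neighbors exceeds the global mean by more than ``std_ratio`` standard
    deviations.
    """

    k_neighbors: int = 20
    std_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.std_ratio <= 0:
            raise ValueError("std_ratio must be positive")


def depth_band_filter(cloud: PointCloud, band: DepthBand) -> PointCloud:
    """Keep points with ``band.z_min <= z <= band.z_max``."""
    z = cloud.points[:, 2]
    return cloud.select((z >= band.z_min) & (z <= band.z_max))


def polygon_roi_filter(cloud: PointCloud, roi: PlanarPolygon) -> PointCloud:
    """Keep points whose (x, y) lies inside or on the ROI polygon boundary."""
    if len(cloud) == 0:
        return cloud
    pts = shapely.points(cloud.points[:, 0], cloud.points[:, 1])
    mask = shapely.covers(roi.as_shapely(), pts)
    return cloud.select(mask)


def otsu_threshold(values: np.ndarray) -> int:
    """Otsu's threshold over the 256-bin 8-bit histogram of ``values``.

    Returns the bin ``t`` maximizing between-class variance for the split
    ``{v <= t} | {v > t}``; the smallest such ``t`` on ties. Values are
    clipped/rounded to integers in [0, 255].
    """
    v = np.clip(np.rint(np.asarray(values, dtype=np.float64)), 0, 255).astype(np.int64)
    if v.size < 2 or np.all(v == v.flat[0]):
        raise DegenerateInputError("otsu_threshold needs at least 2 distinct values")
    hist = np.bincount(v.ravel(), minlength=256).astype(np.float64)
    p = hist / hist.sum()
    omega = np.cumsum(p)                      # class-0 probability for t = 0..255
    mu = np.cumsum(p * np.arange(256))        # class-0 first moment
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    between[~np.isfinite(between)] = -np.inf  # one-sided splits carry no information
    return int(np.argmax(between))


def _grayscale(colors: np.ndarray) -> np.ndarray:
    # ITU-R BT.601 luma; the pipeline only needs a scalar intensity for Otsu
    return colors @ np.array([0.299, 0.587, 0.114])


def color_segment(cloud: PointCloud) -> PointCloud:
    """Keep the majority-intensity side of the Otsu threshold.

    The animal dominates the scene after the spatial filters, so the class
    holding more points is kept; exact ties go to the brighter class (the
    animals image lighter than background shadow).
    """
    if not cloud.has_colors:
        raise PointCloudError("color_segment requires per-point colors")
    gray = _grayscale(cloud.colors)
    try:
        t = otsu_threshold(gray)
    except DegenerateInputError:
        logger.warning(
            "color_segment: constant intensity in %r, returning cloud unchanged",
            cloud.source_id,
        )
        return cloud
    dark = gray <= t
    n_dark = int(dark.sum())
    keep_bright = (len(cloud) - n_dark) >= n_dark  # tie -> brighter class
    return cloud.select(~dark if keep_bright else dark)


def remove_statistical_outliers(
    cloud: PointCloud, params: OutlierParams = OutlierParams()
) -> PointCloud:
    """Drop points whose mean k-nearest-neighbor distance is anomalous.

    Not idempotent: removing points changes the neighbor statistics, so a
    second application may remove more.
    """
    k = params.k_neighbors
    if len(cloud) <= k:
        raise PointCloudError(
            f"outlier removal needs > {k} points, got {len(cloud)}"
        )
    tree = cKDTree(cloud.points)
    # k+1 because each point is its own nearest neighbor at distance 0
    dists, _ = tree.query(cloud.points, k=k + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    cutoff = mean_d.mean() + params.std_ratio * mean_d.std()
    return cloud.select(mean_d <= cutoff)


def random_subsample(
    cloud: PointCloud,
    n: int = CANONICAL_N_POINTS,
    seed: int = 0,
    pad: bool = False,
) -> PointCloud:
    """Uniform random subsample (without replacement) to exactly ``n`` points.

    With ``pad=True`` a cloud smaller than ``n`` is padded by duplicating
    uniformly chosen points (fixed-size network input requires exactly ``n``);
    by default a too-small cloud is an error. Selected points keep their
    input order, so the result is a subsequence when no padding occurs.
    """
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    if len(cloud) < n:
        if not pad:
            raise PointCloudError(
                f"cloud {cloud.source_id!r} has {len(cloud)} < {n} points (use pad)"
            )
        extra = rng.integers(0, len(cloud), size=n - len(cloud))
        idx = np.sort(np.concatenate([np.arange(len(cloud)), extra]))
        return cloud.select(idx)
    idx = np.sort(rng.choice(len(cloud), size=n, replace=False))
    return cloud.select(idx)


def crop_head(
    cloud: PointCloud,
    slice_width: float = 0.02,
    anterior_fraction: float = 0.35,
) -> PointCloud:
    """Remove the head by cutting at the narrowest neck slice.

    Deterministic proxy for manual neck cropping: project points onto the
    first principal axis in the xy plane, build a width profile (y-spread per
    ``slice_width`` slice along the axis), call "anterior" the
    ``anterior_fraction`` of the axis on the end with the smaller mean width
    (the head end), and drop everything beyond the minimum-width slice inside
    that region.
    """
    if len(cloud) < 100:
        raise PointCloudError("crop_head needs >= 100 points to estimate a body axis")
    xy = cloud.points[:, :2]
    centered = xy - xy.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] < 1e-12:
        raise PointCloudError("crop_head: degenerate xy geometry, no principal axis")
    axis = evecs[:, -1]           # major axis
    ortho = evecs[:, 0]
    s = centered @ axis           # along-axis coordinate
    w = centered @ ortho          # across-axis coordinate
    lo, hi = s.min(), s.max()
    n_slices = max(int(np.ceil((hi - lo) / slice_width)), 3)
    bins = np.clip(((s - lo) / slice_width).astype(int), 0, n_slices - 1)
    widths = np.full(n_slices, np.nan)
    for b in range(n_slices):
        sel = bins == b
        if sel.sum() >= 3:
            widths[b] = w[sel].max() - w[sel].min()
    valid = np.isfinite(widths)
    if valid.sum() < 3:
        raise PointCloudError("crop_head: too few populated slices")
    # head end = the end with the smaller mean width over its anterior_fraction
    n_ant = max(int(round(n_slices * anterior_fraction)), 1)
    low_mean = np.nanmean(widths[:n_ant]) if np.isfinite(widths[:n_ant]).any() else np.inf
    high_mean = (
        np.nanmean(widths[-n_ant:]) if np.isfinite(widths[-n_ant:]).any() else np.inf
    )
    head_high = high_mean <= low_mean
    region = np.arange(n_slices - n_ant, n_slices) if head_high else np.arange(n_ant)
    region = region[np.isfinite(widths[region])]
    if region.size == 0:
        return cloud
    neck = region[np.argmin(widths[region])]
    keep = bins <= neck if head_high else bins >= neck
    return cloud.select(keep)


def jitter_points(cloud: PointCloud, amplitude: float = 0.005, seed: int = 0) -> PointCloud:
    """Perturb each coordinate by an independent uniform draw in [-a, +a].

    Standard point-set training augmentation: geometry changes slightly, the
    weight label does not. Colors and point count are unchanged.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0 or len(cloud) == 0:
        return cloud
    rng = np.random.default_rng(seed)
    delta = rng.uniform(-amplitude, amplitude, size=cloud.points.shape)
    return cloud.with_points(cloud.points + delta)
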