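"""2.5D projected volume and the linear weight~volume baseline.

The projected volume of an animal is the volume of the solid between its
top-view surface and the pen floor: points are binned on a regular xy grid
(default step 1 cm), each cell takes the *maximum* height above the floor
plane of the points falling in it, and the volume is ``step^2 * sum(heights)``.
The floor is the constant plane at camera-frame depth ``L`` (2.7 m in the
study geometry), so a point at depth z has height ``L - z``.

Body volume is then regressed against scale weight with ordinary least
squares, the classical machine-vision baseline the deep model is compared to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cloud import PointCloud, PointCloudError

__all__ = [
    "VolumeGridSpec",
    "HeightGrid",
    "LinearFit",
    "rasterize_height_grid",
    "grid_volume",
    "cloud_projected_volume",
    "fit_weight_volume",
    "predict_weight_from_volume",
]

DEFAULT_PLANE_DISTANCE = 2.7  # camera height above the pen floor, meters


@dataclass(frozen=True)
class VolumeGridSpec:
    """Rasterization parameters: grid step and floor-plane distance (meters).

    Projection is along the camera z axis; the grid is anchored at the
    cloud's (min x, min y) with half-open cells, making results
    translation-covariant and deterministic.
    """

    step: float = 0.01
    plane_distance: float = DEFAULT_PLANE_DISTANCE

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if self.plane_distance <= 0:
            raise ValueError("plane_distance must be positive")


@dataclass(frozen=True)
class HeightGrid:
    """Per-cell maximum heights above the floor plane (meters; empty cells 0)."""

    origin: tuple[float, float]
    step: float
    heights: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=np.float64)
        if h.ndim != 2:
            raise ValueError("heights must be a 2D array")
        if np.any(h < 0):
            raise ValueError("heights must be nonnegative")
        object.__setattr__(self, "heights", h)


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of weight (kg) on volume (m^3)."""

    slope: float
    intercept: float
    r_squared: float
    rmse: float
    n: int


def rasterize_height_grid(cloud: PointCloud, spec: VolumeGridSpec = VolumeGridSpec()) -> HeightGrid:
    """Bin a cloud into a height grid: cell value = max over its points of L - z.

    Cell membership is half-open: point p falls in cell
    ``floor((p - origin) / step)``. Points exactly at the floor (z == L) are
    legal and contribute zero height; points below the floor (z > L) are an
    error.
    """
    if len(cloud) == 0:
        raise PointCloudError("cannot rasterize an empty cloud")
    L = spec.plane_distance
    z = cloud.points[:, 2]
    if np.any(z > L + 1e-12):
        raise PointCloudError(
            f"{int((z > L + 1e-12).sum())} points lie below the floor plane (z > {L})"
        )
    heights_pts = np.maximum(L - z, 0.0)
    xy = cloud.points[:, :2]
    origin = xy.min(axis=0)
    idx = np.floor((xy - origin) / spec.step).astype(np.int64)
    nx, ny = idx.max(axis=0) + 1
    grid = np.zeros((nx, ny))
    np.maximum.at(grid, (idx[:, 0], idx[:, 1]), heights_pts)
    return HeightGrid(origin=(float(origin[0]), float(origin[1])), step=spec.step, heights=grid)


def grid_volume(grid: HeightGrid) -> float:
    """Projected volume in m^3: ``step^2 * sum(cell heights)``."""
    return float(grid.step ** 2 * grid.heights.sum())


def cloud_projected_volume(cloud: PointCloud, spec: VolumeGridSpec = VolumeGridSpec()) -> float:
    """Convenience: rasterize and integrate in one call."""
    return grid_volume(rasterize_height_grid(cloud, spec))


def fit_weight_volume(pairs: Sequence[tuple[float, float]]) -> LinearFit:
    """OLS of weight on volume with intercept.

    ``r_squared = 1 - SS_res / SS_tot`` and ``rmse = sqrt(SS_res / n)``
    (population form, no degrees-of-freedom correction).
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("need >= 2 (volume, weight) pairs")
    vol, wt = arr[:, 0], arr[:, 1]
    if np.ptp(vol) == 0:
        raise ValueError("singular fit: all volumes identical")
    slope, intercept = np.polyfit(vol, wt, deg=1)
    resid = wt - (slope * vol + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((wt - wt.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        rmse=float(np.sqrt(ss_res / len(arr))),
        n=len(arr),
    )


def predict_weight_from_volume(fit: LinearFit, volume: float | np.ndarray):
    """Apply the fitted line: ``slope * volume + intercept`` (kg)."""
    return fit.slope * np.asarray(volume, dtype=np.float64) + fit.intercept
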