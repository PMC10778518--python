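"""Synthetic top-down pig point clouds with known geometry and weight labels.

The study's animals were imaged by a depth camera 2.7 m above a holding pen;
its data is private, so this module generates stand-in clouds with known
ground truth for every stage of the pipeline. A standing pig seen from above
is modeled as the upper half of a *superellipsoid* torso (half-axes
``half_length x half_width x half_height``, cross-section squareness
``shape_exponent``) with its cut plane resting on the floor, joined through
a narrowed elliptical neck to a half-ellipsoid head that can pitch up or
down about the neck joint. Legs are omitted (invisible from directly above),
and resting the belly plane on the floor makes the analytic shape's own
volume identical to its 2.5D projected volume — the quantity the whole
pipeline estimates.

A depth camera returns one sample per line of sight, so clouds are sampled on
the camera-visible composite *top surface* (one z per xy, occluded lower
surfaces never appear). Weight labels follow the premise that body mass
tracks body volume: ``weight = density_coeff x reference projected volume +
noise``, where the reference volume comes from a fine independent numerical
integration of the analytic height field — never from the rasterizer under
test.

Sensor artifacts emulate the two failure modes seen in the study's hardware:
a low-frequency wavy displacement of the depth field, and large missing
chunks of points, plus isotropic per-point noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .cloud import PointCloud, WeightRecord
from .preprocess import CANONICAL_N_POINTS, random_subsample
from .volume import DEFAULT_PLANE_DISTANCE

__all__ = [
    "SyntheticPigSpec",
    "SensorArtifactSpec",
    "sample_pig_surface",
    "reference_projected_volume",
    "assign_weight",
    "apply_sensor_artifacts",
    "make_dataset",
    "make_test_scene",
    "DEFAULT_PEN_DIMS",
]

DEFAULT_PEN_DIMS = (2.9, 1.5)  # holding-pen major x minor axis, meters

# per-point surface colors (RGB), roughly matching light pig skin vs dark clutter
PIG_COLOR = np.array([205, 175, 160])
FLOOR_COLOR = np.array([120, 115, 110])
WALL_COLOR = np.array([90, 85, 80])
BLOB_COLOR = np.array([70, 45, 30])


@dataclass(frozen=True)
class SyntheticPigSpec:
    """Parameters of one synthetic pig and its pose in the pen.

    Half-axes are meters; ``shape_exponent >= 2`` controls cross-section
    squareness (2 = ellipsoid, larger = boxier). ``head_scale`` and
    ``neck_scale`` are fractions of the body half-axes. ``yaw`` (radians) and
    ``xy_offset`` (meters) place the animal in the pen; ``head_pitch``
    (radians, negative = lowered) is the head posture. ``density_coeff``
    (kg/m^3) maps reference projected volume to weight with Gaussian noise
    ``weight_noise_sd`` (kg).
    """

    half_length: float = 0.55
    half_width: float = 0.19
    half_height: float = 0.26
    shape_exponent: float = 2.5
    head_scale: float = 0.35
    neck_scale: float = 0.18
    yaw: float = 0.0
    xy_offset: tuple[float, float] = (0.0, 0.0)
    head_pitch: float = 0.0
    density_coeff: float = 1000.0
    weight_noise_sd: float = 2.0
    seed: int = 0
    plane_distance: float = DEFAULT_PLANE_DISTANCE

    def __post_init__(self) -> None:
        if min(self.half_length, self.half_width, self.half_height) <= 0:
            raise ValueError("half-axes must be positive")
        if self.shape_exponent < 2:
            raise ValueError("shape_exponent must be >= 2")
        if not (0.0 <= self.head_scale < 0.6):
            raise ValueError("head_scale must lie in [0, 0.6)")
        if not (0.0 < self.neck_scale < 0.5):
            raise ValueError("neck_scale must lie in (0, 0.5)")
        if self.density_coeff <= 0:
            raise ValueError("density_coeff must be positive")
        if self.weight_noise_sd < 0:
            raise ValueError("weight_noise_sd must be >= 0")


@dataclass(frozen=True)
class SensorArtifactSpec:
    """Depth-sensor artifact model: wavy field, chunk dropout, point noise."""

    wave_amplitude: float = 0.0    # meters
    wave_frequency: float = 0.0    # cycles per meter across the xy plane
    dropout_chunks: int = 0        # number of missing discs
    dropout_radius: float = 0.0    # meters
    point_noise_sd: float = 0.0    # meters, isotropic

    def __post_init__(self) -> None:
        if min(self.wave_amplitude, self.wave_frequency,
               self.dropout_radius, self.point_noise_sd) < 0 or self.dropout_chunks < 0:
            raise ValueError("artifact parameters must be nonnegative")

    @property
    def is_null(self) -> bool:
        return (self.wave_amplitude == 0 and self.dropout_chunks == 0
                and self.point_noise_sd == 0)


MILD_ARTIFACTS = SensorArtifactSpec(
    wave_amplitude=0.004, wave_frequency=2.0,
    dropout_chunks=2, dropout_radius=0.06, point_noise_sd=0.002,
)


# --------------------------------------------------------------------------
# analytic height field (body frame: z up, floor at z = 0)

def _height_field(spec: SyntheticPigSpec) -> tuple[Callable[[np.ndarray, np.ndarray], np.ndarray], np.ndarray]:
    """Return (H, bbox): H(x, y) -> top-surface height (nan outside footprint).

    The composite is the pointwise max over body, neck and head top surfaces,
    clipped at the floor. bbox is ((xmin, xmax), (ymin, ymax)) in body frame.
    """
    a, b, c = spec.half_length, spec.half_width, spec.half_height
    p = spec.shape_exponent

    def body_h(x, y):
        u = np.abs(x / a) ** p + np.abs(y / b) ** p
        with np.errstate(invalid="ignore"):
            h = c * np.where(u < 1.0, 1.0 - u, np.nan) ** (1.0 / p)
        return h

    parts = [body_h]
    xmax_extra = 0.0
    if spec.head_scale > 0:
        ah, bh, ch = spec.head_scale * a, spec.head_scale * b, spec.head_scale * c
        bn, cn = spec.neck_scale * b, spec.neck_scale * c
        neck_len = 0.7 * ah
        x0, x1 = 0.8 * a, a + neck_len

        def neck_h(x, y):
            inside = (x >= x0) & (x <= x1) & (np.abs(y) < bn)
            with np.errstate(invalid="ignore"):
                arc = cn * np.sqrt(np.where(inside, 1.0 - (y / bn) ** 2, np.nan))
            return arc

        # head ellipsoid pitched about the neck-tip pivot on the floor plane
        theta = spec.head_pitch
        pivot = np.array([x1, 0.0, 0.0])
        center0 = np.array([x1 + 0.85 * ah, 0.0, 0.0])
        # pitch rotation about the y axis; negative theta lowers the head
        rot = np.array(
            [[np.cos(theta), 0.0, -np.sin(theta)],
             [0.0, 1.0, 0.0],
             [np.sin(theta), 0.0, np.cos(theta)]]
        )
        center = pivot + rot @ (center0 - pivot)
        quad = rot @ np.diag([ah ** -2, bh ** -2, ch ** -2]) @ rot.T

        def head_h(x, y):
            dx, dy = x - center[0], y - center[1]
            A = quad[2, 2]
            B = 2.0 * (quad[0, 2] * dx + quad[1, 2] * dy)
            C = quad[0, 0] * dx ** 2 + 2 * quad[0, 1] * dx * dy + quad[1, 1] * dy ** 2 - 1.0
            disc = B ** 2 - 4 * A * C
            with np.errstate(invalid="ignore"):
                z = center[2] + (-B + np.sqrt(np.where(disc >= 0, disc, np.nan))) / (2 * A)
            return z

        parts += [neck_h, head_h]
        xmax_extra = neck_len + 2.0 * ah + abs(np.sin(theta)) * 2.0 * ch

    def height(x, y):
        h = parts[0](x, y)
        for part in parts[1:]:
            h = np.fmax(h, part(x, y))  # fmax ignores NaN: union of footprints
        return np.where(h > 0, h, np.nan)  # floor cut; fully submerged columns vanish

    bbox = np.array([[-a, a + xmax_extra], [-b, b]])
    return height, bbox


def _pose_xy(spec: SyntheticPigSpec, xy: np.ndarray) -> np.ndarray:
    cy, sy = np.cos(spec.yaw), np.sin(spec.yaw)
    rot = np.array([[cy, -sy], [sy, cy]])
    return xy @ rot.T + np.asarray(spec.xy_offset)


def sample_pig_surface(spec: SyntheticPigSpec, n_raw: int = 4000) -> PointCloud:
    """Sample the camera-visible top surface; returns a camera-frame cloud.

    One point per sampled line of sight (uniform over the footprint), exactly
    ``n_raw`` points, with light pig-skin colors. Camera frame: the floor is
    at ``z = plane_distance``, heights become ``z = plane_distance - h``.
    """
    if n_raw < 500:
        raise ValueError("n_raw must be >= 500")
    height, bbox = _height_field(spec)
    rng = np.random.default_rng(spec.seed)
    pts = []
    got = 0
    while got < n_raw:
        m = max(2 * (n_raw - got), 1000)
        x = rng.uniform(bbox[0, 0], bbox[0, 1], size=m)
        y = rng.uniform(bbox[1, 0], bbox[1, 1], size=m)
        h = height(x, y)
        ok = np.isfinite(h)
        pts.append(np.column_stack([x[ok], y[ok], h[ok]]))
        got += int(ok.sum())
    body = np.concatenate(pts)[:n_raw]
    xy = _pose_xy(spec, body[:, :2])
    z = spec.plane_distance - body[:, 2]
    colors = np.clip(
        PIG_COLOR + rng.normal(0, 8, size=(n_raw, 3)), 0, 255
    ).astype(np.uint8)
    return PointCloud(np.column_stack([xy, z]), colors, source_id=f"synthetic-pig-{spec.seed}")


def reference_projected_volume(spec: SyntheticPigSpec, step: float = 0.002) -> float:
    """Ground-truth projected volume by fine numerical integration (m^3).

    Integrates the analytic top-surface height field on a grid of the given
    step (default 2 mm), independent of the rasterizer under test. Pose
    (yaw/offset) does not change the integral; head pitch does.
    """
    height, bbox = _height_field(spec)
    xs = np.arange(bbox[0, 0], bbox[0, 1] + step, step) + step / 2
    ys = np.arange(bbox[1, 0], bbox[1, 1] + step, step) + step / 2
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    h = height(gx.ravel(), gy.ravel())
    return float(np.nansum(h) * step * step)


def assign_weight(spec: SyntheticPigSpec) -> float:
    """Weight label (kg): density x reference volume + Gaussian noise, min 1 kg."""
    w = spec.density_coeff * reference_projected_volume(spec)
    if spec.weight_noise_sd > 0:
        w += np.random.default_rng(spec.seed).normal(0.0, spec.weight_noise_sd)
    return float(max(w, 1.0))


def apply_sensor_artifacts(
    cloud: PointCloud,
    art: SensorArtifactSpec,
    seed: int = 0,
    z_max: float | None = None,
) -> PointCloud:
    """Apply wavy depth displacement, chunk dropout and point noise (seeded).

    ``z_max`` clips depths at the floor plane: displaced returns cannot come
    from beyond the surface the sensor sees.
    """
    if art.is_null or len(cloud) == 0:
        return cloud
    rng = np.random.default_rng(seed)
    pts = cloud.points.copy()
    if art.wave_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        direction = rng.uniform(0, 2 * np.pi)
        proj = pts[:, 0] * np.cos(direction) + pts[:, 1] * np.sin(direction)
        pts[:, 2] += art.wave_amplitude * np.sin(2 * np.pi * art.wave_frequency * proj + phase)
    out = PointCloud(pts, cloud.colors, cloud.source_id)
    if art.dropout_chunks > 0 and art.dropout_radius > 0 and len(out) > 0:
        centers = out.points[rng.integers(0, len(out), size=art.dropout_chunks), :2]
        keep = np.ones(len(out), dtype=bool)
        for cx, cy in centers:
            d2 = (out.points[:, 0] - cx) ** 2 + (out.points[:, 1] - cy) ** 2
            keep &= d2 > art.dropout_radius ** 2
        out = out.select(keep)
    if art.point_noise_sd > 0 and len(out) > 0:
        noisy = out.points + rng.normal(0.0, art.point_noise_sd, size=out.points.shape)
        out = out.with_points(noisy)
    if z_max is not None and len(out) > 0:
        clipped = out.points.copy()
        clipped[:, 2] = np.minimum(clipped[:, 2], z_max)
        out = out.with_points(clipped)
    return out


def _animal_spec(
    target_weight: float,
    rng: np.random.Generator,
    base: SyntheticPigSpec,
) -> SyntheticPigSpec:
    """Draw body dimensions whose reference weight approximates the target.

    Proportions (length:width:height ratios, squareness, head/neck fractions)
    vary per animal; the isotropic scale is solved so that ``density_coeff x
    reference volume`` lands on the target weight (volume scales as the cube
    of the linear scale).
    """
    proto = replace(
        base,
        shape_exponent=float(rng.uniform(2.2, 3.2)),
        head_scale=float(rng.uniform(0.30, 0.42)),
        neck_scale=float(rng.uniform(0.14, 0.22)),
        half_length=base.half_length * float(rng.uniform(0.9, 1.1)),
        half_width=base.half_width * float(rng.uniform(0.9, 1.1)),
        half_height=base.half_height * float(rng.uniform(0.92, 1.08)),
        yaw=0.0, xy_offset=(0.0, 0.0), head_pitch=0.0,
    )
    v_proto = reference_projected_volume(proto, step=0.004)
    scale = (target_weight / (proto.density_coeff * v_proto)) ** (1.0 / 3.0)
    return replace(
        proto,
        half_length=proto.half_length * scale,
        half_width=proto.half_width * scale,
        half_height=proto.half_height * scale,
    )


def make_dataset(
    n_animals: int,
    clouds_per_animal: int = 7,
    weight_range: tuple[float, float] = (20.0, 120.0),
    art: SensorArtifactSpec = SensorArtifactSpec(),
    seed: int = 0,
    n_points: int = CANONICAL_N_POINTS,
    n_raw: int = 4000,
    base: SyntheticPigSpec = SyntheticPigSpec(),
    vary_pose: bool = True,
) -> list[tuple[PointCloud, WeightRecord]]:
    """Generate a labeled multi-animal dataset.

    Per-animal body dimensions are drawn so reference weights span
    ``weight_range`` (evenly spaced targets, shuffled); each animal
    contributes ``clouds_per_animal`` clouds with independently drawn pen
    pose (yaw, offset, head pitch) but a single shared weight label —
    posture changes geometry, not mass. Artifacts are applied per cloud and
    every cloud is subsampled (padding after heavy dropout) to ``n_points``.
    ``vary_pose=False`` freezes every animal at the neutral centered pose
    (for perturbation-free control experiments).
    """
    lo, hi = weight_range
    if not (0.0 < lo < hi < 300.0):
        raise ValueError(f"infeasible weight_range {weight_range}")
    if n_animals < 1 or clouds_per_animal < 1:
        raise ValueError("n_animals and clouds_per_animal must be >= 1")
    rng = np.random.default_rng(seed)
    targets = np.linspace(lo, hi, n_animals) if n_animals > 1 else np.array([(lo + hi) / 2])
    rng.shuffle(targets)
    dataset: list[tuple[PointCloud, WeightRecord]] = []
    for i, target in enumerate(targets):
        spec = _animal_spec(float(target), rng, base)
        weight = spec.density_coeff * reference_projected_volume(spec)
        if spec.weight_noise_sd > 0:
            weight += float(rng.normal(0.0, spec.weight_noise_sd))
        weight = float(np.clip(weight, lo, hi))
        record = WeightRecord(animal_id=f"A{i:04d}", scale_weight=weight)
        for j in range(clouds_per_animal):
            if vary_pose:
                posed = replace(
                    spec,
                    yaw=float(rng.uniform(0, 2 * np.pi)),
                    xy_offset=(float(rng.uniform(-0.6, 0.6)), float(rng.uniform(-0.3, 0.3))),
                    head_pitch=float(rng.uniform(-0.5, 0.15)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            else:
                posed = replace(spec, seed=int(rng.integers(0, 2**31 - 1)))
            cloud = sample_pig_surface(posed, n_raw=n_raw)
            cloud = apply_sensor_artifacts(
                cloud, art, seed=int(rng.integers(0, 2**31 - 1)),
                z_max=posed.plane_distance,
            )
            cloud = random_subsample(
                cloud, n=n_points, seed=int(rng.integers(0, 2**31 - 1)), pad=True
            )
            cloud = PointCloud(cloud.points, cloud.colors, source_id=f"A{i:04d}-c{j}")
            dataset.append((cloud, record))
    return dataset


def make_test_scene(
    spec: SyntheticPigSpec = SyntheticPigSpec(),
    pen_dims: tuple[float, float] = DEFAULT_PEN_DIMS,
    n_pig: int = 2000,
    n_floor: int = 3000,
    n_wall: int = 800,
    n_blob: int = 300,
    point_noise_sd: float = 0.002,
) -> tuple[PointCloud, np.ndarray]:
    """Full pen scene with per-point ground-truth source labels.

    Combines a pig, the pen floor at ``z = L``, wall bands along the pen
    perimeter, and one dark off-color blob standing inside the region of
    interest. Returns ``(cloud, labels)`` with labels in
    ``{"pig", "floor", "wall", "blob"}`` partitioning the points — the
    oracle for validating the preprocessing filter chain.
    """
    L = spec.plane_distance
    major, minor = pen_dims
    rng = np.random.default_rng(spec.seed + 1)

    pig = sample_pig_surface(spec, n_raw=n_pig)

    floor_xy = rng.uniform([-major / 2, -minor / 2], [major / 2, minor / 2], size=(n_floor, 2))
    floor = np.column_stack([floor_xy, np.full(n_floor, L)])

    side = rng.integers(0, 4, size=n_wall)
    t = rng.uniform(-0.5, 0.5, size=n_wall)
    wx = np.where(side < 2, t * major, np.where(side == 2, -major / 2, major / 2))
    wy = np.where(side >= 2, t * minor, np.where(side == 0, -minor / 2, minor / 2))
    wz = L - rng.uniform(0.0, 1.0, size=n_wall)  # walls rise from the floor
    wall = np.column_stack([wx, wy, wz])

    blob_center = np.array([-major / 2 + 0.45, minor / 2 - 0.3])
    blob_r = 0.12
    ang = rng.uniform(0, 2 * np.pi, size=n_blob)
    rad = blob_r * np.sqrt(rng.uniform(0, 1, size=n_blob))
    blob_h = rng.uniform(0.15, 0.45, size=n_blob)  # tall enough to share the pig's depth band
    blob = np.column_stack(
        [blob_center[0] + rad * np.cos(ang), blob_center[1] + rad * np.sin(ang), L - blob_h]
    )

    pts = np.concatenate([pig.points, floor, wall, blob])
    pts[len(pig):] += rng.normal(0, point_noise_sd, size=pts[len(pig):].shape)
    pts[:, 2] = np.minimum(pts[:, 2], L)  # scene noise never reaches below the floor

    def tint(base: np.ndarray, n: int) -> np.ndarray:
        return np.clip(base + rng.normal(0, 6, size=(n, 3)), 0, 255).astype(np.uint8)

    colors = np.concatenate(
        [pig.colors, tint(FLOOR_COLOR, n_floor), tint(WALL_COLOR, n_wall), tint(BLOB_COLOR, n_blob)]
    )
    labels = np.array(
        ["pig"] * len(pig) + ["floor"] * n_floor + ["wall"] * n_wall + ["blob"] * n_blob
    )
    return PointCloud(pts, colors, source_id="synthetic-test-scene"), labels
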