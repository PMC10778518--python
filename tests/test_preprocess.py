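"""The animal-isolation filter chain: each filter against a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import assert_subsequence
from pigweigh.cloud import PointCloud, PointCloudError
from pigweigh.preprocess import (
    DegenerateInputError,
    DepthBand,
    OutlierParams,
    PlanarPolygon,
    color_segment,
    crop_head,
    depth_band_filter,
    jitter_points,
    otsu_threshold,
    polygon_roi_filter,
    random_subsample,
    remove_statistical_outliers,
)
from pigweigh.synthetic import SyntheticPigSpec, sample_pig_surface


class TestDepthBand:
    def test_brute_force_membership(self, random_cloud):
        band = DepthBand(2.2, 2.55)
        out = depth_band_filter(random_cloud, band)
        keep = [i for i, p in enumerate(random_cloud.points) if 2.2 <= p[2] <= 2.55]
        assert np.array_equal(out.points, random_cloud.points[keep])
        assert np.array_equal(out.colors, random_cloud.colors[keep])
        assert 0 < len(out) < len(random_cloud)

    def test_all_inside_is_identity(self, random_cloud):
        out = depth_band_filter(random_cloud, DepthBand(0.1, 10.0))
        assert np.array_equal(out.points, random_cloud.points)

    def test_empty_cloud(self):
        out = depth_band_filter(PointCloud(np.zeros((0, 3))), DepthBand(1, 2))
        assert len(out) == 0

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            DepthBand(2.5, 2.0)


def _ray_cast_inside(poly, x, y):
    """Independent point-in-polygon oracle: ray casting + explicit edge check."""
    verts = list(poly) + [poly[0]]
    # on-boundary check
    for (x1, y1), (x2, y2) in zip(verts[:-1], verts[1:]):
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
            return True
    inside = False
    for (x1, y1), (x2, y2) in zip(verts[:-1], verts[1:]):
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


class TestPolygonRoi:
    UNIT_SQUARE = PlanarPolygon(((0, 0), (1, 0), (1, 1), (0, 1)))

    def test_interior_point_kept(self):
        pc = PointCloud(np.array([[0.5, 0.5, 2.0]]))
        assert len(polygon_roi_filter(pc, self.UNIT_SQUARE)) == 1

    def test_boundary_point_kept(self):
        pc = PointCloud(np.array([[1.0, 0.5, 2.0], [0.0, 0.0, 2.0], [1.5, 0.5, 2.0]]))
        out = polygon_roi_filter(pc, self.UNIT_SQUARE)
        assert len(out) == 2  # edge and vertex kept, exterior dropped

    def test_against_ray_casting_oracle(self, rng):
        pentagon = PlanarPolygon(
            tuple((np.cos(t), np.sin(t)) for t in np.linspace(0, 2 * np.pi, 6)[:-1])
        )
        pts = np.column_stack([rng.uniform(-1.5, 1.5, (1000, 2)), np.full(1000, 2.0)])
        pc = PointCloud(pts)
        out = polygon_roi_filter(pc, pentagon)
        expect = [
            i for i in range(1000)
            if _ray_cast_inside(pentagon.vertices, pts[i, 0], pts[i, 1])
        ]
        assert np.array_equal(out.points, pts[expect])

    def test_too_few_vertices(self):
        with pytest.raises(ValueError):
            PlanarPolygon(((0, 0), (1, 1)))

    def test_self_intersecting_rejected(self):
        with pytest.raises(ValueError):
            PlanarPolygon(((0, 0), (1, 1), (1, 0), (0, 1)))


def _otsu_oracle(values):
    """Exhaustive 256-candidate between-class-variance scan."""
    hist = np.bincount(np.asarray(values, dtype=int), minlength=256)
    n = hist.sum()
    best_t, best_v = None, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1:] * np.arange(t + 1, 256)).sum() / w1
        v = (w0 / n) * (w1 / n) * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_symmetric_bimodal(self):
        values = np.array([0] * 50 + [255] * 50)
        t = otsu_threshold(values)
        assert 0 <= t < 255
        assert (values <= t).sum() == 50

    def test_equals_exhaustive_scan_on_random_histograms(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 400))
            values = rng.integers(0, 256, size=n)
            if np.ptp(values) == 0:
                values = np.append(values, (values[0] + 1) % 256)
            assert otsu_threshold(values) == _otsu_oracle(values)

    def test_matches_skimage(self, rng):
        from skimage.filters import threshold_otsu

        for _ in range(20):
            values = np.concatenate([
                rng.integers(10, 60, size=150), rng.integers(150, 240, size=80)
            ])
            t = otsu_threshold(values)
            t_ski = threshold_otsu(values.astype(np.uint8))
            # conventions differ by at most the bin boundary
            assert abs(int(t) - int(t_ski)) <= 1

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.full(10, 37))


class TestColorSegment:
    def _two_tone(self, n_light, n_dark, rng):
        pts = rng.uniform(0, 1, size=(n_light + n_dark, 3))
        colors = np.vstack([
            np.tile([220, 210, 200], (n_light, 1)),
            np.tile([60, 40, 30], (n_dark, 1)),
        ]).astype(np.uint8)
        return PointCloud(pts, colors)

    def test_majority_light_survives(self, rng):
        pc = self._two_tone(900, 100, rng)
        out = color_segment(pc)
        assert len(out) == 900
        assert (out.colors > 128).all()

    def test_majority_dark_survives(self, rng):
        pc = self._two_tone(100, 900, rng)
        out = color_segment(pc)
        assert len(out) == 900
        assert (out.colors < 128).all()

    def test_tie_keeps_brighter_class(self, rng):
        out = color_segment(self._two_tone(500, 500, rng))
        assert len(out) == 500
        assert (out.colors > 128).all()

    def test_monochrome_returned_unchanged(self, rng, caplog):
        pts = rng.uniform(0, 1, (50, 3))
        pc = PointCloud(pts, np.tile([100, 100, 100], (50, 1)).astype(np.uint8))
        with caplog.at_level("WARNING"):
            out = color_segment(pc)
        assert np.array_equal(out.points, pc.points)
        assert any("unchanged" in r.message for r in caplog.records)

    def test_colorless_cloud_rejected(self):
        with pytest.raises(PointCloudError):
            color_segment(PointCloud(np.zeros((5, 3))))


class TestOutlierRemoval:
    def test_single_far_point_removed(self):
        xx, yy = np.meshgrid(np.arange(20) * 0.01, np.arange(20) * 0.01)
        plane = np.column_stack([xx.ravel(), yy.ravel(), np.full(400, 2.0)])
        far = np.array([[5.0, 5.0, 2.0]])
        pc = PointCloud(np.vstack([plane, far]))
        out = remove_statistical_outliers(pc, OutlierParams(k_neighbors=8, std_ratio=2.0))
        assert len(out) == 400
        assert not (out.points == far).all(axis=1).any()

    def test_symmetric_lattice_untouched(self):
        # every point on a ring has identical neighbor distances, so no point
        # can exceed the mean-plus-spread cutoff
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pc = PointCloud(np.column_stack([np.cos(t), np.sin(t), np.full(100, 2.0)]))
        out = remove_statistical_outliers(pc, OutlierParams(k_neighbors=4, std_ratio=2.0))
        assert len(out) == 100

    def test_matches_brute_force_knn(self, rng):
        pts = rng.normal(0, 0.1, size=(120, 3))
        pc = PointCloud(pts)
        k, ratio = 6, 1.5
        # brute-force oracle: full pairwise distance matrix
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        mean_knn = np.sort(d, axis=1)[:, 1 : k + 1].mean(axis=1)
        cutoff = mean_knn.mean() + ratio * mean_knn.std()
        out = remove_statistical_outliers(pc, OutlierParams(k, ratio))
        assert np.array_equal(out.points, pts[mean_knn <= cutoff])

    def test_too_few_points(self):
        with pytest.raises(PointCloudError):
            remove_statistical_outliers(PointCloud(np.zeros((5, 3))),
                                        OutlierParams(k_neighbors=10))


class TestRandomSubsample:
    def test_subset_of_input(self, rng):
        pts = rng.uniform(size=(5000, 3))
        pc = PointCloud(pts)
        out = random_subsample(pc, n=1500, seed=3)
        assert len(out) == 1500
        as_set = {tuple(p) for p in pts}
        assert all(tuple(p) in as_set for p in out.points)

    def test_full_size_is_identity(self, random_cloud):
        out = random_subsample(random_cloud, n=len(random_cloud), seed=0)
        assert np.array_equal(out.points, random_cloud.points)

    def test_seed_reproducibility(self, random_cloud):
        a = random_subsample(random_cloud, n=200, seed=11)
        b = random_subsample(random_cloud, n=200, seed=11)
        c = random_subsample(random_cloud, n=200, seed=12)
        assert np.array_equal(a.points, b.points)
        assert not np.array_equal(a.points, c.points)

    def test_too_small_errors_unless_padded(self, rng):
        pc = PointCloud(rng.uniform(size=(100, 3)))
        with pytest.raises(PointCloudError):
            random_subsample(pc, n=150, seed=0)
        padded = random_subsample(pc, n=150, seed=0, pad=True)
        assert len(padded) == 150


class TestCropHead:
    def test_head_removed_body_kept(self):
        spec = SyntheticPigSpec(seed=2, head_scale=0.35)
        body_only = sample_pig_surface(
            SyntheticPigSpec(seed=2, head_scale=0.0), n_raw=2000
        )
        full = sample_pig_surface(spec, n_raw=2500)
        # label by x in the body frame: head/neck points lie beyond the torso
        is_head = full.points[:, 0] > spec.half_length * 0.999
        out = crop_head(full)
        kept = {tuple(p) for p in out.points}
        head_kept = sum(tuple(p) in kept for p in full.points[is_head])
        body_kept = sum(tuple(p) in kept for p in full.points[~is_head])
        assert head_kept / max(is_head.sum(), 1) < 0.25
        assert body_kept / (~is_head).sum() > 0.9

    def test_headless_body_mostly_retained(self):
        pc = sample_pig_surface(SyntheticPigSpec(seed=4, head_scale=0.0), n_raw=2000)
        out = crop_head(pc)
        assert len(out) >= 0.95 * len(pc)

    def test_mirrored_cloud_crops_mirrored_region(self):
        spec = SyntheticPigSpec(seed=2)
        pc = sample_pig_surface(spec, n_raw=2000)
        mirrored = PointCloud(pc.points * np.array([-1.0, 1.0, 1.0]), pc.colors)
        out = crop_head(pc)
        out_m = crop_head(mirrored)
        # same points survive up to the sign flip (bin boundaries may shift by
        # one slice, so allow a sliver of disagreement)
        a = {tuple(np.round(p, 9)) for p in out.points}
        b = {tuple(np.round(p * np.array([-1.0, 1.0, 1.0]), 9)) for p in out_m.points}
        assert len(a ^ b) < 0.02 * len(a)

    def test_degenerate_geometry_rejected(self):
        pc = PointCloud(np.tile([0.5, 0.5, 2.0], (200, 1)))
        with pytest.raises(PointCloudError):
            crop_head(pc)

    def test_too_few_points_rejected(self):
        with pytest.raises(PointCloudError):
            crop_head(PointCloud(np.random.default_rng(0).uniform(size=(50, 3))))


class TestJitter:
    def test_zero_amplitude_identity(self, random_cloud):
        out = jitter_points(random_cloud, amplitude=0.0, seed=5)
        assert np.array_equal(out.points, random_cloud.points)

    def test_displacement_bounded(self, random_cloud):
        out = jitter_points(random_cloud, amplitude=0.005, seed=5)
        assert np.abs(out.points - random_cloud.points).max() <= 0.005
        assert len(out) == len(random_cloud)
        assert np.array_equal(out.colors, random_cloud.colors)

    def test_uniform_moments(self):
        pc = PointCloud(np.zeros((400_000, 3)))
        a = 0.005
        delta = jitter_points(pc, amplitude=a, seed=9).points
        assert abs(delta.mean()) < 1e-5
        assert np.isclose(delta.var(), a**2 / 3, rtol=0.01)

    def test_bitwise_reproducible(self, random_cloud):
        a = jitter_points(random_cloud, 0.005, seed=3).points
        b = jitter_points(random_cloud, 0.005, seed=3).points
        assert np.array_equal(a, b)


@settings(max_examples=25, deadline=None, derandomize=True, database=None)
@given(
    zmin=st.floats(2.0, 2.3),
    width=st.floats(0.05, 0.5),
    seed=st.integers(0, 10_000),
)
def test_filters_return_subsequences(zmin, width, seed):
    """Order preserved, colors carried, no point invented, for every filter."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform([-1, -1, 2.0], [1, 1, 2.7], size=(300, 3))
    colors = rng.integers(0, 256, (300, 3)).astype(np.uint8)
    pc = PointCloud(pts, colors)
    for out in (
        depth_band_filter(pc, DepthBand(zmin, zmin + width)),
        polygon_roi_filter(pc, PlanarPolygon(((-0.5, -0.5), (0.7, -0.3), (0.2, 0.8)))),
        color_segment(pc),
        remove_statistical_outliers(pc, OutlierParams(5, 1.0)),
        random_subsample(pc, 100, seed=seed),
    ):
        assert_subsequence(out, pc)
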