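"""Navigation-point extraction, depth attachment and the fused pipeline."""

import numpy as np
import pytest

from rownav.depth_io import DepthMap
from rownav.fusion import (
    FusionConfig,
    InstanceMaskSet,
    NavigationPoint,
    attach_depth,
    extract_navigation_points,
    fuse,
    row_point_cloud,
    to_camera_frame,
    write_ply,
    write_xyz,
)
from rownav.geometry import CameraIntrinsics, project
from rownav.synthetic import SceneConfig, render_scene


def brute_force_points(labels, n_bands):
    """Explicit double loop over pixels and bands (the extraction oracle)."""
    out = []
    for inst in sorted(int(i) for i in np.unique(labels) if i):
        pix = [(v, u) for v in range(labels.shape[0]) for u in range(labels.shape[1])
               if labels[v, u] == inst]
        v_min = min(v for v, _ in pix)
        v_max = max(v for v, _ in pix)
        extent = v_max - v_min + 1
        for b in range(n_bands):
            in_band = [(v, u) for v, u in pix
                       if min((v - v_min) * n_bands // extent, n_bands - 1) == b]
            if not in_band:
                continue
            out.append((inst, b,
                        sum(u for _, u in in_band) / len(in_band),
                        sum(v for v, _ in in_band) / len(in_band)))
    return out


def random_blob_mask(rng, shape=(60, 80), n_instances=3):
    """Disjoint random rectangles-with-holes as instance masks."""
    labels = np.zeros(shape, dtype=np.int32)
    xs = np.sort(rng.choice(np.arange(2, shape[1] - 10), size=n_instances, replace=False))
    for i, x0 in enumerate(xs, start=1):
        w = int(rng.integers(3, 8))
        y0 = int(rng.integers(0, shape[0] // 2))
        h = int(rng.integers(4, shape[0] - y0))
        block = rng.random((h, w)) < 0.8
        block[0, 0] = True  # at least one pixel
        region = labels[y0:y0 + h, x0:x0 + w]
        region[block & (region == 0)] = i
    present = [i for i in range(1, n_instances + 1) if np.any(labels == i)]
    remap = np.zeros(n_instances + 1, dtype=np.int32)
    for new, old in enumerate(present, start=1):
        remap[old] = new
    return remap[labels]


class TestExtractNavigationPoints:
    def test_solid_rectangle_band_means(self):
        """10x28 rectangle, 14 bands -> 14 points at u=14.5, v=0.5,2.5,...,26.5."""
        labels = np.zeros((28, 32), dtype=np.int32)
        labels[0:28, 10:20] = 1
        pts = extract_navigation_points(InstanceMaskSet(labels), FusionConfig(n_bands=14))
        assert len(pts) == 14
        for i, p in enumerate(pts):
            assert p.u == pytest.approx(14.5)
            assert p.v == pytest.approx(0.5 + 2 * i)
            assert p.band_index == i

    def test_single_band_is_centroid(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[2:7, 3:8] = 2
        (p,) = extract_navigation_points(InstanceMaskSet(labels), FusionConfig(n_bands=1))
        vs, us = np.nonzero(labels == 2)
        assert p.u == pytest.approx(us.mean())
        assert p.v == pytest.approx(vs.mean())

    def test_short_instance_emits_at_most_height_points(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[4:9, 5] = 1  # 5 px tall
        pts = extract_navigation_points(InstanceMaskSet(labels), FusionConfig(n_bands=14))
        assert 1 <= len(pts) <= 5

    def test_matches_brute_force_on_random_blobs(self, rng):
        for trial in range(50):
            labels = random_blob_mask(rng)
            n_bands = int(rng.integers(1, 15))
            got = extract_navigation_points(InstanceMaskSet(labels), FusionConfig(n_bands=n_bands))
            want = brute_force_points(labels, n_bands)
            assert len(got) == len(want), f"trial {trial}"
            for p, (inst, b, u, v) in zip(got, want):
                assert (p.instance_id, p.band_index) == (inst, b)
                assert p.u == pytest.approx(u, abs=1e-9)
                assert p.v == pytest.approx(v, abs=1e-9)

    def test_points_inside_instance_bounding_box(self, rng):
        for _ in range(10):
            labels = random_blob_mask(rng)
            pts = extract_navigation_points(InstanceMaskSet(labels), FusionConfig(n_bands=7))
            per_inst = {}
            for p in pts:
                per_inst.setdefault(p.instance_id, []).append(p)
            for inst, ps in per_inst.items():
                assert len(ps) <= 7
                vs, us = np.nonzero(labels == inst)
                for p in ps:
                    assert us.min() <= p.u <= us.max()
                    assert vs.min() <= p.v <= vs.max()

    def test_mask_validation(self):
        with pytest.raises(ValueError):
            InstanceMaskSet(np.zeros((3, 3)))  # float labels
        with pytest.raises(ValueError):
            InstanceMaskSet(np.array([[-1, 0]]))


class TestAttachDepth:
    def _points(self):
        return [NavigationPoint(1, 0, u=14.5, v=0.5)]

    def test_constant_map_kept(self):
        d = DepthMap(np.full((28, 32), 2.0))
        (p,) = attach_depth(self._points(), d)
        assert p.depth == 2.0

    def test_null_depth_dropped(self):
        d = DepthMap(np.zeros((28, 32)))
        assert attach_depth(self._points(), d) == []

    def test_beyond_max_depth_dropped(self):
        d = DepthMap(np.full((28, 32), 6.2))
        assert attach_depth(self._points(), d, FusionConfig(max_depth=5.0)) == []

    def test_label_filter_keeps_position_matched_pairs(self):
        label = DepthMap(np.full((28, 32), 3.0))
        pred = DepthMap(np.full((28, 32), 7.0))  # beyond 5 m but label governs the filter
        (p,) = attach_depth(self._points(), pred, filter_depth=label)
        assert p.depth == 7.0

    def test_bilinear_lookup_interpolates_but_respects_nulls(self):
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        d = DepthMap(vals)
        cfg = FusionConfig(n_bands=1, depth_lookup="bilinear")
        (p,) = attach_depth([NavigationPoint(1, 0, u=0.5, v=0.5)], d, cfg)
        assert p.depth == pytest.approx(2.5)
        vals0 = vals.copy()
        vals0[0, 0] = 0.0
        assert attach_depth([NavigationPoint(1, 0, u=0.5, v=0.5)], DepthMap(vals0), cfg) == []


class TestToCameraFrame:
    def test_principal_point(self, k):
        (p,) = to_camera_frame([NavigationPoint(1, 0, u=k.cx, v=k.cy, depth=3.0)], k)
        assert np.allclose(p.point3d, [0.0, 0.0, 3.0])

    def test_reprojection_round_trip(self, k, rng):
        pts = [NavigationPoint(1, i, u=float(rng.uniform(0, k.width)),
                               v=float(rng.uniform(0, k.height)),
                               depth=float(rng.uniform(0.5, 5)))
               for i in range(20)]
        for p in to_camera_frame(pts, k):
            u, v, d = project(p.point3d, k)
            assert abs(u - p.u) < 1e-9 and abs(v - p.v) < 1e-9

    def test_missing_depth_rejected(self, k):
        with pytest.raises(ValueError, match="no depth"):
            to_camera_frame([NavigationPoint(1, 0, u=1.0, v=1.0)], k)

    def test_empty_input(self, k):
        assert to_camera_frame([], k) == []


class TestRowPointCloud:
    def test_constant_plane_cloud(self, k):
        labels = np.zeros((360, 640), dtype=np.int32)
        labels[100:200, 50:90] = 1
        d = DepthMap(np.full((360, 640), 2.0))
        clouds = row_point_cloud(InstanceMaskSet(labels), d, k)
        assert clouds[1].shape == (100 * 40, 3)
        assert np.allclose(clouds[1][:, 2], 2.0)

    def test_all_missing_gives_flagged_empty_cloud(self, k):
        labels = np.zeros((360, 640), dtype=np.int32)
        labels[10:20, 10:20] = 1
        clouds = row_point_cloud(InstanceMaskSet(labels), DepthMap(np.zeros((360, 640))), k)
        assert clouds[1].shape == (0, 3)


class TestFuse:
    def test_identical_maps_give_zero_cds(self, default_scene):
        scene = default_scene
        res = fuse(scene.masks, scene.depth, scene.config.camera, depth_label=scene.depth)
        assert res.cd_navigation == 0.0
        assert res.cd_rows == 0.0

    def test_cd_shrinks_as_multiplicative_error_vanishes(self, default_scene):
        scene = default_scene
        cds = []
        for eps in (0.04, 0.02, 0.01):
            pred = DepthMap.sanitize(scene.depth.values * (1 + eps))
            res = fuse(scene.masks, pred, scene.config.camera, depth_label=scene.depth)
            cds.append(res.cd_navigation)
        assert cds[0] > cds[1] > cds[2] > 0

    def test_position_matched_pairs(self, default_scene):
        scene = default_scene
        pred = DepthMap.sanitize(scene.depth.values * 1.3)
        res = fuse(scene.masks, pred, scene.config.camera, depth_label=scene.depth)
        assert len(res.pred_points) == len(res.label_points)
        for p, l in zip(res.pred_points, res.label_points):
            assert (p.u, p.v) == (l.u, l.v)
            assert (p.instance_id, p.band_index) == (l.instance_id, l.band_index)

    def test_fused_points_match_analytic_ground_truth(self, default_scene):
        scene = default_scene
        res = fuse(scene.masks, scene.depth, scene.config.camera, depth_label=scene.depth)
        gt = {(p.instance_id, p.band_index): p.point3d
              for p in scene.nav_points if p.depth is not None and p.depth <= 5.0}
        got = {(p.instance_id, p.band_index): p.point3d for p in res.pred_points}
        assert set(got) == set(gt)
        for key in gt:
            assert np.max(np.abs(gt[key] - got[key])) < 1e-6

    def test_empty_mask_warns_not_errors(self, default_scene):
        scene = default_scene
        empty = InstanceMaskSet(np.zeros_like(scene.masks.labels))
        res = fuse(empty, scene.depth, scene.config.camera, depth_label=scene.depth)
        assert res.pred_points == []
        assert res.warnings

    def test_point_count_bounded_by_bands(self, default_scene):
        scene = default_scene
        res = fuse(scene.masks, scene.depth, scene.config.camera,
                   cfg=FusionConfig(n_bands=14, max_depth=20.0))
        counts = {}
        for p in res.pred_points:
            counts[p.instance_id] = counts.get(p.instance_id, 0) + 1
        assert all(c <= 14 for c in counts.values())


class TestExports:
    def test_xyz_and_ply(self, tmp_path, rng):
        cloud = rng.normal(size=(5, 3))
        write_xyz(cloud, tmp_path / "c.xyz")
        back = np.loadtxt(tmp_path / "c.xyz")
        assert np.allclose(back, cloud, atol=1e-6)
        write_ply(cloud, tmp_path / "c.ply")
        text = (tmp_path / "c.ply").read_text()
        assert text.startswith("ply") and "element vertex 5" in text
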