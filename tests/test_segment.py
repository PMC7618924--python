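"""Segmentation: star-convex geometry, classical detector, size pre-filter."""

import numpy as np
import pytest

from blastotrack.core import LabelVolume
from blastotrack.segment import (RaySet, StarConvexShape, detect_nuclei_classical,
                                 filter_small, nms_star_convex, star_convex_decode,
                                 star_convex_encode, star_convex_iou)
from blastotrack.validate import match_labels


def ellipsoid_volume(semi_axes, spacing=(1.0, 1.0, 1.0), shape=(40, 40, 40),
                     center=None, axes_order=(0, 1, 2)):
    """Rasterize one axis-aligned ellipsoid as a LabelVolume."""
    spacing = np.asarray(spacing, float)
    center = np.array(shape) / 2 * spacing if center is None else np.asarray(center)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    pos = np.stack(grids, axis=-1) * spacing
    q = (pos - center) / np.asarray(semi_axes)[list(axes_order)]
    mask = np.sum(q**2, axis=-1) <= 1.0
    return LabelVolume(labels=mask.astype(np.int32), spacing=spacing)


class TestRaySet:
    def test_needs_at_least_32_rays(self):
        from blastotrack.core import ConfigError
        with pytest.raises(ConfigError):
            RaySet.fibonacci(8)

    def test_directions_unit_norm(self):
        rays = RaySet.fibonacci(96, anisotropy_scale=(2.0, 1.0, 1.0))
        assert np.allclose(np.linalg.norm(rays.directions, axis=1), 1.0)


class TestEncode:
    def test_sphere_distances_near_radius(self):
        lv = ellipsoid_volume((6.0, 6.0, 6.0))
        rays = RaySet.fibonacci(96)
        shape = star_convex_encode(lv, 1, rays)
        diag = np.linalg.norm(lv.spacing)
        assert np.all(np.abs(shape.distances - 6.0) <= diag)

    def test_ellipsoid_min_max_distances(self):
        # long axis 8 um along x, short 4 um
        lv = ellipsoid_volume((4.0, 4.0, 8.0))
        rays = RaySet.fibonacci(192)
        shape = star_convex_encode(lv, 1, rays)
        assert shape.distances.max() == pytest.approx(8.0, abs=1.0)
        assert shape.distances.min() == pytest.approx(4.0, abs=1.0)

    def test_single_voxel_instance(self):
        labels = np.zeros((5, 5, 5), np.int32)
        labels[2, 2, 2] = 1
        lv = LabelVolume(labels=labels, spacing=np.array([2.0, 1.0, 1.0]))
        shape = star_convex_encode(lv, 1, RaySet.fibonacci(64))
        assert np.all(shape.distances <= np.linalg.norm(lv.spacing))

    def test_missing_label_raises(self):
        lv = ellipsoid_volume((4.0, 4.0, 4.0))
        with pytest.raises(KeyError):
            star_convex_encode(lv, 99, RaySet.fibonacci(64))


class TestDecode:
    @pytest.mark.parametrize("semi_axes,spacing", [
        ((6.0, 6.0, 6.0), (1.0, 1.0, 1.0)),
        ((4.0, 5.0, 8.0), (1.0, 1.0, 1.0)),
        ((5.0, 7.0, 8.0), (2.0, 1.0, 1.0)),
    ])
    def test_round_trip_iou(self, semi_axes, spacing):
        """decode(encode(L)) IoU >= 0.9 for convex instances >= 500 voxels."""
        shape3 = tuple(int(24 / s) for s in spacing)
        lv = ellipsoid_volume(semi_axes, spacing=spacing, shape=shape3)
        assert lv.labels.sum() >= 500
        rays = RaySet.fibonacci(96, anisotropy_scale=spacing)
        enc = star_convex_encode(lv, 1, rays)
        dec = star_convex_decode([enc], rays, lv.labels.shape, spacing)
        inter = np.logical_and(lv.labels == 1, dec.labels == 1).sum()
        union = np.logical_or(lv.labels == 1, dec.labels == 1).sum()
        assert inter / union >= 0.9

    def test_sphere_decode_volume(self):
        r = 6.0
        center = np.array([12.0, 12.0, 12.0])
        rays = RaySet.fibonacci(96)
        s = StarConvexShape(center=center, distances=np.full(len(rays), r))
        dec = star_convex_decode([s], rays, (25, 25, 25), (1.0, 1.0, 1.0))
        vol = (dec.labels == 1).sum()
        assert vol == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)

    def test_disjoint_shapes_do_not_overlap(self):
        rays = RaySet.fibonacci(64)
        s1 = StarConvexShape(center=(5.0, 5.0, 5.0), distances=np.full(64, 3.0))
        s2 = StarConvexShape(center=(5.0, 5.0, 15.0), distances=np.full(64, 3.0))
        dec = star_convex_decode([s1, s2], rays, (11, 11, 21), (1.0, 1.0, 1.0))
        assert set(np.unique(dec.labels)) == {0, 1, 2}


class TestNMS:
    def test_duplicate_keeps_higher_score(self):
        rays = RaySet.fibonacci(64)
        s = StarConvexShape(center=(5.0, 5.0, 5.0), distances=np.full(64, 3.0))
        dup = StarConvexShape(center=(5.0, 5.0, 5.0), distances=np.full(64, 3.0))
        kept = nms_star_convex([s, dup], [0.9, 0.8], 0.3, rays)
        assert len(kept) == 1

    def test_disjoint_all_kept(self):
        rays = RaySet.fibonacci(64)
        shapes = [StarConvexShape(center=(5.0, 5.0, 5.0 + 10 * i),
                                  distances=np.full(64, 3.0)) for i in range(3)]
        assert len(nms_star_convex(shapes, [0.5, 0.6, 0.7], 0.3, rays)) == 3

    def test_overlap_chain_matches_bruteforce(self):
        """A-B overlap, B-C overlap, A-C disjoint, scores A>B>C: greedy keeps
        {A, C} — cross-checked against an exhaustive suppression oracle."""
        rays = RaySet.fibonacci(96)
        mk = lambda z: StarConvexShape(center=(8.0, 8.0, z),
                                       distances=np.full(96, 4.0))
        shapes = [mk(6.0), mk(8.5), mk(11.0)]  # A, B, C
        scores = [0.9, 0.8, 0.7]
        kept = nms_star_convex(shapes, scores, 0.3, rays)
        # brute-force oracle: visit by score, suppress by pairwise IoU
        iou = {(i, j): star_convex_iou(shapes[i], shapes[j], rays)
               for i in range(3) for j in range(3) if i < j}
        assert iou[(0, 1)] >= 0.3 and iou[(1, 2)] >= 0.3 and iou[(0, 2)] < 0.3
        keep_oracle = []
        for i in np.argsort(scores)[::-1]:
            if all(iou[tuple(sorted((i, j)))] < 0.3 for j in keep_oracle):
                keep_oracle.append(i)
        kept_idx = {i for i, s in enumerate(shapes) if any(s is k for k in kept)}
        assert kept_idx == set(keep_oracle) == {0, 2}


class TestDetect:
    def test_recovers_well_separated_nuclei(self, single_frame_render):
        truth, frame, truth_labels = single_frame_render
        from blastotrack.preprocess import normalize_intensity
        lv = detect_nuclei_classical(normalize_intensity(frame))
        lv = filter_small(lv, 30.0)
        assert len(lv.ids()) == len(truth.nuclei)
        mapping = match_labels(lv, truth_labels, min_iou=0.5)
        assert len(mapping) == len(truth.nuclei)
        for p, t in mapping.items():
            pm, tm = lv.labels == p, truth_labels.labels == t
            iou = np.logical_and(pm, tm).sum() / np.logical_or(pm, tm).sum()
            assert iou >= 0.7

    def test_blank_frame_detects_nothing(self):
        from blastotrack.core import VolumetricFrame
        f = VolumetricFrame(intensity=np.zeros((10, 10, 10)),
                            spacing=np.array([2.0, 1.0, 1.0]))
        with pytest.warns(UserWarning):
            lv = detect_nuclei_classical(f)
        assert len(lv.ids()) == 0

    def test_close_nuclei_may_merge_but_never_split_extra(self):
        truth, frame, _ = (None, None, None)
        from blastotrack import synth
        from blastotrack.preprocess import normalize_intensity
        t = synth.make_blastocyst(n_outer=6, n_inner=0, n_frames=1, kappa=0.5,
                                  seed=8, radius=14.0)
        frames, _ = synth.render(t, seed=8)
        lv = detect_nuclei_classical(normalize_intensity(frames[0]),
                                     min_seed_distance=14.0)
        assert len(lv.ids()) <= 6


class TestFilterSmall:
    def _volume_ladder(self):
        # instances of 10, 29.9(~30-eps), 30, 45 um^3 at voxel volume 0.1 um^3
        spacing = np.array([0.1, 1.0, 1.0])
        labels = np.zeros((4, 50, 12), np.int32)
        for i, vol in enumerate([10.0, 29.9, 30.0, 45.0]):
            n_vox = int(round(vol / 0.1))
            labels[i].ravel()[:n_vox] = i + 1
        lv = LabelVolume(labels=labels, spacing=spacing)
        assert [round(v, 6) for v in lv.volumes().values()] == [10.0, 29.9, 30.0, 45.0]
        return lv

    def test_strict_boundary_semantics(self):
        """'smaller than 30 um^3' removes 10 and 29.9, keeps 30 and 45."""
        out = filter_small(self._volume_ladder(), 30.0)
        assert sorted(out.ids()) == [3, 4]
        assert sorted(round(v, 6) for v in out.volumes().values()) == [30.0, 45.0]

    def test_zero_min_volume_is_identity(self):
        lv = self._volume_ladder()
        out = filter_small(lv, 0.0)
        assert np.array_equal(out.labels, lv.labels)

    def test_all_tiny_gives_empty(self):
        out = filter_small(self._volume_ladder(), 1e6)
        assert len(out.ids()) == 0

    def test_idempotent_and_never_creates_labels(self):
        lv = self._volume_ladder()
        once = filter_small(lv, 30.0)
        twice = filter_small(once, 30.0)
        assert np.array_equal(once.labels, twice.labels)
        assert set(once.ids()) <= set(lv.ids())
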