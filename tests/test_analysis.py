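"""Segmentation, quantification, tracking and mask-erosion checks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk as draw_disk

from reactoscope.analysis import (SegmentationResult, Tracker, erode_mask,
                                  link_tracks, quantify, segment, snr)
from reactoscope.microscope import (VirtualSampleParams, ground_truth_labels,
                                    snap_image)
from reactoscope.scenarios import make_population


def seg_from_centroids(points, shape=(128, 128), r=5):
    lab = np.zeros(shape, dtype=np.int32)
    res = SegmentationResult(lab)
    for i, (pr, pc) in enumerate(points, start=1):
        rr, cc = draw_disk((pr, pc), r, shape=shape)
        lab[rr, cc] = i
        res.centroids[i] = (float(pr), float(pc))
        res.areas[i] = float(len(rr))
    return res


class TestSegment:
    def test_blank_image_no_labels(self):
        assert segment(np.full((64, 64), 7.0)).labels == []

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            segment(np.zeros((4, 4, 4)))

    def test_single_cell_contains_truth_centroid(self, quiet_params, rng):
        from tests.conftest import make_cell

        cell = make_cell(centroid=(40.0, 80.0))
        img = snap_image([cell], "brightfield", 50.0, quiet_params, rng)
        res = segment(img)
        assert len(res.labels) == 1
        assert res.label_image[40, 80] == res.labels[0]

    def test_rendered_scene_iou_against_ground_truth(self, rng):
        # 20 well-separated cells; per-cell IoU vs truth ellipses >= 0.8
        params = VirtualSampleParams(image_shape=(256, 256))
        pop = make_population(20, (256, 256), rng)
        img = snap_image(pop, "brightfield", 50.0, params, rng)
        res = segment(img)
        assert len(res.labels) == 20
        truth = ground_truth_labels(pop, (256, 256))
        for cell in pop:
            tmask = truth == cell.id + 1
            lab = res.label_image[int(round(cell.centroid[0])),
                                  int(round(cell.centroid[1]))]
            assert lab > 0
            smask = res.label_image == lab
            iou = np.logical_and(tmask, smask).sum() / np.logical_or(
                tmask, smask).sum()
            assert iou >= 0.8


class TestQuantify:
    def test_uniform_image(self):
        res = seg_from_centroids([(30, 30), (80, 80)])
        out = quantify(res, np.full((128, 128), 42.0))
        assert out == {1: pytest.approx(42.0), 2: pytest.approx(42.0)}

    def test_mean_of_three_pixels(self):
        lab = np.zeros((4, 4), dtype=np.int32)
        lab[0, :3] = 1
        res = SegmentationResult(lab, centroids={1: (0.0, 1.0)},
                                 areas={1: 3.0})
        img = np.zeros((4, 4))
        img[0, :3] = [10.0, 20.0, 30.0]
        assert quantify(res, img)[1] == pytest.approx(20.0)

    def test_empty_label_set(self):
        assert quantify(SegmentationResult(np.zeros((8, 8), np.int32)),
                        np.zeros((8, 8))) == {}

    def test_invariant_to_label_permutation(self):
        res = seg_from_centroids([(30, 30), (80, 80), (30, 90)])
        img = np.arange(128 * 128, dtype=float).reshape(128, 128)
        out = quantify(res, img)
        # permute labels 1->3, 2->1, 3->2
        perm = {1: 3, 2: 1, 3: 2}
        lab2 = np.zeros_like(res.label_image)
        for old, new in perm.items():
            lab2[res.label_image == old] = new
        res2 = SegmentationResult(
            lab2, centroids={perm[k]: v for k, v in res.centroids.items()},
            areas={perm[k]: v for k, v in res.areas.items()})
        out2 = quantify(res2, img)
        for old, new in perm.items():
            assert out2[new] == pytest.approx(out[old])

    def test_linearity_vs_molecule_count(self, rng):
        # quantified mean tracks ground-truth copy number (R^2 > 0.95)
        params = VirtualSampleParams(image_shape=(512, 512), shot_noise=True,
                                     read_noise_sd=1.0)
        pop = make_population(100, (512, 512), rng)
        counts = rng.uniform(50, 2000, size=len(pop))
        for c, n in zip(pop, counts):
            c.protein_count = float(n)
        bf = snap_image(pop, "brightfield", 50.0, params, rng)
        fl = snap_image(pop, "GFP", 100.0, params, rng)
        res = segment(bf)
        assert len(res.labels) == 100
        means = quantify(res, fl)
        x, y = [], []
        for cell in pop:
            lab = res.label_image[int(round(cell.centroid[0])),
                                  int(round(cell.centroid[1]))]
            x.append(cell.protein_count)
            y.append(means[lab])
        r = np.corrcoef(x, y)[0, 1]
        assert r * r > 0.95


class TestSnr:
    def test_uniform_image_unity(self):
        res = seg_from_centroids([(64, 64)])
        assert snr(res, np.full((128, 128), 55.0)) == pytest.approx(1.0)

    def test_two_to_one(self):
        res = seg_from_centroids([(64, 64)])
        img = np.full((128, 128), 100.0)
        img[res.label_image == 1] = 200.0
        assert snr(res, img) == pytest.approx(2.0)

    def test_offset_moves_snr_toward_one(self):
        res = seg_from_centroids([(64, 64)])
        img = np.full((128, 128), 100.0)
        img[res.label_image == 1] = 300.0
        assert snr(res, img + 100.0) < snr(res, img)
        assert snr(res, img + 100.0) > 1.0

    def test_no_cells_is_error(self):
        with pytest.raises(ValueError):
            snr(SegmentationResult(np.zeros((16, 16), np.int32)),
                np.ones((16, 16)))


class TestLinkTracks:
    def test_identity_on_repeated_frame(self):
        res = seg_from_centroids([(30, 30), (80, 80)])
        tracks = []
        link_tracks(tracks, res, frame=0)
        link_tracks(tracks, res, frame=1)
        assert len(tracks) == 2
        assert all(t.frames == [0, 1] for t in tracks)

    def test_uniform_shift_keeps_all_tracks(self):
        pts = [(30.0, 30.0), (30.0, 90.0), (90.0, 30.0), (90.0, 90.0)]
        tracks = []
        link_tracks(tracks, seg_from_centroids(pts), frame=0)
        shifted = [(p + 1.0, q + 1.0) for p, q in pts]
        link_tracks(tracks, seg_from_centroids(shifted), frame=1, max_disp=10.0)
        assert len(tracks) == 4
        for t in tracks:
            assert t.frames == [0, 1]
            p0, p1 = t.centroids[0], t.centroids[1]
            assert math.hypot(p1[0] - p0[0], p1[1] - p0[1]) == pytest.approx(
                math.sqrt(2.0))

    def test_far_object_becomes_new_track(self):
        tracks = []
        link_tracks(tracks, seg_from_centroids([(30, 30)]), frame=0)
        link_tracks(tracks, seg_from_centroids([(30, 30), (100, 100)]),
                    frame=1, max_disp=10.0)
        ids = sorted(t.track_id for t in tracks)
        assert len(ids) == 2 and ids[1] != ids[0]

    def test_matches_exhaustive_assignment_oracle(self, rng):
        # on <=6 cells, the linker must find the minimum-total-squared-
        # displacement assignment; oracle enumerates all permutations
        for _ in range(10):
            n = int(rng.integers(2, 7))
            prev_pts = rng.uniform(20, 100, size=(n, 2))
            curr_pts = prev_pts + rng.uniform(-3, 3, size=(n, 2))
            order = rng.permutation(n)
            tracks = []
            link_tracks(tracks, seg_from_centroids(prev_pts, r=3), frame=0)
            link_tracks(tracks, seg_from_centroids(curr_pts[order], r=3),
                        frame=1, max_disp=15.0)
            best_cost, best_perm = np.inf, None
            for perm in itertools.permutations(range(n)):
                cost = sum(((prev_pts[i] - curr_pts[order][list(perm)[i]]) ** 2
                            ).sum() for i in range(n))
                if cost < best_cost:
                    best_cost, best_perm = cost, perm
            for i, t in enumerate(sorted(tracks, key=lambda t: t.track_id)):
                expect = tuple(curr_pts[order][best_perm[i]])
                assert t.centroids[1] == pytest.approx(expect)

    def test_tracking_accuracy_on_rendered_motion(self, rng):
        # >= 99% correct links on jittered scenes, oracle = truth ids
        from reactoscope.cells import PopulationParams, step_population

        params = VirtualSampleParams(image_shape=(256, 256))
        pop = make_population(30, (256, 256), rng)
        pp = PopulationParams(division_area=1e9, jitter_px=0.5)
        tracker = Tracker(max_disp=10.0)
        truth_of_track, correct, total = {}, 0, 0
        for frame in range(15):
            if frame:
                pop = step_population(pop, 3.0, rng, pp)
            img = snap_image(pop, "brightfield", 50.0, params, rng)
            res = segment(img)
            tracker.update(res, frame)
            pts = {c.id: c.centroid for c in pop}
            for t in tracker.tracks:
                if not t.present_at(frame):
                    continue
                pr, pc = t.centroids[frame]
                nearest = min(pts, key=lambda i: (pts[i][0] - pr) ** 2
                              + (pts[i][1] - pc) ** 2)
                if t.track_id in truth_of_track:
                    total += 1
                    correct += truth_of_track[t.track_id] == nearest
                else:
                    truth_of_track[t.track_id] = nearest
        assert total > 0
        assert correct / total >= 0.99


class TestErodeMask:
    def test_radius_zero_identity(self):
        mask = np.zeros((32, 32), bool)
        mask[10:20, 10:20] = True
        assert np.array_equal(erode_mask(mask, 0), mask)

    def test_disk_erosion_matches_analytic_area(self):
        mask = np.zeros((64, 64), bool)
        rr, cc = draw_disk((32, 32), 5.5)
        mask[rr, cc] = True
        out = erode_mask(mask, 2)
        # eroded disk radius ~3: area within a 1-px ring of pi*r^2
        lo = math.pi * 2.0 ** 2
        hi = math.pi * 4.0 ** 2
        assert lo <= out.sum() <= hi

    def test_over_erosion_falls_back_to_centroid_pixel(self):
        mask = np.zeros((32, 32), bool)
        rr, cc = draw_disk((16, 16), 3.5)
        mask[rr, cc] = True
        out = erode_mask(mask, 10)
        assert out.sum() == 1
        assert out[16, 16]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(radius=st.integers(0, 6), seed=st.integers(0, 1000))
    def test_anti_extensive_and_monotone(self, radius, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((48, 48), bool)
        rr, cc = draw_disk(tuple(rng.uniform(12, 36, 2)), rng.uniform(3, 9))
        mask[np.clip(rr, 0, 47), np.clip(cc, 0, 47)] = True
        out = erode_mask(mask, radius)
        assert not np.any(out & ~mask)  # anti-extensive
        if radius > 0:
            prev = erode_mask(mask, radius - 1)
            if out.sum() > 1:  # fallback pixel exempt from monotonicity
                assert not np.any(out & ~prev)
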