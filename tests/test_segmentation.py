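"""Background model, two-threshold detection, freezing, projections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from nematrack.segmentation import (
    BackgroundModel,
    DetectionParams,
    detect_blobs,
    freeze_regions,
    project,
    segment_video,
    trace_boundary,
    update_background,
)


def _bg(estimate, **kw):
    kw.setdefault("alpha_dark", 0.5)
    kw.setdefault("alpha_light", 0.05)
    return BackgroundModel(estimate=np.asarray(estimate, dtype=float), **kw)


class TestUpdateBackground:
    def test_identical_frame_leaves_estimate_unchanged(self):
        est = np.full((4, 4), 137.0)
        bg = _bg(est.copy())
        update_background(bg, est)
        np.testing.assert_array_equal(bg.estimate, est)

    def test_asymmetric_update_arithmetic(self):
        bg = _bg(np.array([[200.0, 100.0]]))
        update_background(bg, np.array([[100.0, 200.0]]))
        # darkening: 200 + 0.5*(100-200) = 150; lightening: 100 + 0.05*100 = 105
        np.testing.assert_allclose(bg.estimate, [[150.0, 105.0]])

    def test_lightening_converges_geometrically(self):
        bg = _bg(np.full((3, 3), 100.0), alpha_light=0.1, alpha_dark=0.4)
        frame = np.full((3, 3), 200.0)
        gap = 100.0
        for k in range(1, 20):
            update_background(bg, frame)
            expected = gap * (1 - 0.1) ** k
            np.testing.assert_allclose(frame - bg.estimate, expected, rtol=1e-9)

    def test_frozen_pixels_never_change(self):
        bg = _bg(np.full((4, 4), 200.0))
        bg.frozen_mask[1, 2] = True
        update_background(bg, np.full((4, 4), 50.0))
        assert bg.estimate[1, 2] == 200.0
        assert np.all(bg.estimate[0] == 125.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            update_background(_bg(np.zeros((4, 4))), np.zeros((5, 4)))

    def test_asymmetry_halving_time_ratio(self):
        """Dark steps converge ~alpha_dark/alpha_light times faster."""
        ad, al = 0.2, 0.02

        def halving_steps(start, target, alpha):
            est, k = start, 0
            while abs(est - target) > abs(start - target) / 2:
                est += alpha * (target - est)
                k += 1
            return k

        n_dark = halving_steps(200.0, 100.0, ad)
        n_light = halving_steps(100.0, 200.0, al)
        assert n_light / n_dark == pytest.approx(ad / al, rel=0.15)

    @settings(deadline=None, max_examples=30)
    @given(
        frames=hnp.arrays(
            np.uint8, (6, 5, 5), elements=st.integers(0, 255)
        )
    )
    def test_estimate_bounded_by_observed_intensities(self, frames):
        """Per pixel, the estimate stays within the range ever observed."""
        bg = BackgroundModel.from_frame(frames[0], 0.6, 0.3)
        lo = frames[0].astype(float).copy()
        hi = frames[0].astype(float).copy()
        for f in frames[1:]:
            update_background(bg, f)
            lo = np.minimum(lo, f)
            hi = np.maximum(hi, f)
            assert np.all(bg.estimate >= lo - 1e-9)
            assert np.all(bg.estimate <= hi + 1e-9)


def _disk_frame(centers, radius=8, bg=200, dark=100, shape=(64, 64)):
    frame = np.full(shape, float(bg))
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    painted = 0
    for cx, cy in centers:
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
        frame[mask] = dark
        painted += int(mask.sum())
    return frame, painted


class TestDetectBlobs:
    params = DetectionParams(detect_contrast=0.3, fill_contrast=0.15, min_area=20)

    def test_frame_equal_to_background_yields_nothing(self):
        bg = _bg(np.full((32, 32), 180.0))
        assert detect_blobs(np.full((32, 32), 180.0), bg, self.params) == []

    def test_single_dark_disk(self):
        frame, painted = _disk_frame([(30, 33)])
        bg = _bg(np.full(frame.shape, 200.0))
        blobs = detect_blobs(frame, bg, self.params)
        assert len(blobs) == 1
        b = blobs[0]
        assert abs(b.centroid[0] - 30) < 0.5 and abs(b.centroid[1] - 33) < 0.5
        assert b.area == painted  # fill recovers exactly the painted pixels
        assert abs(b.area - np.pi * 64) < 0.1 * np.pi * 64

    def test_two_separate_disks_give_two_blobs(self):
        frame, _ = _disk_frame([(15, 15), (45, 45)], radius=6)
        bg = _bg(np.full(frame.shape, 200.0))
        assert len(detect_blobs(frame, bg, self.params)) == 2

    def test_area_bounds_discard_components(self):
        frame, _ = _disk_frame([(30, 30)], radius=8)
        small_max = DetectionParams(min_area=20, max_area=100)
        bg = _bg(np.full(frame.shape, 200.0))
        assert detect_blobs(frame, bg, small_max) == []

    def test_contour_is_closed_and_starts_topmost_leftmost(self):
        frame, _ = _disk_frame([(30, 30)])
        bg = _bg(np.full(frame.shape, 200.0))
        (b,) = detect_blobs(frame, bg, self.params)
        c = b.contour
        assert np.abs(c[0] - c[-1]).max() <= 1  # closed: first adjacent to last
        ys = b.pixels[:, 1]
        assert c[0][1] == ys.min()  # topmost row
        # clockwise in image coords (y down): signed area of polygon >= 0
        x, y = c[:, 0].astype(float), c[:, 1].astype(float)
        signed = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) / 2
        assert signed > 0


class TestTraceBoundary:
    def test_single_pixel(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        np.testing.assert_array_equal(trace_boundary(mask), [[1, 1]])

    def test_boundary_covers_all_edge_pixels_of_rectangle(self):
        mask = np.zeros((8, 10), bool)
        mask[2:6, 3:9] = True
        c = trace_boundary(mask)
        expected = {
            (x, y)
            for y in range(2, 6)
            for x in range(3, 9)
            if y in (2, 5) or x in (3, 8)
        }
        assert {tuple(p) for p in c} == expected


class TestFreezeRegions:
    def test_no_blobs_unfreezes_everything(self):
        bg = _bg(np.full((16, 16), 200.0))
        bg.frozen_mask[:] = True
        freeze_regions(bg, [], margin=2)
        assert not bg.frozen_mask.any()

    def test_blob_and_margin_neighbourhood_frozen(self):
        frame, _ = _disk_frame([(8, 8)], radius=3, shape=(16, 16))
        bg = _bg(np.full((16, 16), 200.0))
        (b,) = detect_blobs(frame, bg, DetectionParams(min_area=5))
        freeze_regions(bg, [b], margin=2)
        for x, y in b.contour:
            assert bg.frozen_mask[y, x]
            assert bg.frozen_mask[
                max(y - 2, 0) : y + 3, max(x - 2, 0) : x + 3
            ].all()
        assert not bg.frozen_mask[0, 0]

    def test_stopped_object_keeps_contrast_against_stale_background(self):
        """After freezing, a motionless object stays detected indefinitely."""
        params = DetectionParams(min_area=5)
        bg = BackgroundModel.from_frame(
            np.full((40, 40), 200.0), alpha_dark=0.5, alpha_light=0.05
        )
        # object moves in, then stops for 30 frames
        positions = [(10, 20), (14, 20), (18, 20)] + [(22, 20)] * 30
        detected = []
        for cx, cy in positions:
            frame, _ = _disk_frame([(cx, cy)], radius=4, shape=(40, 40))
            blobs = detect_blobs(frame, bg, params)
            detected.append(len(blobs))
            freeze_regions(bg, blobs, margin=2)
            update_background(bg, frame)
        assert all(d == 1 for d in detected[1:])
        # background under the stopped object stayed bright
        assert bg.estimate[20, 22] > 180


class TestProject:
    def test_three_by_four_of_ones(self):
        frame = np.ones((3, 4))
        np.testing.assert_array_equal(project(frame, "vertical"), [3, 3, 3, 3])
        np.testing.assert_array_equal(project(frame, "horizontal"), [4, 4, 4])

    def test_dark_column_is_projection_minimum(self):
        frame = np.full((10, 12), 200)
        frame[:, 7] = 50
        assert int(np.argmin(project(frame, "vertical"))) == 7

    @settings(deadline=None, max_examples=50)
    @given(
        frame=hnp.arrays(np.uint8, (16, 16), elements=st.integers(0, 255))
    )
    def test_matches_naive_double_loop_and_conserves_total(self, frame):
        h = project(frame, "horizontal")
        v = project(frame, "vertical")
        naive_h = [sum(int(frame[i, j]) for j in range(16)) for i in range(16)]
        naive_v = [sum(int(frame[i, j]) for i in range(16)) for j in range(16)]
        assert h.tolist() == naive_h
        assert v.tolist() == naive_v
        assert h.sum() == v.sum() == frame.astype(np.int64).sum()


class TestOnSimulatorOutput:
    def test_fast_movers_detected_per_frame(self, fast_plate):
        """>= 95% per-frame detection of worms moving >= 2 px/frame."""
        cfg, frames, truth, blobs = fast_plate
        px = cfg.pixel_size
        tt = truth.table
        hits = tot = 0
        for f in range(50, cfg.n_frames):  # past background burn-in
            cents = np.array(
                [[b.centroid[0] * px, b.centroid[1] * px] for b in blobs[f]]
            ).reshape(-1, 2)
            for _, row in tt[tt.frame == f].iterrows():
                tot += 1
                if len(cents) and np.min(
                    np.linalg.norm(cents - [row.x_mm, row.y_mm], axis=1)
                ) < 0.5:
                    hits += 1
        assert hits / tot >= 0.95

    def test_no_detections_on_empty_noisy_plate(self):
        import nematrack as nt

        cfg = nt.PlateSimConfig(n_worms=0, duration=20.0, seed=2, noise_sd=3.0)
        frames, _ = nt.simulate_plate_video(cfg)
        blobs = segment_video(frames, cfg.frame_rate)
        assert sum(len(b) for b in blobs) == 0
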