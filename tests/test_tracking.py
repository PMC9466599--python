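"""Linking, collision handling, gap joining, and animal counting."""

import itertools

import numpy as np
import pytest

import nematrack as nt
from nematrack.segmentation import BlobOutline
from nematrack.tracking import (
    JoinParams,
    LinkParams,
    TrackRecord,
    estimate_count,
    join_records,
    link_frames,
)

PX = 0.04


def blob(x_px, y_px, t, frame, area=50):
    pt = np.array([[int(round(x_px)), int(round(y_px))]])
    return BlobOutline(
        contour=pt, centroid=(x_px, y_px), area=area, t=t,
        frame_index=frame, pixels=pt,
    )


def make_record(rid, t, xy, area=0.08):
    t = np.asarray(t, dtype=float)
    xy = np.asarray(xy, dtype=float).reshape(len(t), 2)
    return TrackRecord(
        record_id=rid, t=t, xy=xy,
        area=np.full(len(t), area), frames=np.arange(len(t)),
        outlines=[None] * len(t),
    )


class TestLinkFrames:
    def test_empty_stream_gives_no_records(self):
        assert link_frames([[], [], []]) == []

    def test_single_slow_worm_one_record(self):
        frames = [
            [blob(10 + 2 * f, 20, f * 0.1, f)] for f in range(30)
        ]
        records = link_frames(frames, LinkParams(max_step=0.5), pixel_size=PX)
        assert len(records) == 1
        assert records[0].n_samples == 30
        assert np.all(np.diff(records[0].t) > 0)

    def test_step_beyond_max_step_starts_new_record(self):
        frames = [[blob(10, 10, 0.0, 0)], [blob(40, 10, 0.1, 1)]]
        records = link_frames(frames, LinkParams(max_step=0.5), pixel_size=PX)
        assert len(records) == 2  # 30 px = 1.2 mm > 0.5 mm

    def test_crossing_worms_terminate_at_merge(self):
        """Two worms crossing: merged blob ends both records (>= 3 records)."""
        frames = []
        f = 0
        for step in range(8):  # approach
            frames.append(
                [blob(10 + 3 * step, 20, f * 0.1, f), blob(58 - 3 * step, 20, f * 0.1, f)]
            )
            f += 1
        for step in range(3):  # merged: one blob, double area
            frames.append([blob(36, 20, f * 0.1, f, area=100)])
            f += 1
        for step in range(8):  # separate again
            frames.append(
                [blob(40 + 3 * step, 20, f * 0.1, f), blob(30 - 3 * step, 20, f * 0.1, f)]
            )
            f += 1
        records = link_frames(frames, LinkParams(max_step=0.5), pixel_size=PX)
        assert len(records) >= 3
        # both pre-merge records end at the merge
        ends = sorted(r.t_end for r in records)
        assert ends[0] == ends[1] == pytest.approx(0.7)
        # every blob belongs to exactly one record
        assert sum(r.n_samples for r in records) == sum(len(fr) for fr in frames)


class TestJoinRecords:
    def test_feasible_gap_is_joined(self):
        r1 = make_record(0, [9.0, 10.0], [(0.0, 0.0), (0.0, 0.0)])
        r2 = make_record(1, [11.0, 12.0], [(0.5, 0.0), (0.5, 0.0)])
        joined = join_records([r1, r2], JoinParams(v_max=1.0, max_gap=30.0))
        assert len(joined) == 1  # 0.5 mm <= 1.0 mm/s * 1 s
        assert joined[0].source_ids == [0, 1]

    def test_too_far_gap_not_joined(self):
        r1 = make_record(0, [9.0, 10.0], [(0.0, 0.0), (0.0, 0.0)])
        r2 = make_record(1, [11.0, 12.0], [(2.0, 0.0), (2.0, 0.0)])
        assert len(join_records([r1, r2], JoinParams(v_max=1.0))) == 2

    def test_gap_beyond_max_gap_not_joined(self):
        r1 = make_record(0, [0.0, 1.0], [(0.0, 0.0), (0.0, 0.0)])
        r2 = make_record(1, [40.0, 41.0], [(0.1, 0.0), (0.1, 0.0)])
        assert len(join_records([r1, r2], JoinParams(max_gap=30.0))) == 2

    def test_incompatible_area_not_joined(self):
        r1 = make_record(0, [9.0, 10.0], [(0.0, 0.0), (0.0, 0.0)], area=0.08)
        r2 = make_record(1, [11.0, 12.0], [(0.1, 0.0), (0.1, 0.0)], area=0.30)
        assert len(join_records([r1, r2], JoinParams(area_tolerance=0.5))) == 2
        assert len(join_records([r1, r2], JoinParams(area_tolerance=None))) == 1

    def test_chain_of_three_fragments_rejoins_to_one(self):
        frags = [
            make_record(0, [0.0, 5.0], [(1.0, 1.0), (1.5, 1.0)]),
            make_record(1, [7.0, 12.0], [(1.6, 1.1), (2.0, 1.5)]),
            make_record(2, [14.0, 20.0], [(2.1, 1.6), (2.5, 2.0)]),
        ]
        joined = join_records(frags)
        assert len(joined) == 1
        assert np.all(np.diff(joined[0].t) > 0)
        assert estimate_count(joined, (0.0, 20.0)) == 1

    def test_idempotent(self):
        frags = [
            make_record(0, [0.0, 5.0], [(1.0, 1.0), (1.5, 1.0)]),
            make_record(1, [7.0, 12.0], [(1.6, 1.1), (2.0, 1.5)]),
            make_record(2, [30.0, 35.0], [(5.0, 5.0), (5.5, 5.0)]),
        ]
        once = join_records(frags)
        twice = join_records(once)
        assert len(once) == len(twice)
        for a, b in zip(once, twice):
            np.testing.assert_array_equal(a.t, b.t)
            np.testing.assert_array_equal(a.xy, b.xy)

    def test_earliest_ending_predecessor_wins(self):
        early = make_record(0, [0.0, 5.0], [(0.0, 0.0), (0.0, 0.0)])
        late = make_record(1, [0.0, 8.0], [(0.0, 0.1), (0.0, 0.1)])
        succ = make_record(2, [10.0, 12.0], [(0.0, 0.0), (0.0, 0.0)])
        joined = join_records([early, late, succ])
        by_src = {tuple(r.source_ids) for r in joined}
        assert (0, 2) in by_src and (1,) in by_src

    def _random_instance(self, rng, n):
        recs = []
        t = 0.0
        for i in range(n):
            t0 = rng.uniform(0, 40)
            span = rng.uniform(1, 10)
            x0, y0 = rng.uniform(0, 5, 2)
            recs.append(
                make_record(
                    i, [t0, t0 + span],
                    [(x0, y0), (x0 + rng.uniform(-1, 1), y0 + rng.uniform(-1, 1))],
                )
            )
        return recs

    def _brute_force_max_joins(self, records, params):
        """Maximum achievable number of joins over all valid chain sets."""
        records = sorted(records, key=lambda r: (r.t_start, r.record_id))

        def compatible(a, b):
            gap = b.t_start - a.t_end
            if not 0 < gap <= params.max_gap:
                return False
            if np.linalg.norm(b.xy[0] - a.xy[-1]) > params.v_max * gap:
                return False
            m = 0.5 * (a.mean_area + b.mean_area)
            return (
                params.area_tolerance is None
                or m == 0
                or abs(a.mean_area - b.mean_area) / m <= params.area_tolerance
            )

        n = len(records)
        best = 0
        edges = [
            (i, j)
            for i, j in itertools.permutations(range(n), 2)
            if compatible(records[i], records[j])
        ]

        def search(used_pred, used_succ, count, start):
            nonlocal best
            best = max(best, count)
            for k in range(start, len(edges)):
                i, j = edges[k]
                if i not in used_pred and j not in used_succ:
                    search(used_pred | {i}, used_succ | {j}, count + 1, k + 1)

        search(frozenset(), frozenset(), 0, 0)
        return best

    def test_greedy_matches_exhaustive_join_count_on_small_instances(self):
        params = JoinParams()
        rng = np.random.default_rng(42)
        for _ in range(40):
            recs = self._random_instance(rng, int(rng.integers(2, 7)))
            joined = join_records(recs, params)
            greedy_joins = len(recs) - len(joined)
            assert greedy_joins == self._brute_force_max_joins(recs, params)


class TestEstimateCount:
    def test_empty(self):
        assert estimate_count([], (0.0, 10.0)) == 0

    def test_non_joinable_records_counted(self):
        recs = [
            make_record(i, [1.0, 9.0], [(i, i), (i, i)]) for i in range(5)
        ]
        assert estimate_count(recs, (0.0, 10.0)) == 5

    def test_records_outside_window_excluded(self):
        recs = [make_record(0, [1.0, 2.0], [(0, 0), (0, 0)])]
        assert estimate_count(recs, (5.0, 10.0)) == 0

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            estimate_count([], (5.0, 5.0))

    def test_joining_never_increases_count(self, small_plate):
        cfg, frames, truth, blobs, joined = small_plate
        raw = link_frames(blobs)
        w = (10.0, 50.0)
        assert estimate_count(joined, w) <= estimate_count(raw, w)
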