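"""Window scores, median-filtered maxima, plate and condition aggregation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nematrack.metrics import AnimalTimecourse
from nematrack.summary import (
    AnimalScore,
    ProtocolSpec,
    WindowSpec,
    build_condition_timecourse,
    default_windows,
    median_filter_speed,
    score_animal,
    summarize_plate,
)


def brute_force_median5(x):
    """Oracle: window-5 running median with replicate-padded ends."""
    x = list(x)
    padded = [x[0], x[0]] + x + [x[-1], x[-1]]
    return np.array(
        [np.median(padded[i : i + 5]) for i in range(len(x))]
    )


class TestMedianFilter:
    def test_single_spike_suppressed(self):
        filtered = median_filter_speed([0, 0, 10, 0, 0])
        np.testing.assert_array_equal(filtered, np.zeros(5))

    def test_ramp_against_oracle(self):
        x = [1, 2, 3, 4, 5, 6, 7]
        np.testing.assert_array_equal(median_filter_speed(x), brute_force_median5(x))

    @settings(deadline=None, max_examples=60)
    @given(
        x=st.lists(st.floats(0, 100, allow_nan=False), min_size=5, max_size=25)
    )
    def test_matches_brute_force_oracle(self, x):
        np.testing.assert_allclose(median_filter_speed(x), brute_force_median5(x))

    @settings(deadline=None, max_examples=40)
    @given(
        x=st.lists(st.floats(0, 100, allow_nan=False), min_size=5, max_size=25)
    )
    def test_filtered_max_bounded_by_raw_extrema(self, x):
        filt = median_filter_speed(x)
        assert filt.max() <= max(x) + 1e-12
        assert filt.max() >= min(x) - 1e-12


def tc_with_speeds(speeds, t0=440.0, dt=0.5, rid=0, length=1.0):
    n = len(speeds)
    t = t0 + np.arange(n) * dt
    table = pd.DataFrame(
        {
            "t_s": t,
            "x_mm": np.zeros(n),
            "y_mm": np.zeros(n),
            "length_mm": length,
            "area_mm2": 0.08,
            "speed_mm_s": np.asarray(speeds, dtype=float),
        }
    )
    return AnimalTimecourse(record_id=rid, table=table)


AROUSED = WindowSpec("aroused", 440.0, 450.0)


class TestScoreAnimal:
    def test_absent_animal_gives_no_score(self):
        tc = tc_with_speeds([1.0] * 10, t0=100.0)
        assert score_animal(tc, AROUSED) is None

    def test_constant_speed(self):
        s = score_animal(tc_with_speeds([2.0] * 12), AROUSED)
        assert s.mean_speed == pytest.approx(2.0)
        assert s.max_speed == pytest.approx(2.0)

    def test_spike_removed_from_max(self):
        s = score_animal(tc_with_speeds([0, 0, 10, 0, 0]), AROUSED)
        assert s.max_speed == 0.0
        assert s.mean_speed == pytest.approx(2.0)

    def test_max_equals_oracle_max(self):
        speeds = [1, 2, 3, 4, 5, 6, 7]
        s = score_animal(tc_with_speeds(speeds), AROUSED)
        assert s.max_speed == brute_force_median5(speeds).max()

    def test_fewer_than_five_samples_no_max(self):
        s = score_animal(tc_with_speeds([1.0] * 4), AROUSED)
        assert np.isnan(s.max_speed)
        assert s.mean_speed == pytest.approx(1.0)


def scores_with_max(values, window="aroused"):
    return [
        AnimalScore(
            record_id=i, window=window, n_samples=10,
            mean_length=1.0, mean_area=0.08, mean_speed=v / 2, max_speed=v,
        )
        for i, v in enumerate(values)
    ]


class TestSummarizePlate:
    def test_four_animals_mean_and_sem(self):
        ps = summarize_plate(scores_with_max([1, 2, 3, 4]), "p1", 0.0)
        assert ps.table.loc["aroused", "mean_max_speed"] == pytest.approx(2.5)
        assert ps.table.loc["aroused", "sem_max_speed"] == pytest.approx(
            np.std([1, 2, 3, 4], ddof=1) / 2, abs=1e-6
        )
        assert ps.table.loc["aroused", "sem_max_speed"] == pytest.approx(0.6455, abs=1e-4)
        assert ps.include_flag

    def test_two_animals_excluded_but_means_recorded(self):
        ps = summarize_plate(scores_with_max([1, 2]), "p1", 0.0)
        assert not ps.include_flag
        assert ps.table.loc["aroused", "mean_max_speed"] == pytest.approx(1.5)

    def test_zero_animals(self):
        ps = summarize_plate([], "p1", 0.0)
        assert not ps.include_flag
        assert ps.n_animals("aroused") == 0


class TestConditionTimecourse:
    def _plate(self, pid, session_h, maxima):
        return summarize_plate(scores_with_max(maxima), pid, session_h)

    def test_single_plate_point_without_sem(self):
        ps = self._plate("p1", 0.0, [1, 2, 3])
        ct = build_condition_timecourse([ps], {"p1": "control"})
        row = ct.table.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert np.isnan(row["sem"])

    def test_excluded_plates_emit_no_point(self):
        ps = self._plate("p1", 0.0, [1, 2])  # only 2 animals
        ct = build_condition_timecourse([ps], {"p1": "control"})
        assert ct.table.empty  # absence of data, not a zero

    def test_unknown_condition_warned_and_excluded(self):
        ps = self._plate("p1", 0.0, [1, 2, 3])
        with pytest.warns(UserWarning, match="no condition"):
            ct = build_condition_timecourse([ps], {})
        assert ct.table.empty

    def test_two_conditions_interleaved(self):
        plates = [
            self._plate("a1", 0.0, [1, 2, 3]),
            self._plate("b1", 0.0, [4, 5, 6]),
            self._plate("a2", 7.0, [2, 3, 4]),
            self._plate("b2", 7.0, [5, 6, 7]),
        ]
        cond = {"a1": "ctl", "a2": "ctl", "b1": "rnai", "b2": "rnai"}
        ct = build_condition_timecourse(plates, cond, session_period_h=6.0)
        assert len(ct.table) == 4
        assert set(ct.table["condition"]) == {"ctl", "rnai"}
        assert set(ct.table["bin_start_h"]) == {0.0, 6.0}

    def test_aggregation_linearity(self):
        plates_1x = [
            self._plate("p1", 0.0, [1, 2, 3]),
            self._plate("p2", 0.0, [2, 3, 4]),
        ]
        plates_3x = [
            self._plate("p1", 0.0, [3, 6, 9]),
            self._plate("p2", 0.0, [6, 9, 12]),
        ]
        cond = {"p1": "c", "p2": "c"}
        m1 = build_condition_timecourse(plates_1x, cond).table["mean"].iloc[0]
        m3 = build_condition_timecourse(plates_3x, cond).table["mean"].iloc[0]
        assert m3 == pytest.approx(3 * m1)


def test_plot_condition_timecourse_renders_series():
    import matplotlib

    matplotlib.use("Agg")
    from nematrack.summary import plot_condition_timecourse

    plates = [
        summarize_plate(scores_with_max([1, 2, 3]), "p1", 0.0),
        summarize_plate(scores_with_max([2, 3, 4]), "p2", 0.0),
        summarize_plate(scores_with_max([1, 2, 3]), "p1b", 7.0),
    ]
    cond = {"p1": "c", "p2": "c", "p1b": "c"}
    ct = build_condition_timecourse(plates, cond)
    ax = plot_condition_timecourse(ct)
    assert len(ax.lines) >= 1


class TestProtocol:
    def test_default_timing(self):
        p = ProtocolSpec()
        assert p.tap_times[0] == 300.0
        assert p.tap_times[-1] == 410.0
        assert len(p.tap_times) == 12
        assert p.recording_end - p.last_tap == pytest.approx(120.0)

    def test_windows_inside_recording(self):
        p = ProtocolSpec()
        for w in default_windows():
            assert p.recording_start <= w.t0 < w.t1 <= p.recording_end

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec(tap_train_start=500.0)


class TestEndToEndArousal:
    def test_aroused_window_speed_elevated_vs_calm(self, protocol_plates):
        """Arousal multiplier 2.0 yields aroused/calm mean-speed ratio in
        [1.5, 2.5] given the exponential arousal decay at the window lag."""
        from nematrack.metrics import MetricsParams, compute_timecourses, filter_animals
        from nematrack.summary import score_plate_animals

        ratios = []
        for cfg, truth, joined in protocol_plates:
            params = MetricsParams(length_stride=5)
            tcs = filter_animals(compute_timecourses(joined, params), params)
            scores = score_plate_animals(tcs)
            ps = summarize_plate(scores, "p", 0.0)
            assert ps.include_flag
            calm = ps.table.loc["calm", "mean_mean_speed"]
            aroused = ps.table.loc["aroused", "mean_mean_speed"]
            ratios.append(aroused / calm)
        assert all(1.5 <= r <= 2.5 for r in ratios)
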