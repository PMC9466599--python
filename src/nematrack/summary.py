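"""Windowed per-animal scores, plate aggregation, condition timecourses.

The standard assay records for 530 s per session: an agitating triple tap
before recording, 300 s of cooldown, a habituation train of 12 taps at 10 s
inter-stimulus interval, then 80 s more of recording.  Per-animal scores are
taken in three windows: "initial" (10-20 s, freshly agitated), "calm"
(275-295 s, back at baseline) and "aroused" (440-450 s, 30 s after the last
tap, during the prolonged post-train activity increase).  Each window yields
mean length, mean area, mean speed, and maximum speed after a 5-point
running median (replicate-padded ends) that suppresses single-sample
spikes.  Plates contribute to condition curves only when at least three
animals were measured; sessions are binned into 6 h cycles, and a bin with
no included plate emits no point (absence of data is not a zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .metrics import AnimalTimecourse

__all__ = [
    "ProtocolSpec",
    "WindowSpec",
    "AnimalScore",
    "PlateSummary",
    "ConditionTimecourse",
    "default_windows",
    "score_animal",
    "score_plate_animals",
    "summarize_plate",
    "build_condition_timecourse",
]


@dataclass
class ProtocolSpec:
    """Timing of the standard tap-habituation recording session."""

    triple_tap_at: float = -5.0  # s, before recording starts
    recording_start: float = 0.0
    tap_train_start: float = 300.0
    n_taps: int = 12
    isi: float = 10.0
    recording_end: float = 530.0
    session_period_h: float = 6.0

    def __post_init__(self) -> None:
        if self.tap_train_start + (self.n_taps - 1) * self.isi >= self.recording_end:
            raise ValueError("tap train must end before recording_end")

    @property
    def tap_times(self) -> tuple[float, ...]:
        return tuple(
            self.tap_train_start + i * self.isi for i in range(self.n_taps)
        )

    @property
    def last_tap(self) -> float:
        return self.tap_times[-1]


@dataclass
class WindowSpec:
    """A named scoring window within the recording."""

    name: str
    t0: float
    t1: float

    def __post_init__(self) -> None:
        if self.t1 <= self.t0:
            raise ValueError("window requires t1 > t0")


def default_windows() -> list[WindowSpec]:
    return [
        WindowSpec("initial", 10.0, 20.0),
        WindowSpec("calm", 275.0, 295.0),
        WindowSpec("aroused", 440.0, 450.0),
    ]


@dataclass
class AnimalScore:
    """Windowed summary for one animal; max_speed is median-filtered first."""

    record_id: int
    window: str
    n_samples: int
    mean_length: float
    mean_area: float
    mean_speed: float
    max_speed: float  # NaN when fewer than 5 speed samples


def median_filter_speed(speed: np.ndarray, size: int = 5) -> np.ndarray:
    """5-point running median with replicate-padded ends."""
    return median_filter(np.asarray(speed, dtype=float), size=size, mode="nearest")


def score_animal(
    timecourse: AnimalTimecourse, window: WindowSpec
) -> AnimalScore | None:
    """Score one animal in one window; None if the animal is absent there.

    Means are over in-window samples; max_speed is the maximum of the
    5-point running median of the in-window speed sequence and requires at
    least 5 speed samples (NaN otherwise).
    """
    sub = timecourse.window(window.t0, window.t1)
    if sub.empty:
        return None
    speeds = sub["speed_mm_s"].to_numpy(dtype=float)
    speeds = speeds[np.isfinite(speeds)]
    if speeds.size >= 5:
        max_speed = float(median_filter_speed(speeds).max())
    else:
        max_speed = float("nan")
    return AnimalScore(
        record_id=timecourse.record_id,
        window=window.name,
        n_samples=len(sub),
        mean_length=float(sub["length_mm"].mean()),
        mean_area=float(sub["area_mm2"].mean()),
        mean_speed=float(np.mean(speeds)) if speeds.size else float("nan"),
        max_speed=max_speed,
    )


def score_plate_animals(
    timecourses: list[AnimalTimecourse],
    windows: list[WindowSpec] | None = None,
) -> list[AnimalScore]:
    """Score every animal in every window, dropping absent combinations."""
    if windows is None:
        windows = default_windows()
    out = []
    for tc in timecourses:
        for w in windows:
            s = score_animal(tc, w)
            if s is not None:
                out.append(s)
    return out


_FIELDS = ("mean_length", "mean_area", "mean_speed", "max_speed")


@dataclass
class PlateSummary:
    """Per-window aggregates for one plate in one session.

    ``table`` is indexed by window name with columns n_animals and
    mean/sem of each score field; a window's include flag is n_animals >= 3.
    ``count_window`` names the window whose count gates inclusion in
    condition curves (default the aroused window, i.e. animals actually
    measured for the headline metric).
    """

    plate_id: str
    session_time_h: float
    table: pd.DataFrame
    count_window: str = "aroused"

    @property
    def include_flag(self) -> bool:
        if self.count_window not in self.table.index:
            return False
        return bool(self.table.loc[self.count_window, "n_animals"] >= 3)

    def n_animals(self, window: str) -> int:
        if window not in self.table.index:
            return 0
        return int(self.table.loc[window, "n_animals"])


def summarize_plate(
    scores: list[AnimalScore],
    plate_id: str,
    session_time_h: float,
    count_window: str = "aroused",
) -> PlateSummary:
    """Aggregate animal scores into per-window n / mean / SEM.

    SEM is the sample SD (n-1) over sqrt(n), reported only for n >= 2.
    Windows with zero animals appear with n_animals = 0 and no means.
    """
    rows = {}
    by_window: dict[str, list[AnimalScore]] = {}
    for s in scores:
        by_window.setdefault(s.window, []).append(s)
    for wname, group in by_window.items():
        row: dict[str, float] = {"n_animals": len(group)}
        for f in _FIELDS:
            vals = np.array([getattr(s, f) for s in group], dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                row[f"mean_{f}"] = np.nan
                row[f"sem_{f}"] = np.nan
                continue
            row[f"mean_{f}"] = float(vals.mean())
            row[f"sem_{f}"] = (
                float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size >= 2 else np.nan
            )
        rows[wname] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "window"
    return PlateSummary(
        plate_id=plate_id,
        session_time_h=session_time_h,
        table=table,
        count_window=count_window,
    )


@dataclass
class ConditionTimecourse:
    """Across-plate averages per condition per 6 h session bin.

    ``table`` columns: condition, bin_start_h, n_plates, and mean/sem of the
    plate-level means of the selected window/field.  SEM across plates, only
    for n_plates >= 2; bins with zero included plates are absent.
    """

    window: str
    score_field: str
    table: pd.DataFrame


def build_condition_timecourse(
    summaries: list[PlateSummary],
    plate_conditions: dict[str, str],
    window: str = "aroused",
    score_field: str = "max_speed",
    session_period_h: float = 6.0,
) -> ConditionTimecourse:
    """Average included plates per condition per session bin.

    Bins are [k * period, (k+1) * period) from experiment start, assigned by
    each recording's start time.  Plates failing the >= 3-animal rule are
    skipped; plates with no condition label are excluded with a warning.
    """
    col = f"mean_{score_field}"
    rows: dict[tuple[str, int], list[float]] = {}
    for ps in summaries:
        cond = plate_conditions.get(ps.plate_id)
        if cond is None:
            warnings.warn(f"plate {ps.plate_id} has no condition label; excluded")
            continue
        if not ps.include_flag:
            continue
        if window not in ps.table.index or col not in ps.table.columns:
            continue
        val = ps.table.loc[window, col]
        if not np.isfinite(val):
            continue
        k = int(np.floor(ps.session_time_h / session_period_h))
        rows.setdefault((cond, k), []).append(float(val))
    out = []
    for (cond, k), vals in sorted(rows.items()):
        arr = np.array(vals)
        out.append(
            {
                "condition": cond,
                "bin_start_h": k * session_period_h,
                "n_plates": len(arr),
                "mean": float(arr.mean()),
                "sem": float(arr.std(ddof=1) / np.sqrt(len(arr)))
                if len(arr) >= 2
                else np.nan,
            }
        )
    table = pd.DataFrame(
        out, columns=["condition", "bin_start_h", "n_plates", "mean", "sem"]
    )
    return ConditionTimecourse(window=window, score_field=score_field, table=table)


def plot_condition_timecourse(ct: ConditionTimecourse, ax=None, **plot_kw):
    """Plot per-condition means vs age with SEM error bars across plates.

    Returns the matplotlib Axes.  Bins without included plates are simply
    absent from the series (gaps, not zeros).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for cond, sub in ct.table.groupby("condition"):
        ax.errorbar(
            sub["bin_start_h"] / 24.0, sub["mean"], yerr=sub["sem"],
            label=str(cond), marker="o", capsize=2, **plot_kw,
        )
    ax.set_xlabel("age (days from recording start)")
    ax.set_ylabel(f"{ct.window} {ct.score_field} (mm/s)")
    ax.legend()
    return ax
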