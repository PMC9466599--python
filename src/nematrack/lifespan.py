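"""Death-time scoring from session snapshots and survival estimation.

Moving-object tracking cannot see animals that have stopped moving, so
lifespan is scored from the static snapshots saved each session.  Three
successive snapshots (spanning 12 h at the standard 6 h cadence) are
intensity-inverted and placed in the red, green and blue channels of one
overlay: a truly motionless (dead) worm contributes identically to all
three channels and appears gray, while any movement between sessions leaves
colored fringes.  A per-region colorfulness score (mean channel range)
quantifies this, and an experimental threshold rule converts colorfulness
trajectories into death calls; scoring by eye from the overlays remains the
reference procedure.

Death times are interval-censored between the last session seen moving and
the first seen still; the Kaplan-Meier product-limit estimator below places
interval events at the interval midpoint by default (configurable) and
treats censored records as at-risk only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OverlayImage",
    "DeathRecord",
    "SurvivalCurve",
    "make_overlay",
    "colorfulness_score",
    "call_death_session",
    "km_estimate",
]


@dataclass
class OverlayImage:
    """RGB temporal overlay; earliest session in red, latest in blue."""

    rgb: np.ndarray  # uint8, (H, W, 3)
    channel_order: tuple[str, ...] = ("earliest", "middle", "latest")

    def channel_frame(self, channel: int) -> np.ndarray:
        """Recover the original grayscale frame from one channel (bit-exact)."""
        return 255 - self.rgb[..., channel]


@dataclass
class DeathRecord:
    """One scored death (or censoring) on a plate.

    Times are in the session clock (hours or days -- any consistent unit);
    a censored record means the animal was last seen alive at t_lo.
    """

    plate_id: str
    x_mm: float
    y_mm: float
    t_lo: float
    t_hi: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.censored and not self.t_hi > self.t_lo:
            raise ValueError("death interval requires t_hi > t_lo")


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S(t) step function over event times."""

    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    median: float  # NaN when S never reaches 0.5

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def make_overlay(
    frames: Sequence[np.ndarray],
) -> OverlayImage:
    """Overlay three successive session snapshots as inverted R, G, B.

    Each channel is exactly 255 minus the corresponding grayscale frame, no
    normalization; where the three frames agree the overlay is gray.
    """
    if len(frames) != 3:
        raise ValueError("need exactly three session snapshots")
    arrs = [np.asarray(f) for f in frames]
    if not (arrs[0].shape == arrs[1].shape == arrs[2].shape):
        raise ValueError("snapshot shapes differ")
    rgb = np.stack([255 - a.astype(np.uint8) for a in arrs], axis=-1)
    return OverlayImage(rgb=rgb)


def colorfulness_score(
    overlay: OverlayImage,
    region: tuple[slice, slice] | np.ndarray | None = None,
) -> float:
    """Mean over the region of (max - min) across channels.

    Zero for a gray (motionless) region; up to 255 where a worm was present
    in one session only.  ``region`` is a pair of slices or a boolean mask;
    None scores the whole image.
    """
    rgb = overlay.rgb.astype(np.int16)
    rng = rgb.max(axis=-1) - rgb.min(axis=-1)
    if region is None:
        sel = rng
    elif isinstance(region, tuple):
        sel = rng[region]
    else:
        sel = rng[np.asarray(region, dtype=bool)]
    if sel.size == 0:
        raise ValueError("empty region")
    return float(sel.mean())


def call_death_session(
    scores: Sequence[float],
    noise_floor: float,
    noise_sd: float,
) -> int | None:
    """Start of the trailing run of colorfulness below noise_floor + 2 * SD.

    Experimental helper for automating the manual overlay call; ``scores``
    is the colorfulness trajectory of the death site's neighbourhood across
    successive overlays.  The site may be gray early on (before the animal
    arrives there), so the call is the first index after the *last* colorful
    overlay, i.e. the beginning of the final motionless stretch.  Returns
    None if the site never shows movement or never stills.
    """
    thresh = noise_floor + 2.0 * noise_sd
    above = [i for i, s in enumerate(scores) if s >= thresh]
    if not above:
        return None
    start = above[-1] + 1
    return start if start < len(scores) else None


def km_estimate(
    records: Sequence[DeathRecord] | pd.DataFrame,
    interval_placement: Literal["midpoint", "right", "left"] = "midpoint",
) -> SurvivalCurve:
    """Kaplan-Meier product-limit survival estimate.

    Interval-scored deaths contribute an event at the interval midpoint (or
    the chosen endpoint); censored records leave the risk set at t_lo
    without an event.  The median is the smallest event time with
    S(t) <= 0.5, NaN if never reached.
    """
    if isinstance(records, pd.DataFrame):
        recs = [
            DeathRecord(
                plate_id=str(r.get("plate_id", "")),
                x_mm=float(r.get("x_mm", np.nan)),
                y_mm=float(r.get("y_mm", np.nan)),
                t_lo=float(r["t_lo"]),
                t_hi=float(r["t_hi"]) if np.isfinite(r.get("t_hi", np.nan)) else float(r["t_lo"]),
                censored=bool(r.get("censored", False)),
            )
            for _, r in records.iterrows()
        ]
    else:
        recs = list(records)
    if not recs:
        raise ValueError("no records")
    times = []
    events = []
    for r in recs:
        if r.censored:
            times.append(r.t_lo)
            events.append(0)
        else:
            if interval_placement == "midpoint":
                times.append(0.5 * (r.t_lo + r.t_hi))
            elif interval_placement == "right":
                times.append(r.t_hi)
            else:
                times.append(r.t_lo)
            events.append(1)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    times = times[order]
    events = events[order]

    uniq = np.unique(times[events == 1])
    n = len(times)
    surv = []
    at_risk = []
    s = 1.0
    for t in uniq:
        n_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n_risk
        at_risk.append(n_risk)
        surv.append(s)
    surv_arr = np.asarray(surv)
    below = np.nonzero(surv_arr <= 0.5)[0]
    median = float(uniq[below[0]]) if below.size else float("nan")
    return SurvivalCurve(
        times=uniq,
        at_risk=np.asarray(at_risk, dtype=int),
        survival=surv_arr,
        median=median,
    )
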