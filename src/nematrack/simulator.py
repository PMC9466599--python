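"""Synthetic plate videos and cohort score tables with known ground truth.

The video generator renders elongated, dark, undulating worm bodies on a
bright plate background (default intensity 200, worm body well above the
1.6:1 background:body contrast floor) at the instrument scale of 40 um per
pixel, and records exact per-frame positions, midlines, lengths and speeds.
Worms move by a persistent random walk; mechanical taps multiply their speed
by an arousal factor that decays exponentially back to baseline, emulating
the prolonged activity increase after a tap train.

The cohort generator produces plate x timepoint score tables (nominally
aroused maximum speed in mm/s) with three multiplicative lognormal variance
components -- experiment, plate, and per-animal sampling -- so the
variance-decomposition and power machinery can be validated against known
inputs.

All randomness flows through a single numpy PCG64 generator seeded from the
config, so equal seeds give bit-identical frames and tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .stats import ScoreMatrix

__all__ = [
    "WormModel",
    "PlateSimConfig",
    "GroundTruth",
    "CohortSimConfig",
    "simulate_plate_video",
    "simulate_cohort_scores",
    "simulate_lifespan_snapshots",
    "default_mean_trajectory",
]


@dataclass
class WormModel:
    """Geometry and kinematics of one simulated animal.

    body_length is the full tip-to-tip extent in mm; body_width the maximum
    body diameter. baseline_speed is the calm crawling speed; after a tap the
    speed is multiplied by up to ``arousal_multiplier``, decaying back to 1.
    heading_persistence in [0, 1] controls how slowly the heading direction
    wanders (1 = straight line).
    """

    body_length: float = 1.0
    body_width: float = 0.08
    undulation_amplitude: float = 0.08
    baseline_speed: float = 0.15
    arousal_multiplier: float = 2.0
    heading_persistence: float = 0.9

    def __post_init__(self) -> None:
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")
        if not 0 < self.body_width < self.body_length:
            raise ValueError("body_width must be in (0, body_length)")
        if self.baseline_speed < 0:
            raise ValueError("baseline_speed must be >= 0")
        if self.arousal_multiplier < 1:
            raise ValueError("arousal_multiplier must be >= 1")
        if not 0 <= self.heading_persistence <= 1:
            raise ValueError("heading_persistence must be in [0, 1]")


@dataclass
class PlateSimConfig:
    """Acquisition and arena parameters for one synthetic plate video.

    Defaults are desk-scale: 256 x 256 px (10.24 x 10.24 mm at 40 um/px),
    10 frames/s, <= 60 s.  The instrument's full scale is reached purely by
    changing these numbers.
    """

    n_worms: int = 5
    arena_size: tuple[float, float] = (10.24, 10.24)  # (width, height) mm
    pixel_size: float = 0.04  # mm per pixel
    frame_rate: float = 10.0  # frames per second
    duration: float = 60.0  # seconds
    background_level: float = 200.0
    worm_darkness: float = 110.0  # body intensity; contrast 200/110 > 1.6
    tap_times: tuple[float, ...] = ()
    noise_sd: float = 2.0
    seed: int = 0
    arousal_tau: float = 90.0  # s, e-folding decay of tap arousal
    record_midlines: bool = True

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_worms < 0:
            raise ValueError("n_worms must be >= 0")
        if self.worm_darkness <= 0 or self.background_level <= 0:
            raise ValueError("intensities must be positive")
        if self.background_level / self.worm_darkness < 1.6:
            raise ValueError(
                "background:worm contrast ratio below 1.6:1 "
                f"({self.background_level}:{self.worm_darkness})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """Frame shape (rows, cols)."""
        w, h = self.arena_size
        return (int(round(h / self.pixel_size)), int(round(w / self.pixel_size)))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class GroundTruth:
    """Exact per-frame state of every simulated worm.

    ``table`` has one row per worm per frame with columns worm_id, frame,
    t_s, x_mm, y_mm (coverage-weighted centroid of the rendered body -- the
    image centroid an ideal detector would measure), length_mm, speed_mm_s
    (commanded centre speed). ``midlines`` (optional) is an array of shape
    (n_frames, n_worms, 11, 2) of midline points in mm (x, y).
    """

    table: pd.DataFrame
    midlines: np.ndarray | None = None

    @property
    def n_worms(self) -> int:
        if self.table.empty:
            return 0
        return int(self.table["worm_id"].nunique())

    def worm(self, worm_id: int) -> pd.DataFrame:
        return self.table[self.table["worm_id"] == worm_id].reset_index(drop=True)


def _midline_points(
    center: np.ndarray,
    heading: float,
    phase: float,
    worm: WormModel,
    n_points: int = 51,
) -> np.ndarray:
    """Midline polyline (n_points, 2) in mm, arc length == body_length.

    The spine is a sinusoid in the worm frame, rescaled about its centroid so
    its polyline arc length equals body_length exactly; its centroid is at
    ``center``.
    """
    L = worm.body_length
    s = np.linspace(0.0, L, n_points)
    u = np.array([math.cos(heading), math.sin(heading)])
    nvec = np.array([-u[1], u[0]])
    n_waves = 1.5
    lateral = worm.undulation_amplitude * np.sin(2 * math.pi * n_waves * s / L + phase)
    pts = np.outer(s - L / 2, u) + np.outer(lateral, nvec)
    # rescale so polyline arc length == L
    seg = np.diff(pts, axis=0)
    arc = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
    if arc > 0:
        pts = pts * (L / arc)
    pts = pts - pts.mean(axis=0)
    return pts + center


def _resample_polyline(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline at n points equidistant in arc length."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        return np.repeat(pts[:1], n, axis=0)
    targets = np.linspace(0.0, total, n)
    x = np.interp(targets, cum, pts[:, 0])
    y = np.interp(targets, cum, pts[:, 1])
    return np.column_stack([x, y])


def _taper_radii(s_frac: np.ndarray, max_radius: float) -> np.ndarray:
    """Body half-width profile: full radius mid-body, tapering to ~0 at tips."""
    edge = 0.15
    t = np.minimum(1.0, np.minimum(s_frac / edge, (1.0 - s_frac) / edge))
    return max_radius * np.sqrt(np.clip(t, 0.0, 1.0))


def _paint_worm(
    canvas: np.ndarray,
    midline_mm: np.ndarray,
    worm: WormModel,
    pixel_size: float,
    darkness: float,
) -> np.ndarray:
    """Rasterize a capsule body along the midline onto ``canvas`` (in place).

    Edges are anti-aliased: a pixel's intensity interpolates between the
    background and the body value by its coverage, approximated from the
    signed distance of the pixel centre to the capsule edge (1 px ramp).
    This emulates optical blur at body edges; a hard-thresholded rendering
    would quantize centroid positions to the pixel grid.

    Returns the coverage-weighted centroid of the rendered body in pixel
    coordinates (x, y) -- the true image centroid an ideal detector would
    measure, recorded as the ground-truth position.
    """
    h, w = canvas.shape
    n_dense = max(40, int(4 * worm.body_length / pixel_size))
    dense = _resample_polyline(midline_mm, n_dense)
    cx = dense[:, 0] / pixel_size
    cy = dense[:, 1] / pixel_size
    s_frac = np.linspace(0.0, 1.0, n_dense)
    radii = np.maximum(
        _taper_radii(s_frac, (worm.body_width / 2) / pixel_size), 0.35
    )
    rmax = int(math.ceil(radii.max() + 1.0))
    x0 = max(int(np.floor(cx.min())) - rmax, 0)
    x1 = min(int(np.ceil(cx.max())) + rmax + 1, w)
    y0 = max(int(np.floor(cy.min())) - rmax, 0)
    y1 = min(int(np.ceil(cy.max())) + rmax + 1, h)
    if x1 <= x0 or y1 <= y0:
        return dense.mean(axis=0) / pixel_size
    off = np.arange(-rmax, rmax + 1)
    oy, ox = np.meshgrid(off, off, indexing="ij")
    px = (np.rint(cx[:, None]) + ox.ravel()[None, :]).astype(np.int64)
    py = (np.rint(cy[:, None]) + oy.ravel()[None, :]).astype(np.int64)
    signed = (
        np.hypot(px - cx[:, None], py - cy[:, None]) - radii[:, None]
    )
    keep = (px >= x0) & (px < x1) & (py >= y0) & (py < y1) & (signed < 0.5)
    lin = (py[keep] - y0) * (x1 - x0) + (px[keep] - x0)
    local = np.full((y1 - y0) * (x1 - x0), np.inf)
    np.minimum.at(local, lin, signed[keep])
    coverage = np.clip(0.5 - local, 0.0, 1.0).reshape(y1 - y0, x1 - x0)
    region = canvas[y0:y1, x0:x1]
    blend = region + (darkness - region) * coverage
    canvas[y0:y1, x0:x1] = np.minimum(region, blend)
    total = coverage.sum()
    if total == 0:
        return dense.mean(axis=0) / pixel_size
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return np.array(
        [(xx * coverage).sum() / total, (yy * coverage).sum() / total]
    )


def simulate_plate_video(
    config: PlateSimConfig,
    worms: Sequence[WormModel] | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic plate video and its exact ground truth.

    Parameters
    ----------
    config
        Acquisition parameters; ``config.n_worms`` animals are simulated.
    worms
        Per-animal models. If omitted, ``config.n_worms`` copies of the
        default :class:`WormModel` are used. If given, its length overrides
        ``config.n_worms``.

    Returns
    -------
    frames : uint8 array of shape (n_frames, rows, cols)
    truth : GroundTruth

    Raises
    ------
    ValueError
        If the arena is too small to hold the requested animals.
    """
    if worms is None:
        worms = [WormModel() for _ in range(config.n_worms)]
    worms = list(worms)
    n_worms = len(worms)
    W, H = config.arena_size
    if n_worms:
        max_len = max(wm.body_length for wm in worms)
        margin = max_len / 2
        if W <= 2 * margin or H <= 2 * margin:
            raise ValueError(
                f"arena {W}x{H} mm too small for worms of length {max_len} mm"
            )
        if n_worms * max_len**2 > 0.5 * W * H:
            raise ValueError(
                f"arena {W}x{H} mm too small for {n_worms} worms "
                f"of length {max_len} mm"
            )
    rng = np.random.Generator(np.random.PCG64(config.seed))
    n_frames = config.n_frames
    dt = 1.0 / config.frame_rate
    shape = config.shape

    # --- trajectories ---------------------------------------------------
    tap_frames = {int(round(tt * config.frame_rate)) for tt in config.tap_times}
    states = []
    for wm in worms:
        margin = wm.body_length / 2
        pos = np.array(
            [
                rng.uniform(margin, W - margin),
                rng.uniform(margin, H - margin),
            ]
        )
        heading = rng.uniform(0, 2 * math.pi)
        phase = rng.uniform(0, 2 * math.pi)
        states.append({"pos": pos, "heading": heading, "phase": phase, "arousal": 0.0})

    decay = math.exp(-dt / config.arousal_tau)

    midlines = (
        np.zeros((n_frames, n_worms, 11, 2)) if config.record_midlines else None
    )
    rows: dict[str, list] = {k: [] for k in
                             ("worm_id", "frame", "t_s", "x_mm", "y_mm",
                              "length_mm", "speed_mm_s")}
    frames = np.empty((n_frames, *shape), dtype=np.uint8)

    for f in range(n_frames):
        t = f * dt
        canvas = np.full(shape, float(config.background_level))
        for i, (wm, st) in enumerate(zip(worms, states)):
            if f in tap_frames:
                st["arousal"] = wm.arousal_multiplier - 1.0
            speed = wm.baseline_speed * (1.0 + st["arousal"])
            mid = _midline_points(st["pos"], st["heading"], st["phase"], wm)
            centroid_px = _paint_worm(
                canvas, mid, wm, config.pixel_size, config.worm_darkness
            )
            rows["worm_id"].append(i)
            rows["frame"].append(f)
            rows["t_s"].append(t)
            rows["x_mm"].append(centroid_px[0] * config.pixel_size)
            rows["y_mm"].append(centroid_px[1] * config.pixel_size)
            rows["length_mm"].append(wm.body_length)
            rows["speed_mm_s"].append(speed)
            if midlines is not None:
                midlines[f, i] = _resample_polyline(mid, 11)
            # advance state to next frame
            sigma = (1.0 - wm.heading_persistence) * 2.0 * math.sqrt(dt)
            st["heading"] += sigma * rng.standard_normal()
            step = speed * dt
            st["pos"] = st["pos"] + step * np.array(
                [math.cos(st["heading"]), math.sin(st["heading"])]
            )
            # reflecting boundary
            margin = wm.body_length / 2
            for k, hi in ((0, W), (1, H)):
                if st["pos"][k] < margin:
                    st["pos"][k] = 2 * margin - st["pos"][k]
                    st["heading"] = (math.pi - st["heading"]) if k == 0 else -st["heading"]
                elif st["pos"][k] > hi - margin:
                    st["pos"][k] = 2 * (hi - margin) - st["pos"][k]
                    st["heading"] = (math.pi - st["heading"]) if k == 0 else -st["heading"]
            wavelength = wm.body_length / 1.5
            st["phase"] -= 2 * math.pi * step / wavelength
            st["arousal"] *= decay

        if config.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, config.noise_sd, shape)
        frames[f] = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    truth = GroundTruth(table=pd.DataFrame(rows), midlines=midlines)
    return frames, truth


# ---------------------------------------------------------------------------
# Lifespan snapshot series
# ---------------------------------------------------------------------------

def simulate_lifespan_snapshots(
    n_worms: int = 8,
    n_sessions: int = 12,
    death_sessions: Sequence[float] | None = None,
    session_hours: float = 6.0,
    arena_size: tuple[float, float] = (10.24, 10.24),
    pixel_size: float = 0.04,
    background_level: float = 200.0,
    worm_darkness: float = 110.0,
    noise_sd: float = 1.0,
    move_sd_mm: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """One snapshot per session; each worm freezes at its death session.

    Alive worms jitter their position and posture between sessions (Gaussian
    displacement of SD ``move_sd_mm``); dead worms are rendered at exactly
    their final position and posture.  Deterministic pixel content (noise is
    drawn per session, identically seeded), so a dead worm's neighbourhood
    differs between sessions only by the noise.

    Returns (snapshots uint8 (n_sessions, H, W), truth DataFrame with columns
    worm_id, x_mm, y_mm, death_session).
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    W, H = arena_size
    shape = (int(round(H / pixel_size)), int(round(W / pixel_size)))
    wm = WormModel()
    if death_sessions is None:
        death_sessions = rng.uniform(2, n_sessions - 1, n_worms)
    death_sessions = np.asarray(death_sessions, dtype=float)
    margin = wm.body_length
    pos = np.column_stack(
        [rng.uniform(margin, W - margin, n_worms), rng.uniform(margin, H - margin, n_worms)]
    )
    heading = rng.uniform(0, 2 * math.pi, n_worms)
    phase = rng.uniform(0, 2 * math.pi, n_worms)
    snaps = np.empty((n_sessions, *shape), dtype=np.uint8)
    final_pos = pos.copy()
    for s in range(n_sessions):
        canvas = np.full(shape, float(background_level))
        for i in range(n_worms):
            alive = s < death_sessions[i]
            if alive and s > 0:
                pos[i] = np.clip(
                    pos[i] + rng.normal(0, move_sd_mm, 2),
                    margin,
                    [W - margin, H - margin],
                )
                heading[i] += rng.normal(0, 0.6)
                phase[i] += rng.normal(0, 1.5)
                final_pos[i] = pos[i]
            mid = _midline_points(pos[i], heading[i], phase[i], wm)
            _paint_worm(canvas, mid, wm, pixel_size, worm_darkness)
        if noise_sd > 0:
            canvas = canvas + rng.normal(0, noise_sd, shape)
        snaps[s] = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    truth = pd.DataFrame(
        {
            "worm_id": np.arange(n_worms),
            "x_mm": final_pos[:, 0],
            "y_mm": final_pos[:, 1],
            "death_session": death_sessions,
            "death_h": death_sessions * session_hours,
        }
    )
    return snaps, truth


# ---------------------------------------------------------------------------
# Cohort score tables
# ---------------------------------------------------------------------------

def default_mean_trajectory(t_days: np.ndarray | float) -> np.ndarray | float:
    """Aroused maximum speed vs age (mm/s): rises to 0.3 at day 2, then declines."""
    t = np.asarray(t_days, dtype=float)
    peak, t_peak = 0.3, 2.0
    out = peak * (t / t_peak) * np.exp(1.0 - t / t_peak)
    return out if out.shape else float(out)


@dataclass
class CohortSimConfig:
    """Variance structure of a multi-experiment plate cohort.

    Scores are built multiplicatively: mean trajectory x experiment effect x
    plate effect x mean of per-animal effects, each effect lognormal with
    unit mean and the configured CV, drawn independently per timepoint.
    Plates of the "experimental" condition have scores multiplied by
    ``day3_fold_change`` from ``day3_onset`` onward.
    """

    n_experiments: int = 10
    plates_per_condition: int = 4
    animals_per_plate: int = 50
    cv_experiment: float = 0.15
    cv_plate: float = 0.10
    cv_animal: float = 0.40
    mean_trajectory: Callable[[np.ndarray], np.ndarray] = default_mean_trajectory
    day3_fold_change: float = 1.0
    day3_onset: float = 3.0
    timepoints: np.ndarray = field(
        default_factory=lambda: np.arange(0.25, 12.0, 0.25)
    )
    include_experimental: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cv_experiment", "cv_plate", "cv_animal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_experiments < 1 or self.plates_per_condition < 1:
            raise ValueError("counts must be >= 1")
        if self.animals_per_plate < 1:
            raise ValueError("animals_per_plate must be >= 1")


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Lognormal draws with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=shape)


def simulate_cohort_scores(config: CohortSimConfig) -> ScoreMatrix:
    """Generate a plate x timepoint score table with known variance components.

    Returns a :class:`~nematrack.stats.ScoreMatrix` whose ``scores`` frame is
    indexed by plate_id with one column per timepoint (days), with experiment
    and condition labels per plate and tidy per-animal scores attached.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    t = np.asarray(config.timepoints, dtype=float)
    base = np.asarray(config.mean_trajectory(t), dtype=float)
    if np.any(base < 0):
        raise ValueError("mean_trajectory must be >= 0 everywhere")
    conditions = ["control"] + (
        ["experimental"] if config.include_experimental else []
    )
    n_t = len(t)
    plate_rows = []
    score_rows = []
    animal_frames = []
    for e in range(config.n_experiments):
        # one experiment effect per timepoint: session-level batch variation
        e_eff = _lognormal_unit_mean(rng, config.cv_experiment, n_t)
        for cond in conditions:
            for p in range(config.plates_per_condition):
                plate_id = f"e{e:02d}_{cond[:4]}_p{p:02d}"
                p_eff = _lognormal_unit_mean(rng, config.cv_plate, n_t)
                a_eff = _lognormal_unit_mean(
                    rng, config.cv_animal, (config.animals_per_plate, n_t)
                )
                animal_scores = base * e_eff * p_eff * a_eff
                if cond == "experimental" and config.day3_fold_change != 1.0:
                    animal_scores = np.where(
                        t >= config.day3_onset,
                        animal_scores * config.day3_fold_change,
                        animal_scores,
                    )
                plate_score = animal_scores.mean(axis=0)
                plate_rows.append((plate_id, f"exp{e:02d}", cond))
                score_rows.append(plate_score)
                animal_frames.append(
                    pd.DataFrame(
                        {
                            "plate_id": plate_id,
                            "t_days": np.repeat(t, config.animals_per_plate),
                            "score": animal_scores.T.ravel(),
                        }
                    )
                )
    plates = pd.DataFrame(plate_rows, columns=["plate_id", "experiment", "condition"])
    scores = pd.DataFrame(
        np.vstack(score_rows), index=plates["plate_id"], columns=t
    )
    n_animals = pd.DataFrame(
        np.full((len(plates), n_t), config.animals_per_plate),
        index=plates["plate_id"],
        columns=t,
    )
    return ScoreMatrix(
        scores=scores,
        experiment=plates.set_index("plate_id")["experiment"],
        condition=plates.set_index("plate_id")["condition"],
        n_animals=n_animals,
        animal_scores=pd.concat(animal_frames, ignore_index=True),
    )
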