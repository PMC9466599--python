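"""Shared fixtures: small simulated plates reused across test modules.

Video simulation dominates test runtime, so plates are session-scoped and
sized for a desk run: 256x256 px (10.24 mm) unless a test needs realistic
plate density.
"""

import numpy as np
import pytest

import nematrack as nt
from nematrack.segmentation import segment_video


@pytest.fixture(scope="session")
def small_plate():
    """5 default worms, 60 s, with segmentation and joined tracks."""
    cfg = nt.PlateSimConfig(n_worms=5, duration=60.0, seed=9)
    frames, truth = nt.simulate_plate_video(cfg)
    blobs = segment_video(frames, cfg.frame_rate)
    joined = nt.join_records(nt.link_frames(blobs))
    return cfg, frames, truth, blobs, joined


@pytest.fixture(scope="session")
def fast_plate():
    """5 vigorous worms (0.8 mm/s = 2 px/frame), 30 s: detection fixture."""
    worms = [nt.WormModel(baseline_speed=0.8) for _ in range(5)]
    cfg = nt.PlateSimConfig(n_worms=5, duration=30.0, seed=5)
    frames, truth = nt.simulate_plate_video(cfg, worms)
    blobs = segment_video(frames, cfg.frame_rate)
    return cfg, frames, truth, blobs


@pytest.fixture(scope="session")
def tapped_plate():
    """5 worms, 60 s, taps at 10/20/30/40 s: speed-accuracy fixture spanning
    calm and aroused locomotion."""
    cfg = nt.PlateSimConfig(
        n_worms=5, duration=60.0, seed=9, tap_times=(10.0, 20.0, 30.0, 40.0)
    )
    frames, truth = nt.simulate_plate_video(cfg)
    blobs = segment_video(frames, cfg.frame_rate)
    joined = nt.join_records(nt.link_frames(blobs))
    return cfg, truth, joined


@pytest.fixture(scope="session")
def single_worm_plate():
    """One default worm, 40 s: length-recovery fixture."""
    cfg = nt.PlateSimConfig(n_worms=1, duration=40.0, seed=3)
    frames, truth = nt.simulate_plate_video(cfg)
    blobs = segment_video(frames, cfg.frame_rate)
    return cfg, frames, truth, blobs


@pytest.fixture(scope="session")
def protocol_plates():
    """Two full 530 s tap-protocol plates with arousal multiplier 2.0."""
    from nematrack.summary import ProtocolSpec

    proto = ProtocolSpec()
    plates = []
    for seed in (1, 2):
        cfg = nt.PlateSimConfig(
            n_worms=4, duration=530.0, seed=seed, tap_times=proto.tap_times
        )
        frames, truth = nt.simulate_plate_video(cfg)
        blobs = segment_video(frames, cfg.frame_rate)
        joined = nt.join_records(nt.link_frames(blobs))
        plates.append((cfg, truth, joined))
    return plates


def match_truth_worm(record, truth_table):
    """worm_id of the ground-truth worm nearest a record's first sample."""
    f0 = int(record.frames[0])
    sub = truth_table[truth_table.frame == f0]
    d = np.linalg.norm(sub[["x_mm", "y_mm"]].values - record.xy[0], axis=1)
    return sub.iloc[int(np.argmin(d))].worm_id
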