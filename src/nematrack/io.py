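"""File formats: frames, the line-oriented blobs format, and CSV tables.

The blobs format is a simplified, plain-text stand-in for the tracker's
native output, one line per blob:

    frame t_s blob_id area cx cy n_contour x1 y1 x2 y2 ...

with a JSON sidecar recording the detection parameters.  All CSV outputs
carry units in their column names (``_mm``, ``_s``, ``_mm2``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .segmentation import BlobOutline, DetectionParams
from .tracking import TrackRecord

__all__ = [
    "read_frames",
    "write_frames_png",
    "write_frames_tiff",
    "write_blobs",
    "read_blobs",
    "write_records",
    "read_records",
    "write_ground_truth",
    "load_config_file",
    "dump_config_file",
]


def read_frames(path: str | Path) -> np.ndarray:
    """Load a video as (n_frames, H, W) uint8 from a directory of numbered
    PNGs or a multi-page TIFF."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png")) + sorted(path.glob("*.tif*"))
        if not files:
            raise FileNotFoundError(f"no frame files in {path}")
        frames = [iio.imread(f) for f in files]
        return np.stack(frames)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    raise ValueError(f"cannot read frames from {path}")


def write_frames_png(frames: np.ndarray, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out_dir / f"frame_{i:06d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def write_frames_tiff(frames: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(frames, dtype=np.uint8))
    return path


def write_blobs(
    blob_frames: list[list[BlobOutline]],
    path: str | Path,
    params: DetectionParams | None = None,
) -> Path:
    """Write per-frame blobs in the line-oriented text format (+ JSON sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        blob_id = 0
        for blobs in blob_frames:
            for b in blobs:
                coords = " ".join(
                    f"{int(x)} {int(y)}" for x, y in np.asarray(b.contour)
                )
                fh.write(
                    f"{b.frame_index} {b.t:.6g} {blob_id} {b.area} "
                    f"{b.centroid[0]:.4f} {b.centroid[1]:.4f} "
                    f"{len(b.contour)} {coords}\n"
                )
                blob_id += 1
    if params is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(dataclasses.asdict(params), indent=2))
    return path


def read_blobs(path: str | Path) -> list[list[BlobOutline]]:
    """Read the blobs text format back into per-frame lists.

    Filled-pixel sets are not stored in the format; ``pixels`` is
    reconstructed as the contour points (sufficient for linking, which uses
    centroids and areas).
    """
    frames: dict[int, list[BlobOutline]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            f = int(parts[0])
            t = float(parts[1])
            area = int(parts[3])
            cx, cy = float(parts[4]), float(parts[5])
            n = int(parts[6])
            coords = np.array(parts[7 : 7 + 2 * n], dtype=np.int64).reshape(n, 2)
            frames.setdefault(f, []).append(
                BlobOutline(
                    contour=coords,
                    centroid=(cx, cy),
                    area=area,
                    t=t,
                    frame_index=f,
                    pixels=coords,
                )
            )
    if not frames:
        return []
    n_frames = max(frames) + 1
    return [frames.get(i, []) for i in range(n_frames)]


def write_records(
    records: list[TrackRecord], path: str | Path, join_map_path: str | Path | None = None
) -> Path:
    """Track records as tidy CSV (record_id, t_s, x_mm, y_mm, area_mm2)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for r in records:
        frames.append(
            pd.DataFrame(
                {
                    "record_id": r.record_id,
                    "t_s": r.t,
                    "x_mm": r.xy[:, 0],
                    "y_mm": r.xy[:, 1],
                    "area_mm2": r.area,
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["record_id", "t_s", "x_mm", "y_mm", "area_mm2"])
    )
    df.to_csv(path, index=False)
    if join_map_path is not None:
        join_map = {str(r.record_id): r.source_ids for r in records}
        Path(join_map_path).write_text(json.dumps(join_map, indent=2))
    return path


def read_records(path: str | Path) -> list[TrackRecord]:
    df = pd.read_csv(path)
    records = []
    for rid, g in df.groupby("record_id"):
        g = g.sort_values("t_s")
        records.append(
            TrackRecord(
                record_id=int(rid),
                t=g["t_s"].to_numpy(),
                xy=g[["x_mm", "y_mm"]].to_numpy(),
                area=g["area_mm2"].to_numpy(),
                frames=np.arange(len(g)),
                outlines=[None] * len(g),
            )
        )
    records.sort(key=lambda r: (r.t_start, r.record_id))
    return records


def write_ground_truth(truth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.table.to_csv(path, index=False)
    return path


def load_config_file(path: str | Path) -> dict[str, Any]:
    """Load a JSON or YAML configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def dump_config_file(config: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=False))
    else:
        path.write_text(json.dumps(config, indent=2))
    return path
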