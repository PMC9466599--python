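"""Background-subtraction segmentation of dark worms on a bright plate.

The background is a per-pixel decaying average with an asymmetric update:
darkening pixels are accepted quickly (``alpha_dark``) while lightening ones
are absorbed slowly (``alpha_light``), which keeps slow-moving animals in
contrast as they creep into new territory.  Candidate pixels whose intensity
falls a fraction ``detect_contrast`` below the background seed a flood fill
at the laxer ``fill_contrast`` threshold (two-threshold hysteresis); each
surviving connected component yields an outer contour (Moore boundary
following, clockwise from the topmost-leftmost boundary pixel) and a
centroid.  The background is frozen in a margin around every detection so a
worm that stops moving keeps its full contrast against the stale estimate.

Coordinates are 0-based with origin at the top-left; x runs rightward along
columns and y downward along rows.  Centroids and contours are in pixel
units; conversion to mm happens downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "BackgroundModel",
    "DetectionParams",
    "BlobOutline",
    "update_background",
    "detect_blobs",
    "freeze_regions",
    "project",
    "segment_video",
    "trace_boundary",
]

_FOUR = ndimage.generate_binary_structure(2, 1)
_EIGHT = ndimage.generate_binary_structure(2, 2)


@dataclass
class BackgroundModel:
    """Decaying-average background estimate with frozen regions.

    ``alpha_dark`` > ``alpha_light`` implements the asymmetric update; pixels
    under ``frozen_mask`` are never updated until explicitly unfrozen.
    """

    estimate: np.ndarray
    alpha_dark: float = 0.08
    alpha_light: float = 0.02
    frozen_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.estimate = np.asarray(self.estimate, dtype=np.float64)
        if self.frozen_mask is None:
            self.frozen_mask = np.zeros(self.estimate.shape, dtype=bool)
        if not 0 < self.alpha_light < self.alpha_dark <= 1:
            raise ValueError("require 0 < alpha_light < alpha_dark <= 1")
        if self.frozen_mask.shape != self.estimate.shape:
            raise ValueError("frozen_mask shape mismatch")

    @classmethod
    def from_frame(
        cls, frame: np.ndarray, alpha_dark: float = 0.08, alpha_light: float = 0.02
    ) -> "BackgroundModel":
        """Initialize from the first frame, copied verbatim.

        Animals present in the first frame are burned into the estimate and
        become detectable once they move away (their new position darkens
        faster than their old one lightens); allow a burn-in of roughly one
        body length of travel before trusting detections.
        """
        return cls(
            estimate=np.array(frame, dtype=np.float64),
            alpha_dark=alpha_dark,
            alpha_light=alpha_light,
        )


@dataclass
class DetectionParams:
    """Two-threshold blob detection parameters.

    Contrasts are fractional intensity deficits relative to the local
    background estimate (robust to illumination level): a pixel seeds a
    detection when I < (1 - detect_contrast) * background and joins the fill
    when I < (1 - fill_contrast) * background.
    """

    detect_contrast: float = 0.3
    fill_contrast: float = 0.15
    min_area: int = 20
    max_area: int = 3000
    seed_connectivity: int = 4
    fill_connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.fill_contrast < self.detect_contrast < 1:
            raise ValueError("require 0 < fill_contrast < detect_contrast < 1")
        if not 0 < self.min_area < self.max_area:
            raise ValueError("require 0 < min_area < max_area")
        if self.seed_connectivity not in (4, 8) or self.fill_connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class BlobOutline:
    """One detected object in one frame.

    ``contour`` is an ordered (n, 2) array of (x, y) pixel coordinates
    tracing the outer boundary clockwise from the topmost-leftmost boundary
    pixel; first and last points are neighbours.  ``pixels`` holds the filled
    (x, y) coordinates, used for background freezing and midline extraction.
    """

    contour: np.ndarray
    centroid: tuple[float, float]
    area: int
    t: float
    frame_index: int
    pixels: np.ndarray


def update_background(bg: BackgroundModel, frame: np.ndarray) -> BackgroundModel:
    """Asymmetric decaying-average update (in place; returns ``bg``).

    Non-frozen pixels move toward the frame by ``alpha_dark`` of the residual
    where the frame is darker than the estimate and by ``alpha_light`` where
    it is lighter.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != bg.estimate.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {bg.estimate.shape}"
        )
    resid = frame - bg.estimate
    alpha = np.where(resid < 0, bg.alpha_dark, bg.alpha_light)
    free = ~bg.frozen_mask
    bg.estimate[free] += (alpha * resid)[free]
    return bg


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Outer boundary of a connected region by Moore boundary following.

    Returns an ordered (n, 2) array of (x, y) = (col, row) coordinates,
    traced clockwise in image coordinates (y down) starting from the
    topmost-leftmost boundary pixel.  A single-pixel region yields one point.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    if rows.size == 1:
        return np.array([[cols[0], rows[0]]], dtype=np.int64)
    # start: topmost, then leftmost
    order = np.lexsort((cols, rows))
    r0, c0 = int(rows[order[0]]), int(cols[order[0]])
    filled = set(zip(rows.tolist(), cols.tolist()))
    # Moore neighbourhood, clockwise starting from W:
    # W, NW, N, NE, E, SE, S, SW  (y down)
    nbrs = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
    contour = [(r0, c0)]
    # backtrack starts pointing W of the start pixel
    prev_dir = 0
    cur = (r0, c0)
    start = cur
    first_next = None
    while True:
        found = False
        # begin scan one step clockwise past the backtrack direction
        for k in range(8):
            d = (prev_dir + 1 + k) % 8
            nr, nc = cur[0] + nbrs[d][0], cur[1] + nbrs[d][1]
            if (nr, nc) in filled:
                # resume the clockwise scan just past the edge we entered by
                prev_dir = (d + 4) % 8
                cur = (nr, nc)
                found = True
                break
        if not found:  # isolated pixel cluster fallback
            break
        if first_next is None:
            first_next = cur
            contour.append(cur)
            continue
        # Jacob's stopping criterion: back at start, entering the same way
        if cur == start and contour[1] == first_next and len(contour) > 2:
            break
        contour.append(cur)
        if len(contour) > 4 * rows.size + 8:  # safety net; cannot trip on valid input
            break
    if len(contour) > 1 and contour[-1] == start:
        contour = contour[:-1]
    arr = np.array(contour, dtype=np.int64)
    return arr[:, ::-1].copy()  # (row, col) -> (x, y)


def detect_blobs(
    frame: np.ndarray,
    bg: BackgroundModel,
    params: DetectionParams,
    t: float = 0.0,
    frame_index: int = 0,
) -> list[BlobOutline]:
    """Two-threshold hysteresis detection of dark blobs.

    Seeds are pixels darker than (1 - detect_contrast) x background; fill
    components are taken at (1 - fill_contrast) with ``fill_connectivity``;
    a component survives if it contains at least one seed and its area lies
    in [min_area, max_area].
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != bg.estimate.shape:
        raise ValueError("frame/background shape mismatch")
    seeds = frame < (1.0 - params.detect_contrast) * bg.estimate
    if not seeds.any():
        return []
    fill = frame < (1.0 - params.fill_contrast) * bg.estimate
    structure = _EIGHT if params.fill_connectivity == 8 else _FOUR
    labels, n = ndimage.label(fill, structure=structure)
    if n == 0:
        return []
    seeded = np.unique(labels[seeds])
    seeded = seeded[seeded > 0]
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=seeded)
    keep = seeded[(areas >= params.min_area) & (areas <= params.max_area)]
    blobs: list[BlobOutline] = []
    if keep.size == 0:
        return blobs
    objects = ndimage.find_objects(labels)
    for lab in keep:
        sl = objects[lab - 1]
        sub = labels[sl] == lab
        rr, cc = np.nonzero(sub)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        # trace on the cropped mask and shift, to stay O(blob size)
        local = trace_boundary(sub)
        local[:, 0] += sl[1].start  # x
        local[:, 1] += sl[0].start  # y
        # intensity-weighted centroid over the component plus a 1 px ring:
        # edge pixels too faint for the fill threshold still carry part of
        # the body's intensity deficit, and weighting them in recovers
        # sub-pixel position
        r0 = max(sl[0].start - 1, 0)
        r1 = min(sl[0].stop + 1, frame.shape[0])
        c0 = max(sl[1].start - 1, 0)
        c1 = min(sl[1].stop + 1, frame.shape[1])
        ring = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        ring[rr - r0, cc - c0] = True
        ring = ndimage.binary_dilation(ring, structure=_EIGHT)
        wr, wc = np.nonzero(ring)
        wr = wr + r0
        wc = wc + c0
        wts = np.maximum(bg.estimate[wr, wc] - frame[wr, wc], 0.0)
        wsum = wts.sum()
        if wsum > 0:
            centroid = (float((wc * wts).sum() / wsum), float((wr * wts).sum() / wsum))
        else:
            centroid = (float(cc.mean()), float(rr.mean()))
        blobs.append(
            BlobOutline(
                contour=local,
                centroid=centroid,
                area=int(rr.size),
                t=t,
                frame_index=frame_index,
                pixels=np.column_stack([cc, rr]),
            )
        )
    return blobs


def freeze_regions(
    bg: BackgroundModel, blobs: list[BlobOutline], margin: int = 2
) -> BackgroundModel:
    """Freeze the background within ``margin`` pixels of every detection.

    The frozen mask is rebuilt from scratch on every call, so previously
    frozen pixels with no current blob nearby are unfrozen.
    """
    mask = np.zeros(bg.estimate.shape, dtype=bool)
    for b in blobs:
        mask[b.pixels[:, 1], b.pixels[:, 0]] = True
    if mask.any() and margin > 0:
        mask = ndimage.binary_dilation(mask, structure=_EIGHT, iterations=margin)
    bg.frozen_mask = mask
    return bg


def project(frame: np.ndarray, axis: str) -> np.ndarray:
    """Project intensities onto the horizontal or vertical axis.

    axis="horizontal": element i is the sum of row i (length = n_rows);
    axis="vertical": element i is the sum of column i (length = n_cols).
    """
    frame = np.asarray(frame)
    if axis == "horizontal":
        return frame.sum(axis=1, dtype=np.int64)
    if axis == "vertical":
        return frame.sum(axis=0, dtype=np.int64)
    raise ValueError("axis must be 'horizontal' or 'vertical'")


def segment_video(
    frames: np.ndarray,
    frame_rate: float,
    params: DetectionParams | None = None,
    alpha_dark: float = 0.08,
    alpha_light: float = 0.02,
    freeze_margin: int = 3,
) -> list[list[BlobOutline]]:
    """Run the full per-frame loop over a video.

    The background is initialized from the first frame; for each frame,
    blobs are detected against the current background, the background is
    frozen around them, and then updated with the frame.  Returns one blob
    list per frame.
    """
    if params is None:
        params = DetectionParams()
    frames = np.asarray(frames)
    bg = BackgroundModel.from_frame(
        frames[0], alpha_dark=alpha_dark, alpha_light=alpha_light
    )
    out: list[list[BlobOutline]] = []
    for f in range(frames.shape[0]):
        t = f / frame_rate
        blobs = detect_blobs(frames[f], bg, params, t=t, frame_index=f)
        freeze_regions(bg, blobs, margin=freeze_margin)
        update_background(bg, frames[f])
        out.append(blobs)
    return out
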