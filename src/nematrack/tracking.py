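"""Frame-to-frame linking, gap joining, and moving-animal counting.

Per-frame blobs are chained into track records by greedy nearest-centroid
assignment.  No attempt is made to preserve identity through collisions:
when two records claim the same blob (animals touching and merging into one
object) or one record splits into several blobs, the involved records are
terminated and fresh ones started.  A greedy joining pass then reconnects
temporally separated fragments of what is plausibly the same animal, asking
whether it could have travelled from where it was lost to where a new record
appears (distance <= v_max x gap) within a bounded gap and with a similar
body area.  Counting joined records that overlap a time window gives a far
better estimate of the number of moving animals than counting raw records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import BlobOutline

__all__ = [
    "TrackRecord",
    "LinkParams",
    "JoinParams",
    "link_frames",
    "join_records",
    "estimate_count",
]


@dataclass
class TrackRecord:
    """One temporally contiguous (or joined) chain of blob observations.

    Positions are in mm, areas in mm^2; ``source_ids`` lists the raw record
    ids merged into this one (itself only, before joining).
    """

    record_id: int
    t: np.ndarray
    xy: np.ndarray  # (n, 2) mm
    area: np.ndarray  # (n,) mm^2
    frames: np.ndarray
    outlines: list[BlobOutline | None] = field(default_factory=list)
    source_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")
        if not self.source_ids:
            self.source_ids = [self.record_id]

    @property
    def t_start(self) -> float:
        return float(self.t[0])

    @property
    def t_end(self) -> float:
        return float(self.t[-1])

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def mean_area(self) -> float:
        return float(np.mean(self.area))


@dataclass
class LinkParams:
    """Frame-to-frame assignment parameters (mm per frame interval)."""

    max_step: float = 0.5
    area_ratio_max: float = 1.8

    def __post_init__(self) -> None:
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")


@dataclass
class JoinParams:
    """Gap-joining feasibility bounds.

    v_max is the fastest plausible travel speed between loss and
    reappearance (default 1.0 mm/s, roughly twice a vigorous aroused crawl);
    max_gap bounds the unobserved interval; area_tolerance is the maximum
    fractional difference of mean areas (None disables the area check).
    """

    v_max: float = 1.0
    max_gap: float = 30.0
    area_tolerance: float | None = 0.5

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.max_gap <= 0:
            raise ValueError("v_max and max_gap must be positive")


class _Builder:
    __slots__ = ("rid", "t", "xy", "area", "frames", "outlines")

    def __init__(self, rid: int):
        self.rid = rid
        self.t: list[float] = []
        self.xy: list[tuple[float, float]] = []
        self.area: list[float] = []
        self.frames: list[int] = []
        self.outlines: list[BlobOutline] = []

    def add(self, t: float, xy: tuple[float, float], area: float, frame: int,
            outline: BlobOutline) -> None:
        self.t.append(t)
        self.xy.append(xy)
        self.area.append(area)
        self.frames.append(frame)
        self.outlines.append(outline)

    def finish(self) -> TrackRecord:
        return TrackRecord(
            record_id=self.rid,
            t=np.array(self.t),
            xy=np.array(self.xy),
            area=np.array(self.area),
            frames=np.array(self.frames, dtype=np.int64),
            outlines=self.outlines,
        )


def link_frames(
    blob_frames: list[list[BlobOutline]],
    params: LinkParams | None = None,
    pixel_size: float = 0.04,
    frame_rate: float | None = None,
) -> list[TrackRecord]:
    """Chain per-frame blobs into track records by greedy nearest-centroid.

    ``blob_frames`` is one list of blobs per frame, time-ordered (as produced
    by :func:`~nematrack.segmentation.segment_video`); blob centroids/areas
    are converted from pixels to mm with ``pixel_size``.

    Assignment per frame transition: a record may claim blobs within
    ``max_step`` of its last centroid.  A blob claimed by two or more records
    is a collision: the claimants are terminated and the blob starts a new
    record.  A record whose feasible blobs (not feasible for anyone else)
    number two or more has split: it is terminated and each blob starts a
    new record.  Remaining feasible record-blob pairs are matched greedily by
    ascending distance; a matched blob whose area jumps by more than
    ``area_ratio_max`` relative to the record's running mean also terminates
    the record.  Every blob ends up in exactly one record.
    """
    if params is None:
        params = LinkParams()
    finished: list[TrackRecord] = []
    active: list[_Builder] = []
    next_id = 0

    for f, blobs in enumerate(blob_frames):
        n_b = len(blobs)
        cent = np.array(
            [[b.centroid[0] * pixel_size, b.centroid[1] * pixel_size] for b in blobs]
        ).reshape(n_b, 2)
        t = blobs[0].t if n_b else None

        assigned_blob: dict[int, _Builder] = {}
        if active and n_b:
            last = np.array([b.xy[-1] for b in active])
            d = np.linalg.norm(last[:, None, :] - cent[None, :, :], axis=2)
            feasible = d <= params.max_step
            rec_feas = [np.nonzero(feasible[i])[0] for i in range(len(active))]
            blob_feas = [np.nonzero(feasible[:, j])[0] for j in range(n_b)]

            dead: set[int] = set()
            taken: set[int] = set()
            # collisions: a blob claimed (nearest feasible choice) by >= 2
            # records means the animals merged into one object
            claims: dict[int, list[int]] = {}
            for i in range(len(active)):
                if len(rec_feas[i]):
                    j = int(rec_feas[i][np.argmin(d[i, rec_feas[i]])])
                    claims.setdefault(j, []).append(i)
            for j, claimants in claims.items():
                if len(claimants) >= 2:
                    dead.update(claimants)
                    taken.add(j)  # merged blob starts a new record below
            # splits: a surviving record whose exclusively-feasible blobs
            # number >= 2 has broken into several objects
            for i in range(len(active)):
                if i in dead:
                    continue
                mine = [
                    j for j in rec_feas[i]
                    if j not in taken
                    and all(k in dead for k in blob_feas[j] if k != i)
                ]
                if len(mine) >= 2:
                    dead.add(i)
            # greedy 1-1 matching among the rest
            pairs = sorted(
                (d[i, j], i, j)
                for i in range(len(active))
                if i not in dead
                for j in rec_feas[i]
                if j not in taken
            )
            matched_rec: set[int] = set()
            for dist, i, j in pairs:
                if i in matched_rec or j in assigned_blob or i in dead or j in taken:
                    continue
                rec = active[i]
                mean_area = float(np.mean(rec.area))
                a = blobs[j].area * pixel_size**2
                ratio = max(a, mean_area) / max(min(a, mean_area), 1e-12)
                if ratio > params.area_ratio_max:
                    dead.add(i)  # merge/occlusion suspected: terminate
                    continue
                assigned_blob[j] = rec
                matched_rec.add(i)

            survivors = []
            for i, rec in enumerate(active):
                if i in matched_rec:
                    survivors.append(rec)
                else:
                    finished.append(rec.finish())
            active = survivors
        elif active and not n_b:
            finished.extend(rec.finish() for rec in active)
            active = []

        for j, blob in enumerate(blobs):
            a = blob.area * pixel_size**2
            xy = (cent[j, 0], cent[j, 1])
            rec = assigned_blob.get(j)
            if rec is None:
                rec = _Builder(next_id)
                next_id += 1
                active.append(rec)
            rec.add(blob.t, xy, a, f, blob)

    finished.extend(rec.finish() for rec in active)
    finished.sort(key=lambda r: (r.t_start, r.record_id))
    return finished


def _areas_compatible(a1: float, a2: float, tol: float | None) -> bool:
    if tol is None:
        return True
    m = 0.5 * (a1 + a2)
    if m == 0:
        return True
    return abs(a1 - a2) / m <= tol


def join_records(
    records: list[TrackRecord], params: JoinParams | None = None
) -> list[TrackRecord]:
    """Greedily reconnect record fragments that one animal could account for.

    Records are visited in order of start time.  A record R2 is appended to
    an earlier-ended chain R1 when 0 < t_start(R2) - t_end(R1) <= max_gap,
    the end-to-start distance is at most v_max x gap, and mean areas agree
    within area_tolerance.  Each chain accepts at most one successor at a
    time; among eligible predecessors the earliest-ending wins, ties broken
    by smaller distance.  Applying the pass twice changes nothing
    (idempotent): joined chains leave no eligible gaps behind.
    """
    if params is None:
        params = JoinParams()
    ordered = sorted(records, key=lambda r: (r.t_start, r.record_id))
    chains: list[list[TrackRecord]] = []
    for rec in ordered:
        best: tuple[float, float, int] | None = None  # (t_end, dist, chain idx)
        for ci, chain in enumerate(chains):
            tail = chain[-1]
            gap = rec.t_start - tail.t_end
            if not 0 < gap <= params.max_gap:
                continue
            dist = float(np.linalg.norm(rec.xy[0] - tail.xy[-1]))
            if dist > params.v_max * gap:
                continue
            chain_area = float(np.mean(np.concatenate([c.area for c in chain])))
            if not _areas_compatible(chain_area, rec.mean_area, params.area_tolerance):
                continue
            key = (tail.t_end, dist, ci)
            if best is None or key[:2] < best[:2]:
                best = key
        if best is None:
            chains.append([rec])
        else:
            chains[best[2]].append(rec)

    out = []
    for chain in chains:
        if len(chain) == 1:
            out.append(chain[0])
            continue
        out.append(
            TrackRecord(
                record_id=chain[0].record_id,
                t=np.concatenate([c.t for c in chain]),
                xy=np.vstack([c.xy for c in chain]),
                area=np.concatenate([c.area for c in chain]),
                frames=np.concatenate([c.frames for c in chain]),
                outlines=sum((c.outlines for c in chain), []),
                source_ids=sum((c.source_ids for c in chain), []),
            )
        )
    out.sort(key=lambda r: (r.t_start, r.record_id))
    return out


def estimate_count(records: list[TrackRecord], window: tuple[float, float]) -> int:
    """Number of (joined) records overlapping the time window (t0, t1)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must satisfy t1 > t0")
    return sum(1 for r in records if r.t_start <= t1 and r.t_end >= t0)
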