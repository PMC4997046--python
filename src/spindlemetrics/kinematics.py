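"""Chromosome congression and anaphase kinematics from 4D time-lapse.

Mirrors the live-imaging measurements of the study: 3D object centroids
are extracted per frame, linked over time, and summarised as the
chromosome offset (congression metric: 3D distance between the chromosome
mass and the spindle centre at metaphase), the anaphase A distance (3D
displacement of a chromosome mass between two time points) and the
anaphase rate (that distance divided by elapsed time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .morphometry import SegmentationResult, segment_channel
from .stack import DNA, ImageStack

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

TRACK_COLUMNS = ["t", "frame", "object_id", "channel", "z", "y", "x", "total_intensity"]


@dataclass
class CentroidTrack:
    """Labeled object centroids over time (tidy frame, μm coordinates)."""

    data: pd.DataFrame
    flagged_frames: list[int]

    def __post_init__(self) -> None:
        missing = set(TRACK_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValidationError(f"track missing columns {sorted(missing)}")
        times = self.data.drop_duplicates("frame")["t"].to_numpy()
        if np.any(np.diff(times) <= 0):
            raise ValidationError("time must be strictly increasing")
        if not np.isfinite(self.data[["z", "y", "x"]].to_numpy()).all():
            raise ValidationError("centroids must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["t"].unique())

    def centroid(self, object_id: int, t: float) -> np.ndarray:
        row = self.data[(self.data["object_id"] == object_id) & (self.data["t"] == t)]
        if row.empty:
            raise ValidationError(f"object {object_id} absent at t={t}")
        return row[["z", "y", "x"]].to_numpy()[0]


def _frame_objects(img: np.ndarray, mask: np.ndarray, voxel_size):
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    out = []
    for lab in range(1, n + 1):
        sel = labels == lab
        w = img[sel].astype(float)
        coords = np.argwhere(sel) * np.asarray(voxel_size)
        total = w.sum()
        centroid = (w / total) @ coords if total > 0 else coords.mean(axis=0)
        out.append((centroid, float(total)))
    return out


def extract_centroids(
    stack: ImageStack,
    segs: list[SegmentationResult] | None = None,
    channel: str = DNA,
    max_displacement: float | None = None,
) -> CentroidTrack:
    """Intensity-weighted object centroids per frame, linked over time.

    Objects are linked frame-to-frame by nearest-centroid assignment
    (optimal matching on the distance matrix) with a maximum displacement
    per frame; unmatched detections start new object ids.  Frames with no
    objects are flagged, not fatal.
    """
    if stack.ndim != 4:
        raise ValidationError("extract_centroids needs a 4D (t,z,y,x) stack")
    frames = list(stack.frames())
    if segs is None:
        segs = [segment_channel(f, channel) for f in frames]
    if len(segs) != len(frames):
        raise ValidationError("need one segmentation per frame")
    if max_displacement is None:
        max_displacement = float("inf")

    rows = []
    flagged = []
    prev: list[tuple[int, np.ndarray]] = []  # (object_id, centroid)
    next_id = 0
    for i, (frame, seg) in enumerate(zip(frames, segs)):
        t = i * (stack.time_step or 1.0)
        objs = _frame_objects(frame.channel(channel), seg.mask, stack.voxel_size)
        if not objs:
            flagged.append(i)
            prev = []
            continue
        ids = [-1] * len(objs)
        if prev:
            cost = np.array([[np.linalg.norm(c - pc) for _, pc in prev]
                             for c, _ in objs])
            ri, ci = linear_sum_assignment(cost)
            for r, c in zip(ri, ci):
                if cost[r, c] <= max_displacement:
                    ids[r] = prev[c][0]
        for j in range(len(objs)):
            if ids[j] == -1:
                ids[j] = next_id
                next_id += 1
        next_id = max(next_id, max(ids) + 1)
        for (centroid, total), oid in zip(objs, ids):
            rows.append((t, i, oid, channel, *centroid, total))
        prev = [(oid, c) for (c, _), oid in zip(objs, ids)]

    if not rows:
        raise ValidationError("no objects detected in any frame")
    return CentroidTrack(pd.DataFrame(rows, columns=TRACK_COLUMNS), flagged)


def chromosome_offset(chromosome_centroid, spindle_centroid) -> float:
    """Euclidean 3D distance between chromosome-mass and spindle centroids (μm)."""
    a = np.asarray(chromosome_centroid, dtype=float)
    b = np.asarray(spindle_centroid, dtype=float)
    if a.shape != (3,) or b.shape != (3,):
        raise ValidationError("centroids must be 3D points")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("centroids must be finite")
    return float(np.linalg.norm(a - b))


@dataclass
class KinematicsResult:
    """Anaphase A summary for one chromosome mass (or the cell mean)."""

    anaphase_distance: float  # μm
    anaphase_rate: float      # μm/min == distance / (t_end - t_start)
    t_start: float
    t_end: float
    object_id: int | None = None
    chromosome_offset: float | None = None

    def __post_init__(self) -> None:
        if self.anaphase_distance < 0:
            raise ValidationError("distance must be non-negative")


@dataclass
class AnaphaseMetrics:
    """Per-mass anaphase results plus the cell-level mean."""

    per_object: list[KinematicsResult]
    mean: KinematicsResult
    errors: dict[int, str]


def _inter_mass_distances(track: CentroidTrack) -> dict[float, float]:
    out = {}
    for t, grp in track.data.groupby("t"):
        if len(grp) == 2:
            pts = grp[["z", "y", "x"]].to_numpy()
            out[float(t)] = float(np.linalg.norm(pts[0] - pts[1]))
    return out


def default_anaphase_window(track: CentroidTrack,
                            onset_excess: float = 2.0) -> tuple[float, float]:
    """Pick the anaphase window from the track itself.

    ``t_start`` is the first time the inter-mass distance exceeds its
    baseline (the first two-object frame) by ``onset_excess`` μm; ``t_end``
    is the last frame.  Falls back to the full track when no onset is
    found.
    """
    dists = _inter_mass_distances(track)
    times = track.times
    if dists:
        ts = sorted(dists)
        baseline = dists[ts[0]]
        for t in ts:
            if dists[t] > baseline + onset_excess:
                return float(t), float(times[-1])
    return float(times[0]), float(times[-1])


def anaphase_metrics(
    track: CentroidTrack,
    t_start: float | None = None,
    t_end: float | None = None,
) -> AnaphaseMetrics:
    """Anaphase A distance and rate per chromosome mass, plus the cell mean.

    The distance is the 3D displacement of a mass's centroid between
    ``t_start`` and ``t_end``; the rate is that distance over elapsed
    time.  An object missing at either endpoint yields a per-object error;
    the remaining objects are still reported.
    """
    auto_start, auto_end = default_anaphase_window(track)
    if t_start is None:
        t_start = auto_start
    if t_end is None:
        t_end = auto_end
    if not t_start < t_end:
        raise ValidationError(f"need t_start < t_end, got {t_start} >= {t_end}")
    times = set(track.data["t"])
    if t_start not in times or t_end not in times:
        raise ValidationError("t_start and t_end must be sampled time points")

    results, errors = [], {}
    for oid in sorted(track.data["object_id"].unique()):
        try:
            p0 = track.centroid(oid, t_start)
            p1 = track.centroid(oid, t_end)
        except ValidationError as exc:
            errors[int(oid)] = str(exc)
            continue
        dist = float(np.linalg.norm(p1 - p0))
        results.append(KinematicsResult(
            anaphase_distance=dist,
            anaphase_rate=dist / (t_end - t_start),
            t_start=float(t_start), t_end=float(t_end), object_id=int(oid)))
    if not results:
        raise ValidationError("no object present at both window endpoints")
    mean = KinematicsResult(
        anaphase_distance=float(np.mean([r.anaphase_distance for r in results])),
        anaphase_rate=float(np.mean([r.anaphase_rate for r in results])),
        t_start=float(t_start), t_end=float(t_end))
    return AnaphaseMetrics(per_object=results, mean=mean, errors=errors)
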