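"""Directionally gated particle tracking and instantaneous velocities.

Detections from consecutive frames are linked one-to-one by minimizing total
link distance, subject to two hard admissibility gates: a maximum physical
link distance, and a maximum angular deviation of the displacement from a
preferred flow direction (default: +x, "left to right", with a ±70°
window).  The gate boundary is inclusive, so a displacement at exactly the
maximum deviation still links.  Among admissible links the assignment
maximizes the number of links and, among those, minimizes the total
distance (solved globally per frame pair with the Hungarian algorithm; a
greedy nearest-first mode is available for cross-checks).

Instantaneous velocity along a track is the Euclidean displacement in µm
divided by the elapsed time between the two detections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import CalibrationError, ValidationError


@dataclass
class TrackingParams:
    """Gates and filters for frame-to-frame linking."""

    max_link_distance: float = 10.0     # µm
    preferred_direction: float = 0.0    # degrees; 0 = +x
    max_deviation: float = 70.0         # degrees, inclusive
    allow_gap_frames: int = 0
    min_track_length: int = 2           # frames
    method: str = "lap"                 # "lap" (global optimum) or "greedy"

    def __post_init__(self) -> None:
        if not (0.0 < self.max_deviation <= 180.0):
            raise ValidationError("max_deviation must be in (0, 180]")
        if self.max_link_distance <= 0:
            raise ValidationError("max_link_distance must be > 0")
        if self.min_track_length < 1:
            raise ValidationError("min_track_length must be >= 1")
        if self.allow_gap_frames < 0:
            raise ValidationError("allow_gap_frames must be >= 0")
        if self.method not in ("lap", "greedy"):
            raise ValidationError(f"unknown linking method {self.method!r}")


@dataclass
class Track:
    """One linked trajectory: frame indices and (x, y) pixel positions."""

    track_id: int
    frames: np.ndarray      # (n,) strictly increasing ints
    points: np.ndarray      # (n, 2) px

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TrackSet:
    """All tracks from one movie, with calibration for physical velocities."""

    tracks: list[Track]
    pixel_size: float       # µm / px
    frame_interval: float   # s

    def velocities(self, track: Track) -> np.ndarray:
        return instantaneous_velocity(track, self.pixel_size, self.frame_interval)

    def mean_speeds(self) -> np.ndarray:
        """Per-track mean instantaneous speed, µm/s."""
        return np.array([
            self.velocities(t).mean() for t in self.tracks if len(t) >= 2
        ])

    def all_velocities(self) -> np.ndarray:
        vs = [self.velocities(t) for t in self.tracks if len(t) >= 2]
        return np.concatenate(vs) if vs else np.array([])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            v = self.velocities(t) if len(t) >= 2 else np.array([])
            for i, (f, (x, y)) in enumerate(zip(t.frames, t.points)):
                rows.append({
                    "track_id": t.track_id,
                    "frame": int(f),
                    "x": float(x),
                    "y": float(y),
                    "v_um_per_s": float(v[i]) if i < len(v) else np.nan,
                })
        return pd.DataFrame(
            rows, columns=["track_id", "frame", "x", "y", "v_um_per_s"]
        )


def angular_deviation(dx: float, dy: float, preferred_deg: float) -> float:
    """Absolute deviation (degrees, in [0, 180]) of a displacement from the
    preferred direction.  A zero displacement has no direction and deviates
    by 0 by convention."""
    if dx == 0 and dy == 0:
        return 0.0
    ang = math.degrees(math.atan2(dy, dx))
    diff = (ang - preferred_deg + 180.0) % 360.0 - 180.0
    return abs(diff)


def admissible(
    p: np.ndarray, q: np.ndarray, params: TrackingParams, pixel_size: float
) -> bool:
    """Both gates: physical distance and angular deviation (inclusive)."""
    d = q - p
    dist_um = math.hypot(*d) * pixel_size
    if dist_um > params.max_link_distance:
        return False
    return angular_deviation(d[0], d[1], params.preferred_direction) <= params.max_deviation


def _link_frame_pair(
    a: np.ndarray, b: np.ndarray, params: TrackingParams, pixel_size: float
) -> list[tuple[int, int]]:
    """One-to-one links between detections of two frames.

    Maximizes the number of admissible links, then minimizes their total
    physical distance.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return []
    diff = b[None, :, :] - a[:, None, :]
    dist = np.hypot(diff[..., 0], diff[..., 1]) * pixel_size
    ok = dist <= params.max_link_distance
    for i in range(n):
        for j in range(m):
            if ok[i, j] and angular_deviation(
                diff[i, j, 0], diff[i, j, 1], params.preferred_direction
            ) > params.max_deviation:
                ok[i, j] = False
    if params.method == "greedy":
        pairs = sorted(
            ((dist[i, j], i, j) for i in range(n) for j in range(m) if ok[i, j])
        )
        used_a: set[int] = set()
        used_b: set[int] = set()
        links = []
        for d, i, j in pairs:
            if i not in used_a and j not in used_b:
                links.append((i, j))
                used_a.add(i)
                used_b.add(j)
        return links
    big = (float(dist[ok].sum()) + params.max_link_distance + 1.0) * (max(n, m) + 1)
    cost = np.where(ok, dist, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if ok[i, j]]


def link(
    detections: Sequence[np.ndarray],
    params: TrackingParams,
    pixel_size: float,
    frame_interval: float,
) -> TrackSet:
    """Link per-frame centroid lists into directional tracks.

    ``detections[f]`` is an (n_f, 2) array of (x, y) pixel coordinates.
    Unmatched detections start new tracks; with ``allow_gap_frames > 0``,
    a track end may additionally be joined to a later track start across up
    to that many missing frames (gates applied to the bridging displacement,
    with the distance budget scaled by the gap).  Tracks shorter than
    ``min_track_length`` are discarded.
    """
    if pixel_size is None or pixel_size <= 0 or frame_interval is None or frame_interval <= 0:
        raise CalibrationError("pixel_size and frame_interval must be > 0")
    if len(detections) < 2:
        raise ValidationError("need at least 2 frames to link")
    dets = [np.asarray(d, dtype=float).reshape(-1, 2) for d in detections]

    tracks: list[dict] = []
    # active[det_index in current frame] -> track list index
    active = {i: t for t, i in enumerate(range(len(dets[0])))}
    tracks = [
        {"frames": [0], "points": [dets[0][i]]} for i in range(len(dets[0]))
    ]
    for f in range(len(dets) - 1):
        links = _link_frame_pair(dets[f], dets[f + 1], params, pixel_size)
        linked_next = {j: i for i, j in links}
        new_active: dict[int, int] = {}
        for j in range(len(dets[f + 1])):
            if j in linked_next:
                t = active[linked_next[j]]
                tracks[t]["frames"].append(f + 1)
                tracks[t]["points"].append(dets[f + 1][j])
            else:
                t = len(tracks)
                tracks.append({"frames": [f + 1], "points": [dets[f + 1][j]]})
            new_active[j] = t
        active = new_active

    if params.allow_gap_frames > 0:
        tracks = _close_gaps(tracks, params, pixel_size)

    out = [
        Track(track_id=k, frames=np.array(t["frames"]), points=np.array(t["points"]))
        for k, t in enumerate(
            t for t in tracks if len(t["frames"]) >= params.min_track_length
        )
    ]
    return TrackSet(tracks=out, pixel_size=pixel_size, frame_interval=frame_interval)


def _close_gaps(tracks: list[dict], params: TrackingParams, pixel_size: float) -> list[dict]:
    """Greedy end-to-start joining across up to allow_gap_frames missing frames."""
    changed = True
    while changed:
        changed = False
        candidates = []
        for ti, t in enumerate(tracks):
            for si, s in enumerate(tracks):
                if ti == si:
                    continue
                gap = s["frames"][0] - t["frames"][-1]
                if not (1 < gap <= params.allow_gap_frames + 1):
                    continue
                d = np.asarray(s["points"][0]) - np.asarray(t["points"][-1])
                dist_um = math.hypot(*d) * pixel_size
                if dist_um > params.max_link_distance * gap:
                    continue
                if angular_deviation(d[0], d[1], params.preferred_direction) > params.max_deviation:
                    continue
                candidates.append((dist_um, ti, si))
        if candidates:
            _, ti, si = min(candidates)
            tracks[ti]["frames"].extend(tracks[si]["frames"])
            tracks[ti]["points"].extend(tracks[si]["points"])
            del tracks[si]
            changed = True
    return tracks


def instantaneous_velocity(
    track: Track, pixel_size: float, frame_interval: float
) -> np.ndarray:
    """Per-step speeds: ||p[i+1] - p[i]|| * pixel_size / (dframes * dt), µm/s."""
    if pixel_size is None or pixel_size <= 0 or frame_interval is None or frame_interval <= 0:
        raise CalibrationError("pixel_size and frame_interval must be > 0")
    if len(track) < 2:
        return np.array([])
    disp = np.diff(track.points, axis=0)
    dist_um = np.hypot(disp[:, 0], disp[:, 1]) * pixel_size
    dframes = np.diff(track.frames)
    return dist_um / (dframes * frame_interval)
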