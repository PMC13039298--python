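"""Frame-to-frame spot linking (LAP) with gap closing.

Consecutive frames are linked by solving the linear assignment problem on
squared Euclidean distances, with a fixed alternative cost for leaving a spot
unlinked — the TrackMate-style frame-to-frame linker. Track ends may then be
bridged to later track starts across up to ``max_gap`` missing frames, with a
distance budget that grows linearly with the gap. Intensity never enters the
cost; it is carried through as a measurement.

The optimisation objective per frame pair is

    minimise  Σ_links d²(i, j)  +  b · (#unlinked spots),   b = max_link_distance²

over one-to-one assignments with every link shorter than ``max_link_distance``.
Because any feasible link costs at most ``b`` (< 2·b for the two unlinked
ends it replaces), the optimum links as many spots as feasibility allows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .detection import Spot


@dataclass
class Track:
    """One focus's time-ordered sub-pixel trajectory."""

    track_id: int
    frames: np.ndarray  # strictly increasing
    x: np.ndarray  # px
    y: np.ndarray  # px
    intensity: np.ndarray
    nucleus_id: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) pixel positions."""
        return np.column_stack([self.x, self.y])


@dataclass
class LinkResult:
    tracks: list[Track]
    n_spots_in: int
    n_spots_discarded: int  # spots belonging to tracks shorter than min_track_length
    n_tracks_discarded: int

    def __iter__(self):
        return iter(self.tracks)


def _solve_pair(
    prev_xy: np.ndarray, next_xy: np.ndarray, max_cost: float
) -> list[tuple[int, int]]:
    """Optimal one-to-one links between two frames; unmatched allowed at cost b."""
    n1, n2 = len(prev_xy), len(next_xy)
    if n1 == 0 or n2 == 0:
        return []
    d2 = cdist(prev_xy, next_xy, "sqeuclidean")
    b = max_cost
    big = 2 * b + 1.0  # infeasible
    # augmented square matrix: [[C, death], [birth, 0]]
    cost = np.full((n1 + n2, n1 + n2), 0.0)
    top_left = np.where(d2 <= b, d2, big)
    cost[:n1, :n2] = top_left
    cost[:n1, n2:] = big
    cost[n1:, :n2] = big
    np.fill_diagonal(cost[:n1, n2:], b)
    np.fill_diagonal(cost[n1:, :n2], b)
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n1 and c < n2 and d2[r, c] <= b
    ]


def link_tracks(
    spots: list[Spot],
    max_link_distance: float = 5.0,
    max_gap: int = 2,
    min_track_length: int = 10,
) -> LinkResult:
    """Link per-frame spots into trajectories.

    Parameters
    ----------
    max_link_distance:
        Largest allowed frame-to-frame displacement, px.
    max_gap:
        Largest number of missing frames a track may bridge; a bridge across
        ``g`` missing frames has distance budget ``max_link_distance·(g+1)``.
    min_track_length:
        Tracks with fewer records are discarded (and counted in the result).
    """
    if max_link_distance <= 0:
        raise ValueError("max_link_distance must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    n_in = len(spots)
    if n_in == 0:
        return LinkResult(tracks=[], n_spots_in=0, n_spots_discarded=0, n_tracks_discarded=0)

    by_frame: dict[int, list[Spot]] = {}
    for s in spots:
        by_frame.setdefault(s.frame, []).append(s)
    frames_present = sorted(by_frame)

    # segments: lists of spots linked frame-to-frame
    segments: list[list[Spot]] = []
    active: dict[int, int] = {}  # index into current frame's spot list -> segment index
    b = max_link_distance**2
    prev_frame: int | None = None
    for f in frames_present:
        cur = by_frame[f]
        if prev_frame is not None and f == prev_frame + 1 and active:
            prev_spots = by_frame[prev_frame]
            prev_xy = np.array([[s.x, s.y] for s in prev_spots])
            cur_xy = np.array([[s.x, s.y] for s in cur])
            links = _solve_pair(prev_xy, cur_xy, b)
        else:
            links = []
        new_active: dict[int, int] = {}
        linked_next = set()
        for i, j in links:
            seg_idx = active.get(i)
            if seg_idx is None:
                continue
            segments[seg_idx].append(cur[j])
            new_active[j] = seg_idx
            linked_next.add(j)
        for j, s in enumerate(cur):
            if j not in linked_next:
                segments.append([s])
                new_active[j] = len(segments) - 1
        active = new_active
        prev_frame = f

    if max_gap > 0 and len(segments) > 1:
        segments = _close_gaps(segments, max_link_distance, max_gap)

    tracks: list[Track] = []
    n_discarded_spots = 0
    n_discarded_tracks = 0
    tid = 0
    for seg in segments:
        if len(seg) < min_track_length:
            n_discarded_spots += len(seg)
            n_discarded_tracks += 1
            continue
        seg = sorted(seg, key=lambda s: s.frame)
        nucleus_ids = {s.nucleus_id for s in seg if s.nucleus_id is not None}
        tracks.append(
            Track(
                track_id=tid,
                frames=[s.frame for s in seg],
                x=[s.x for s in seg],
                y=[s.y for s in seg],
                intensity=[s.intensity for s in seg],
                nucleus_id=nucleus_ids.pop() if len(nucleus_ids) == 1 else None,
            )
        )
        tid += 1
    return LinkResult(
        tracks=tracks,
        n_spots_in=n_in,
        n_spots_discarded=n_discarded_spots,
        n_tracks_discarded=n_discarded_tracks,
    )


def _close_gaps(
    segments: list[list[Spot]], max_link_distance: float, max_gap: int
) -> list[list[Spot]]:
    """Bridge segment ends to later segment starts across up to max_gap frames."""
    changed = True
    while changed:
        changed = False
        ends = [(i, seg[-1]) for i, seg in enumerate(segments) if seg]
        starts = [(i, seg[0]) for i, seg in enumerate(segments) if seg]
        cand_rows = []
        for ei, (i, e) in enumerate(ends):
            for sj, (j, s) in enumerate(starts):
                if i == j:
                    continue
                gap = s.frame - e.frame - 1
                if not (1 <= gap <= max_gap):
                    continue
                budget = max_link_distance * (gap + 1)
                d2 = (e.x - s.x) ** 2 + (e.y - s.y) ** 2
                if d2 <= budget**2:
                    cand_rows.append((ei, sj, d2))
        if not cand_rows:
            break
        n_e, n_s = len(ends), len(starts)
        big = max(c for *_, c in cand_rows) * 4 + 1.0
        cost = np.full((n_e, n_s), big)
        for ei, sj, d2 in cand_rows:
            cost[ei, sj] = d2
        rows, cols = linear_sum_assignment(cost)
        merged_into: dict[int, int] = {}
        for ei, sj in zip(rows, cols):
            if cost[ei, sj] >= big:
                continue
            i, j = ends[ei][0], starts[sj][0]
            while i in merged_into:
                i = merged_into[i]
            if i == j:
                continue
            segments[i].extend(segments[j])
            segments[j] = []
            merged_into[j] = i
            changed = True
        segments = [seg for seg in segments if seg]
    return segments


def tracks_from_truth(truth, min_track_length: int = 1) -> list[Track]:
    """Convert simulator ground-truth trajectories into :class:`Track` objects."""
    tracks = []
    for tid, sub in truth.trajectories.groupby("track_id"):
        sub = sub.sort_values("frame")
        if len(sub) < min_track_length:
            continue
        nid = sub.nucleus_id.iloc[0]
        tracks.append(
            Track(
                track_id=int(tid),
                frames=sub.frame.to_numpy(),
                x=sub.x.to_numpy(),
                y=sub.y.to_numpy(),
                intensity=sub.intensity.to_numpy(),
                nucleus_id=int(nid) if nid == nid else None,
            )
        )
    return tracks


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for f, x, y, i in zip(t.frames, t.x, t.y, t.intensity):
            rows.append(
                {"track_id": t.track_id, "frame": int(f), "x_px": x, "y_px": y,
                 "intensity": i, "nucleus_id": -1 if t.nucleus_id is None else t.nucleus_id}
            )
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "x_px", "y_px", "intensity", "nucleus_id"]
    )
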