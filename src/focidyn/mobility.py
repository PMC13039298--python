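"""Trajectory statistics for DSB-focus mobility.

Implements the measurements used to characterise repair-focus dynamics:

* per-track mean square displacement, MSD(Δt) = ⟨(x(t+Δt) − x(t))² +
  (y(t+Δt) − y(t))²⟩, averaged over *all* overlapping (t, t+Δt) pairs;
* ensemble MSD with pair-count weights and the weighted SEM across curves
  (the msdanalyzer convention);
* a log-log power-law fit MSD = 4·D·Δt^α yielding the apparent diffusion
  coefficient D and the anomalous exponent α (α < 1 sub-diffusive,
  α ≈ 1 Brownian, α ≈ 2 directed);
* cumulative travelled distance Σᵢ √((Xᵢ−Xᵢ₋₁)² + (Yᵢ−Yᵢ₋₁)²) and mean
  speed along the path;
* clustering-event detection: ≥ 2 foci colocalized (pairwise distance within
  a radius) persisting for a minimum duration, 10 min by default.

Positions enter in pixels and are converted to µm through the acquisition
geometry; lags are in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from .config import AcquisitionGeometry
from .tracking import Track

DEFAULT_COLOCALIZATION_RADIUS_UM = 0.5
DEFAULT_MIN_CLUSTER_DURATION_MIN = 10.0


@dataclass
class MSDCurve:
    """MSD per lag with pair counts (weights) and weighted SEM."""

    lags: np.ndarray  # minutes; lags[0] = 0
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray
    sem: np.ndarray  # µm²

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)
        self.sem = np.asarray(self.sem, dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_min": self.lags, "msd_um2": self.msd,
             "sem_um2": self.sem, "n_pairs": self.n_pairs}
        )


@dataclass
class ClusterEvent:
    """An interval during which ≥ 2 tracks stay pairwise colocalized."""

    frame_start: int
    frame_end: int
    members: tuple[int, ...]
    mean_position: tuple[float, float]  # px

    def duration_min(self, frame_interval: float) -> float:
        return (self.frame_end - self.frame_start + 1) * frame_interval


def compute_msd(
    track: Track, geometry: AcquisitionGeometry, max_lag_fraction: float = 0.25
) -> MSDCurve:
    """Per-track MSD over all overlapping pairs, in µm² versus lag in minutes.

    For each integer lag ℓ up to ``floor(max_lag_fraction · track length)``
    (at least 1), every pair of records whose frames differ by exactly ℓ
    contributes its squared 2D displacement; frames missing because of gap
    closing simply contribute no pairs. Lag 0 is included with MSD = 0.
    """
    n = len(track)
    if n < 2:
        raise ValueError("compute_msd requires a track with >= 2 records")
    max_lag = max(int(math.floor(max_lag_fraction * n)), 1)
    frames = track.frames
    xy_um = track.positions * geometry.pixel_size
    pos_by_frame = {int(f): xy_um[i] for i, f in enumerate(frames)}

    lags = [0.0]
    msd = [0.0]
    n_pairs = [n]
    for lag in range(1, max_lag + 1):
        sq = [
            float(np.sum((pos_by_frame[f + lag] - pos_by_frame[f]) ** 2))
            for f in pos_by_frame
            if f + lag in pos_by_frame
        ]
        if not sq:
            continue
        lags.append(lag * geometry.frame_interval)
        msd.append(float(np.mean(sq)))
        n_pairs.append(len(sq))
    return MSDCurve(
        lags=np.array(lags), msd=np.array(msd),
        n_pairs=np.array(n_pairs), sem=np.zeros(len(lags)),
    )


def ensemble_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Weighted ensemble MSD over tracks, with the weighted SEM per lag.

    Per lag the mean is Σ wᵢ·msdᵢ / Σ wᵢ with wᵢ the per-curve pair count;
    the SEM is the weighted standard deviation divided by √n_eff, where
    n_eff = (Σwᵢ)² / Σwᵢ² is the effective number of curves. Curves need not
    share a lag grid; each lag present in any curve is averaged over the
    curves that have it.
    """
    if not curves:
        raise ValueError("ensemble_msd requires at least one curve")
    acc: dict[float, list[tuple[float, float]]] = {}
    for c in curves:
        for lag, m, w in zip(c.lags, c.msd, c.n_pairs):
            acc.setdefault(float(lag), []).append((float(m), float(w)))
    lags = sorted(acc)
    means, sems, totals = [], [], []
    for lag in lags:
        vals = np.array([v for v, _ in acc[lag]])
        wts = np.array([w for _, w in acc[lag]])
        wsum = wts.sum()
        mean = float((wts * vals).sum() / wsum)
        if len(vals) > 1:
            var = float((wts * (vals - mean) ** 2).sum() / wsum)
            n_eff = wsum**2 / (wts**2).sum()
            sem = math.sqrt(var / n_eff)
        else:
            sem = 0.0
        means.append(mean)
        sems.append(sem)
        totals.append(wsum)
    return MSDCurve(
        lags=np.array(lags), msd=np.array(means),
        n_pairs=np.array(totals), sem=np.array(sems),
    )


def fit_msd_powerlaw(
    curve: MSDCurve, fit_lag_range: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Fit MSD = 4·D·Δt^α by weighted least squares in log-log space.

    Returns ``(D, alpha)`` with D in µm²/minᵅ. Weights are the per-lag pair
    counts. ``fit_lag_range`` restricts the fit to lags in
    ``[lo, hi]`` minutes (inclusive); lag 0 is always excluded.
    """
    sel = curve.lags > 0
    if fit_lag_range is not None:
        lo, hi = fit_lag_range
        sel &= (curve.lags >= lo) & (curve.lags <= hi)
    lags = curve.lags[sel]
    msd = curve.msd[sel]
    w = np.asarray(curve.n_pairs, dtype=float)[sel]
    if len(lags) < 3:
        raise ValueError("fit_msd_powerlaw requires >= 3 positive lags in the window")
    if np.any(msd <= 0):
        raise ValueError("fit_msd_powerlaw requires strictly positive MSD values")
    X = np.log(lags)
    Y = np.log(msd)
    coeffs = np.polyfit(X, Y, 1, w=np.sqrt(w))
    alpha = float(coeffs[0])
    D = float(np.exp(coeffs[1]) / 4.0)
    return D, alpha


def cumulative_distance(track: Track, geometry: AcquisitionGeometry) -> float:
    """Total path length in µm: the sum of consecutive step norms."""
    if len(track) < 2:
        raise ValueError("cumulative_distance requires >= 2 records")
    steps = np.diff(track.positions * geometry.pixel_size, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def mean_velocity(track: Track, geometry: AcquisitionGeometry, net: bool = False) -> float:
    """Mean speed along the path, µm/min (cumulative distance / elapsed time).

    With ``net=True`` returns the net-displacement rate instead
    (start-to-end distance / elapsed time).
    """
    if len(track) < 2:
        raise ValueError("mean_velocity requires >= 2 records")
    span_min = (track.frames[-1] - track.frames[0]) * geometry.frame_interval
    if span_min <= 0:
        raise ValueError("track spans zero time")
    if net:
        d = float(np.hypot(*(track.positions[-1] - track.positions[0]))) * geometry.pixel_size
        return d / span_min
    return cumulative_distance(track, geometry) / span_min


def colocalization_episodes(
    tracks: list[Track],
    geometry: AcquisitionGeometry,
    colocalization_radius: float = DEFAULT_COLOCALIZATION_RADIUS_UM,
    min_duration: float = DEFAULT_MIN_CLUSTER_DURATION_MIN,
) -> list[tuple[int, int, tuple[int, int]]]:
    """Pairwise colocalization episodes ≥ ``min_duration`` long.

    For every track pair, maximal runs of consecutive frames in which both
    tracks exist and lie within ``colocalization_radius`` (µm) are found;
    runs spanning at least ``min_duration`` minutes (frames counted
    inclusively: duration = run length × frame_interval) are returned as
    ``(frame_start, frame_end, (track_a, track_b))``.
    """
    if colocalization_radius <= 0:
        raise ValueError("colocalization_radius must be > 0")
    radius_px = colocalization_radius / geometry.pixel_size
    min_frames = math.ceil(min_duration / geometry.frame_interval)
    lut = [{int(f): i for i, f in enumerate(t.frames)} for t in tracks]
    episodes: list[tuple[int, int, tuple[int, int]]] = []
    for a in range(len(tracks)):
        for b in range(a + 1, len(tracks)):
            common = sorted(set(lut[a]) & set(lut[b]))
            if len(common) < min_frames:
                continue
            run_start: int | None = None
            prev = None
            for f in common + [None]:
                close = False
                if f is not None:
                    pa = tracks[a].positions[lut[a][f]]
                    pb = tracks[b].positions[lut[b][f]]
                    close = float(np.hypot(*(pa - pb))) <= radius_px
                contiguous = prev is not None and f is not None and f == prev + 1
                if close and run_start is not None and contiguous:
                    pass  # run continues
                else:
                    if run_start is not None and prev - run_start + 1 >= min_frames:
                        episodes.append(
                            (run_start, prev, (tracks[a].track_id, tracks[b].track_id))
                        )
                    run_start = f if close else None
                prev = f
    return episodes


def detect_cluster_events(
    tracks: list[Track],
    geometry: AcquisitionGeometry,
    colocalization_radius: float = DEFAULT_COLOCALIZATION_RADIUS_UM,
    min_duration: float = DEFAULT_MIN_CLUSTER_DURATION_MIN,
) -> list[ClusterEvent]:
    """Detect clustering events: ≥ 2 foci colocalized for ≥ ``min_duration`` min.

    Built from pairwise :func:`colocalization_episodes`: each qualifying pair
    run is a candidate, and candidates that overlap in time and share a
    member are merged transitively, so a component of three mutually close
    foci reports as one event with three members. The event interval is the
    union of its episodes' intervals.
    """
    if not tracks:
        return []
    episodes = colocalization_episodes(
        tracks, geometry, colocalization_radius, min_duration
    )

    merged: list[list] = []
    changed = True
    pending = [[s, e, set(pair)] for s, e, pair in sorted(episodes)]
    while changed:
        changed = False
        merged = []
        for s, e, m in pending:
            placed = False
            for ev in merged:
                if m & ev[2] and not (e < ev[0] or s > ev[1]):
                    ev[0] = min(ev[0], s)
                    ev[1] = max(ev[1], e)
                    ev[2] |= m
                    placed = True
                    changed = True
                    break
            if not placed:
                merged.append([s, e, m])
        pending = merged

    by_id = {t.track_id: t for t in tracks}
    out = []
    for s, e, members in merged:
        pts = []
        for tid in members:
            t = by_id[tid]
            sel = (t.frames >= s) & (t.frames <= e)
            pts.append(t.positions[sel])
        allpts = np.vstack([p for p in pts if len(p)])
        out.append(
            ClusterEvent(
                frame_start=int(s), frame_end=int(e),
                members=tuple(sorted(members)),
                mean_position=(float(allpts[:, 0].mean()), float(allpts[:, 1].mean())),
            )
        )
    out.sort(key=lambda ev: (ev.frame_start, ev.frame_end, ev.members))
    return out


def foci_size_series(tracks: list[Track]) -> pd.DataFrame:
    """Long-format per-track intensity (focus size) series."""
    rows = []
    for t in tracks:
        for f, i in zip(t.frames, t.intensity):
            rows.append({"track_id": t.track_id, "frame": int(f), "intensity": float(i)})
    return pd.DataFrame(rows, columns=["track_id", "frame", "intensity"])


def per_track_summary(tracks: list[Track], geometry: AcquisitionGeometry) -> pd.DataFrame:
    """Per-track cumulative distance, mean speed and mean intensity."""
    rows = []
    for t in tracks:
        if len(t) < 2:
            continue
        rows.append(
            {
                "track_id": t.track_id,
                "n_frames": len(t),
                "cum_distance_um": cumulative_distance(t, geometry),
                "velocity_um_min": mean_velocity(t, geometry),
                "mean_intensity": float(np.mean(t.intensity)),
                "nucleus_id": -1 if t.nucleus_id is None else t.nucleus_id,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["track_id", "n_frames", "cum_distance_um", "velocity_um_min",
                 "mean_intensity", "nucleus_id"],
    )
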