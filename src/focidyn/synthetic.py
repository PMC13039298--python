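"""Synthetic time-lapse microscopy with known ground truth.

Emulates irradiated nuclei containing diffraction-limited DNA-repair foci
(γH2AX/RAD52/53BP1-like) that move sub-diffusively over a ~100-minute window,
optionally coalescing pairwise on a schedule, while the whole field drifts.
Every simulated quantity — trajectories, merge intervals, nucleus masks,
micronucleus placements — is recorded in a :class:`GroundTruth` so downstream
detection, tracking and statistics can be validated by parameter recovery.

Motion models
-------------
``stationary``
    Fixed positions (zero-motion control).
``brownian``
    Independent Gaussian increments with per-axis variance ``2·D·Δt`` so the
    2D ensemble MSD is ``4·D·Δt``.
``fbm``
    Fractional Brownian motion with anomalous exponent α, synthesised from
    the exact fractional-Gaussian-noise covariance (Cholesky factor), giving
    ensemble MSD ``4·D·Δt^α``. α < 1 is the sub-diffusive regime typical of
    chromatin loci; α = 1 reduces to Brownian motion in distribution.
``confined``
    Brownian increments radially reflected at a disk of ``confinement_radius``
    around the starting position; the MSD plateaus below ``(2·R)²``.
``directed``
    Constant drift velocity plus optional Brownian noise; pure drift has the
    ballistic MSD ``|v|²·Δt²``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .config import AcquisitionGeometry, MotionModel, SimulationConfig
from .stack import ImageStack

_PLACEMENT_ATTEMPTS = 1000
_Z_ATTENUATION = 0.6  # per-plane signal attenuation for multi-z rendering


@dataclass
class GroundTruth:
    """Everything the simulator knows; the oracle for every downstream stage.

    ``trajectories`` is a long-format table with columns
    ``nucleus_id, track_id, frame, x, y, intensity`` (positions in pixels,
    intensity in expected photons). ``merge_events`` lists coalescence
    intervals as ``(frame_start, frame_end, (track_a, track_b))``.
    """

    trajectories: pd.DataFrame
    merge_events: list[tuple[int, int, tuple[int, int]]] = field(default_factory=list)
    nucleus_masks: np.ndarray | None = None
    micronuclei: list[dict] = field(default_factory=list)

    def positions(self, track_id: int) -> np.ndarray:
        """(n, 2) array of (x, y) pixel positions of one track, frame-ordered."""
        sub = self.trajectories[self.trajectories.track_id == track_id].sort_values("frame")
        return sub[["x", "y"]].to_numpy()


def _place_points_in_disk(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    n: int,
    min_spacing: float,
) -> np.ndarray:
    """Uniform points in a disk with a minimum pairwise spacing (dart throwing)."""
    points: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(_PLACEMENT_ATTEMPTS):
            r = radius * math.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * math.pi)
            p = center + r * np.array([math.cos(theta), math.sin(theta)])
            if all(np.hypot(*(p - q)) >= min_spacing for q in points):
                points.append(p)
                break
        else:
            raise ValueError(
                f"could not place {n} foci with spacing {min_spacing:.2f} px in a "
                f"disk of radius {radius:.2f} px after {_PLACEMENT_ATTEMPTS} attempts"
            )
    return np.array(points).reshape(n, 2)


def _fgn_cholesky(n_steps: int, hurst: float) -> np.ndarray:
    """Cholesky factor of the unit-variance fractional-Gaussian-noise covariance."""
    k = np.arange(n_steps)
    d = np.abs(k[:, None] - k[None, :]).astype(float)
    h2 = 2.0 * hurst
    cov = 0.5 * ((d + 1) ** h2 - 2 * d**h2 + np.abs(d - 1) ** h2)
    # tiny jitter guards against numerically semidefinite covariances near alpha=2
    cov[np.diag_indices(n_steps)] += 1e-10
    return np.linalg.cholesky(cov)


def _simulate_displacements_um(
    motion: MotionModel, geometry: AcquisitionGeometry, n_tracks: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_tracks, n_frames, 2) displacements from start, in µm."""
    n_steps = geometry.n_frames - 1
    dt = geometry.frame_interval
    D = motion.diffusion_coefficient
    disp = np.zeros((n_tracks, geometry.n_frames, 2))

    if motion.kind == "stationary":
        return disp

    if motion.kind in ("brownian", "directed", "confined"):
        step_sd = math.sqrt(2.0 * D * dt)
        steps = rng.normal(0.0, step_sd, size=(n_tracks, n_steps, 2)) if step_sd > 0 else np.zeros(
            (n_tracks, n_steps, 2)
        )
        if motion.kind == "confined":
            R = float(motion.confinement_radius)
            pos = np.zeros((n_tracks, 2))
            for s in range(n_steps):
                pos = pos + steps[:, s]
                rad = np.hypot(pos[:, 0], pos[:, 1])
                out = rad > R
                if np.any(out):
                    # fold the radius back into [0, R] (repeated radial reflection)
                    m = np.mod(rad[out], 2 * R)
                    m = np.where(m > R, 2 * R - m, m)
                    pos[out] *= (m / rad[out])[:, None]
                disp[:, s + 1] = pos
        else:
            disp[:, 1:] = np.cumsum(steps, axis=1)
        if motion.kind == "directed":
            t = np.arange(geometry.n_frames)[:, None] * dt
            disp += (t * np.asarray(motion.drift_velocity))[None]
        return disp

    if motion.kind == "fbm":
        if math.isclose(motion.alpha, 2.0):
            # degenerate ballistic limit: perfectly correlated increments
            z = rng.normal(size=(n_tracks, 1, 2))
            steps = np.repeat(z, n_steps, axis=1)
        else:
            L = _fgn_cholesky(n_steps, hurst=motion.alpha / 2.0)
            z = rng.normal(size=(n_tracks, n_steps, 2))
            steps = np.einsum("ij,njc->nic", L, z)
        step_sd = math.sqrt(2.0 * D) * dt ** (motion.alpha / 2.0)
        disp[:, 1:] = np.cumsum(step_sd * steps, axis=1)
        return disp

    raise ValueError(f"unhandled motion kind {motion.kind!r}")


def _place_nuclei(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Place non-overlapping nucleus centres; return (centres_xy_px, label image)."""
    h, w = config.geometry.field_shape
    r_px = config.nucleus_radius / config.geometry.pixel_size
    margin = r_px + 2
    if 2 * margin >= min(h, w) and config.n_nuclei > 0:
        raise ValueError("nucleus_radius too large for field_shape")
    centers: list[np.ndarray] = []
    for _ in range(config.n_nuclei):
        for _attempt in range(_PLACEMENT_ATTEMPTS):
            c = np.array([rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)])
            if all(np.hypot(*(c - q)) >= 2 * r_px + 4 for q in centers):
                centers.append(c)
                break
        else:
            raise ValueError(
                f"could not place {config.n_nuclei} non-overlapping nuclei "
                f"after {_PLACEMENT_ATTEMPTS} attempts"
            )
    labels = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    for i, c in enumerate(centers, start=1):
        labels[(xx - c[0]) ** 2 + (yy - c[1]) ** 2 <= r_px**2] = i
    return np.array(centers).reshape(-1, 2), labels


def simulate_trajectories(config: SimulationConfig) -> GroundTruth:
    """Simulate focus trajectories for every nucleus under ``config.motion``.

    Returns one trajectory per focus, ``n_frames`` records long; tracks named
    in a scheduled merge share the leading track's positions from the merge
    frame onward. Positions are reflected at the field border so every record
    stays inside ``field_shape``. Fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    geometry = config.geometry
    h, w = geometry.field_shape
    centers, nucleus_masks = _place_nuclei(rng, config)

    n_total = config.n_nuclei * config.foci_per_nucleus
    r_px = config.nucleus_radius / geometry.pixel_size
    starts = np.zeros((n_total, 2))
    nucleus_of = np.zeros(n_total, dtype=int)
    tid = 0
    for nid in range(config.n_nuclei):
        pts = _place_points_in_disk(
            rng, centers[nid], max(r_px - config.spacing_px / 2, 1.0),
            config.foci_per_nucleus, config.spacing_px,
        )
        for p in pts:
            starts[tid] = p
            nucleus_of[tid] = nid + 1
            tid += 1

    disp_um = _simulate_displacements_um(config.motion, geometry, n_total, rng)
    pos = starts[:, None, :] + disp_um / geometry.pixel_size  # (n, T, 2), px

    merge_events: list[tuple[int, int, tuple[int, int]]] = []
    for (a, b), start in sorted(config.merge_schedule, key=lambda e: e[1]):
        if a >= n_total or b >= n_total:
            raise ValueError(f"merge_schedule names track {max(a, b)} but only {n_total} exist")
        # the slave track follows the master at a fixed sub-radius offset so the
        # pair stays colocalized yet individually detectable (0 → coincident)
        theta = rng.uniform(0, 2 * math.pi)
        offset = config.merge_offset_px * np.array([math.cos(theta), math.sin(theta)])
        pos[b, start:] = pos[a, start:] + offset
        merge_events.append((start, geometry.n_frames - 1, (a, b)))

    # reflect at the field border (rarely triggered at realistic parameters)
    for axis, size in ((0, w), (1, h)):
        p = pos[..., axis]
        p = np.abs(p)
        p = np.where(p > size - 1, 2 * (size - 1) - p, p)
        pos[..., axis] = np.clip(p, 0, size - 1)

    frames = np.tile(np.arange(geometry.n_frames), n_total)
    traj = pd.DataFrame(
        {
            "nucleus_id": np.repeat(nucleus_of, geometry.n_frames),
            "track_id": np.repeat(np.arange(n_total), geometry.n_frames),
            "frame": frames,
            "x": pos[..., 0].ravel(),
            "y": pos[..., 1].ravel(),
            "intensity": config.photon_budget,
        }
    )
    return GroundTruth(
        trajectories=traj, merge_events=merge_events, nucleus_masks=nucleus_masks
    )


def _gaussian_psf_window(x0: float, y0: float, sigma: float, total: float,
                         shape: tuple[int, int]) -> tuple[slice, slice, np.ndarray]:
    """Pixel-integrated isotropic Gaussian restricted to a ±6σ window."""
    h, w = shape
    half = int(math.ceil(6 * sigma)) + 1
    cx0, cx1 = max(int(math.floor(x0)) - half, 0), min(int(math.floor(x0)) + half + 1, w)
    cy0, cy1 = max(int(math.floor(y0)) - half, 0), min(int(math.floor(y0)) + half + 1, h)
    if cx0 >= cx1 or cy0 >= cy1:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    s = sigma * math.sqrt(2.0)
    ex = 0.5 * (
        special.erf((np.arange(cx0, cx1) + 0.5 - x0) / s)
        - special.erf((np.arange(cx0, cx1) - 0.5 - x0) / s)
    )
    ey = 0.5 * (
        special.erf((np.arange(cy0, cy1) + 0.5 - y0) / s)
        - special.erf((np.arange(cy0, cy1) - 0.5 - y0) / s)
    )
    return slice(cy0, cy1), slice(cx0, cx1), total * np.outer(ey, ex)


def render_stack(truth: GroundTruth, config: SimulationConfig, channel: str = "foci") -> ImageStack:
    """Render ground-truth trajectories into a noisy image stack.

    Each focus becomes a pixel-integrated Gaussian of width ``psf_sigma``
    carrying its expected photon budget; the whole field is translated by the
    cumulative ``drift_per_frame``; Poisson shot noise (optional via
    ``config.shot_noise``) and Gaussian read noise are then applied.
    Deterministic under ``config.seed``.
    """
    geometry = config.geometry
    h, w = geometry.field_shape
    rng = np.random.default_rng([int(config.seed), 1])
    drift = np.asarray(config.drift_per_frame, dtype=float)

    traj = truth.trajectories
    by_frame = dict(tuple(traj.groupby("frame"))) if len(traj) else {}

    expected = np.full((geometry.n_frames, h, w), float(config.background_level))
    for t in range(geometry.n_frames):
        sub = by_frame.get(t)
        if sub is None:
            continue
        dx, dy = drift * t
        for x, y, inten in zip(sub.x, sub.y, sub.intensity):
            ys, xs, win = _gaussian_psf_window(
                x + dx, y + dy, geometry.psf_sigma, float(inten), (h, w)
            )
            expected[t, ys, xs] += win

    if geometry.n_z > 1:
        atten = _Z_ATTENUATION ** np.arange(geometry.n_z)
        signal = expected - config.background_level
        expected = config.background_level + signal[:, None] * atten[None, :, None, None]

    if config.shot_noise:
        data = rng.poisson(expected).astype(float)
    else:
        data = expected.copy()
    if config.read_noise_sd > 0:
        data = data + rng.normal(0.0, config.read_noise_sd, size=data.shape)
    return ImageStack(data=np.clip(data, 0, None), channel=channel, geometry=geometry)


@dataclass
class MicronucleusField:
    """A fixed-cell DAPI/HP1α two-channel field (single 2D frame per channel)."""

    dapi: np.ndarray
    hp1a: np.ndarray
    truth: GroundTruth


def simulate_micronucleus_field(
    config: SimulationConfig,
    n_micronuclei: int = 7,
    hp1a_positive: int | list[bool] | None = None,
    micronucleus_radius_um: float = 1.0,
    dapi_level: float = 600.0,
    hp1a_level: float = 500.0,
    periphery_clearance_px: float = 6.0,
) -> MicronucleusField:
    """Simulate a fixed-cell field of main nuclei plus extranuclear micronuclei.

    Main nuclei are large DAPI disks containing bright HP1α heterochromatin
    patches; micronuclei are small DAPI disks placed outside every main
    nucleus (clearance ``periphery_clearance_px`` beyond the nuclear rim),
    each flagged HP1α-positive (heterochromatic origin) or not. The truth
    lists every micronucleus with centre, radius and flag.

    ``hp1a_positive`` may be a count (the first k micronuclei are positive),
    an explicit flag list, or None (all positive).
    """
    if config.n_nuclei < 1:
        raise ValueError("micronucleus fields require n_nuclei >= 1")
    rng = np.random.default_rng([int(config.seed), 2])
    geometry = config.geometry
    h, w = geometry.field_shape
    r_px = config.nucleus_radius / geometry.pixel_size
    mn_r = micronucleus_radius_um / geometry.pixel_size

    centers, labels = _place_nuclei(rng, config)
    yy, xx = np.mgrid[0:h, 0:w]

    if hp1a_positive is None:
        flags = [True] * n_micronuclei
    elif isinstance(hp1a_positive, int):
        flags = [i < hp1a_positive for i in range(n_micronuclei)]
    else:
        flags = list(hp1a_positive)
        if len(flags) != n_micronuclei:
            raise ValueError("hp1a_positive flag list length must equal n_micronuclei")

    dapi = np.full((h, w), float(config.background_level))
    hp1a = np.full((h, w), float(config.background_level))
    for c in centers:
        dapi[(xx - c[0]) ** 2 + (yy - c[1]) ** 2 <= r_px**2] += dapi_level
        # heterochromatin patches inside the nucleus
        for _ in range(4):
            pr = 0.18 * r_px
            rr = (r_px - pr - 1) * math.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * math.pi)
            pc = c + rr * np.array([math.cos(th), math.sin(th)])
            hp1a[(xx - pc[0]) ** 2 + (yy - pc[1]) ** 2 <= pr**2] += hp1a_level

    micronuclei: list[dict] = []
    placed: list[np.ndarray] = []
    for i in range(n_micronuclei):
        for _attempt in range(_PLACEMENT_ATTEMPTS):
            c = np.array(
                [rng.uniform(mn_r + 2, w - mn_r - 2), rng.uniform(mn_r + 2, h - mn_r - 2)]
            )
            clear_of_nuclei = all(
                np.hypot(*(c - q)) >= r_px + periphery_clearance_px + mn_r for q in centers
            )
            clear_of_mn = all(np.hypot(*(c - q)) >= 3 * mn_r for q in placed)
            if clear_of_nuclei and clear_of_mn:
                break
        else:
            raise ValueError("could not place micronuclei outside the nuclear peripheries")
        placed.append(c)
        mask = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 <= mn_r**2
        dapi[mask] += dapi_level
        if flags[i]:
            hp1a[mask] += hp1a_level
        micronuclei.append(
            {"center": (float(c[0]), float(c[1])), "radius": float(mn_r),
             "hp1a_positive": bool(flags[i])}
        )

    # soften disk edges, then apply the camera noise model
    dapi = ndimage.gaussian_filter(dapi, 1.0)
    hp1a = ndimage.gaussian_filter(hp1a, 1.0)
    out = []
    for img in (dapi, hp1a):
        noisy = rng.poisson(img).astype(float) if config.shot_noise else img.copy()
        if config.read_noise_sd > 0:
            noisy = noisy + rng.normal(0.0, config.read_noise_sd, size=noisy.shape)
        out.append(np.clip(noisy, 0, None))

    truth = GroundTruth(
        trajectories=pd.DataFrame(
            columns=["nucleus_id", "track_id", "frame", "x", "y", "intensity"]
        ),
        nucleus_masks=labels,
        micronuclei=micronuclei,
    )
    return MicronucleusField(dapi=out[0], hp1a=out[1], truth=truth)


def write_ground_truth(truth: GroundTruth, directory) -> None:
    """Write trajectories and merge events as CSV under ``directory``."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    traj = truth.trajectories.rename(columns={"x": "x_px", "y": "y_px"})
    traj.to_csv(directory / "truth_trajectories.csv", index=False)
    rows = [
        {"event_id": i, "frame_start": s, "frame_end": e, "track_ids": f"{a};{b}"}
        for i, (s, e, (a, b)) in enumerate(truth.merge_events)
    ]
    pd.DataFrame(rows, columns=["event_id", "frame_start", "frame_end", "track_ids"]).to_csv(
        directory / "truth_merge_events.csv", index=False
    )
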