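"""Configuration dataclasses for acquisition geometry, motion models and simulations.

All physical quantities carry explicit units in their field docs: lengths in
micrometres (µm) or pixels (px), times in minutes, intensities in expected
photon counts. Conversions between pixel and physical coordinates always go
through :attr:`AcquisitionGeometry.pixel_size`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

MOTION_KINDS = ("stationary", "brownian", "fbm", "confined", "directed")


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Physical calibration of a time-lapse acquisition.

    Parameters
    ----------
    pixel_size:
        Lateral sampling, µm per pixel.
    frame_interval:
        Time between consecutive frames, minutes.
    n_frames:
        Number of time points (≥ 2).
    n_z:
        Number of z planes per time point (1 for a 2D acquisition).
    field_shape:
        (height, width) of the field of view in pixels.
    psf_sigma:
        Standard deviation of the Gaussian point-spread function, pixels.
    """

    pixel_size: float = 0.11
    frame_interval: float = 2.0
    n_frames: int = 51
    n_z: int = 1
    field_shape: tuple[int, int] = (256, 256)
    psf_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        if len(self.field_shape) != 2 or min(self.field_shape) <= 0:
            raise ValueError("field_shape must be two positive integers")
        if self.psf_sigma < 0.5:
            raise ValueError("psf_sigma must be >= 0.5 px")

    @property
    def total_time(self) -> float:
        """Observation window in minutes, (n_frames - 1) * frame_interval."""
        return (self.n_frames - 1) * self.frame_interval


@dataclass(frozen=True)
class MotionModel:
    """Stochastic motion law used by the trajectory simulator.

    ``kind`` selects among: ``stationary`` (no motion), ``brownian``
    (MSD = 4·D·Δt), ``fbm`` (fractional Brownian motion, MSD = 4·D·Δt^α),
    ``confined`` (Brownian reflected at a disk of ``confinement_radius``),
    and ``directed`` (constant drift velocity plus optional Brownian noise).
    """

    kind: str = "brownian"
    diffusion_coefficient: float = 0.005  # µm²/min (µm²/min^alpha for fbm)
    alpha: float = 1.0
    confinement_radius: float | None = None  # µm
    drift_velocity: tuple[float, float] = (0.0, 0.0)  # µm/min, (vx, vy)

    def __post_init__(self) -> None:
        if self.kind not in MOTION_KINDS:
            raise ValueError(f"unknown motion kind {self.kind!r}; expected one of {MOTION_KINDS}")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be >= 0")
        if not (0 < self.alpha <= 2):
            raise ValueError("alpha must lie in (0, 2]")
        if self.kind == "confined" and (self.confinement_radius is None or self.confinement_radius <= 0):
            raise ValueError("confined motion requires confinement_radius > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic acquisition.

    ``merge_schedule`` lists pairwise coalescence events as
    ``((track_a, track_b), start_frame)``; from ``start_frame`` onward the
    second track is pinned to the first, emulating two repair foci merging
    into one repair centre. ``drift_per_frame`` is a rigid whole-field
    translation in (dx, dy) pixels per frame applied at render time.
    """

    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    n_nuclei: int = 3
    nucleus_radius: float = 5.0  # µm
    foci_per_nucleus: int = 20
    motion: MotionModel = field(default_factory=MotionModel)
    merge_schedule: tuple[tuple[tuple[int, int], int], ...] = ()
    drift_per_frame: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px/frame
    merge_offset_px: float = 4.2  # residual separation of merged foci (0 = coincident)
    photon_budget: float = 1000.0  # expected photons per focus per frame
    background_level: float = 100.0  # expected background counts per pixel
    read_noise_sd: float = 2.0  # counts
    shot_noise: bool = True
    min_spacing_px: float | None = None  # defaults to 4 * psf_sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be > 0")
        if self.foci_per_nucleus < 0:
            raise ValueError("foci_per_nucleus must be >= 0")
        if self.photon_budget < 0 or self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("intensity parameters must be >= 0")
        for (pair, start) in self.merge_schedule:
            if len(pair) != 2 or pair[0] == pair[1]:
                raise ValueError("merge_schedule pairs must name two distinct tracks")
            if not (0 <= start < self.geometry.n_frames):
                raise ValueError("merge start frames must lie within [0, n_frames)")

    @property
    def spacing_px(self) -> float:
        """Minimum initial inter-focus spacing (px); detection identifiability floor."""
        if self.min_spacing_px is not None:
            return self.min_spacing_px
        return 4.0 * self.geometry.psf_sigma


def _geometry_from_dict(d: dict) -> AcquisitionGeometry:
    d = dict(d)
    if "field_shape" in d:
        d["field_shape"] = tuple(int(v) for v in d["field_shape"])
    return AcquisitionGeometry(**d)


def _motion_from_dict(d: dict) -> MotionModel:
    d = dict(d)
    if "drift_velocity" in d:
        d["drift_velocity"] = tuple(float(v) for v in d["drift_velocity"])
    return MotionModel(**d)


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain mapping (YAML/JSON)."""
    d = dict(d)
    if "geometry" in d:
        d["geometry"] = _geometry_from_dict(d["geometry"])
    if "motion" in d:
        d["motion"] = _motion_from_dict(d["motion"])
    if "merge_schedule" in d:
        d["merge_schedule"] = tuple(
            ((int(p[0]), int(p[1])), int(s)) for p, s in d["merge_schedule"]
        )
    if "drift_per_frame" in d:
        d["drift_per_frame"] = tuple(float(v) for v in d["drift_per_frame"])
    return SimulationConfig(**d)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Read a simulation config from a YAML file whose keys mirror the dataclasses."""
    with open(path) as fh:
        return simulation_config_from_dict(yaml.safe_load(fh) or {})


def save_simulation_config(config: SimulationConfig, path: str | Path) -> None:
    d = asdict(config)
    # YAML round-trips lists, not tuples
    d["geometry"]["field_shape"] = list(config.geometry.field_shape)
    d["motion"]["drift_velocity"] = list(config.motion.drift_velocity)
    d["drift_per_frame"] = list(config.drift_per_frame)
    d["merge_schedule"] = [[list(p), s] for p, s in config.merge_schedule]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
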