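"""The in-memory image-stack container and its TIFF round trip.

An :class:`ImageStack` holds one channel of a time-lapse acquisition as a
``(frame, z, row, col)`` or ``(frame, row, col)`` float array together with
its :class:`~focidyn.config.AcquisitionGeometry`. Stacks are written as
multi-page TIFF (time-major page order) with a YAML sidecar recording the
geometry, so a stack on disk is self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .config import AcquisitionGeometry


@dataclass
class ImageStack:
    data: np.ndarray  # (T, Z, Y, X) or (T, Y, X), non-negative
    channel: str
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError("stack data must be (T, Y, X) or (T, Z, Y, X)")
        if self.data.shape[0] != self.geometry.n_frames:
            raise ValueError(
                f"stack has {self.data.shape[0]} frames but geometry declares "
                f"{self.geometry.n_frames}"
            )
        if not np.all(np.isfinite(self.data)) or self.data.min() < 0:
            raise ValueError("intensities must be finite and >= 0")

    @property
    def has_z(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame(self, t: int) -> np.ndarray:
        """Return frame ``t`` (2D only)."""
        if self.has_z:
            raise ValueError("frame() requires a z-projected stack")
        return self.data[t]


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF plus a ``.meta.yaml`` geometry sidecar."""
    path = Path(path)
    data = stack.data
    if stack.has_z:
        pages = data.reshape(-1, *data.shape[-2:])  # time-major, z within time
    else:
        pages = data
    tifffile.imwrite(path, pages.astype(np.float32), photometric="minisblack")
    meta = {
        "channel": stack.channel,
        "axes": "TZYX" if stack.has_z else "TYX",
        "geometry": {
            "pixel_size": stack.geometry.pixel_size,
            "frame_interval": stack.geometry.frame_interval,
            "n_frames": stack.geometry.n_frames,
            "n_z": stack.geometry.n_z,
            "field_shape": list(stack.geometry.field_shape),
            "psf_sigma": stack.geometry.psf_sigma,
        },
    }
    with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack` (sidecar required)."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar {sidecar} not found")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    g = meta["geometry"]
    geometry = AcquisitionGeometry(
        pixel_size=g["pixel_size"],
        frame_interval=g["frame_interval"],
        n_frames=g["n_frames"],
        n_z=g["n_z"],
        field_shape=tuple(g["field_shape"]),
        psf_sigma=g["psf_sigma"],
    )
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if meta["axes"] == "TZYX":
        data = pages.reshape(geometry.n_frames, geometry.n_z, *pages.shape[-2:])
    else:
        data = pages
    return ImageStack(data=np.asarray(data, dtype=float), channel=meta["channel"], geometry=geometry)
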