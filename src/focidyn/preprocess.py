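"""Stack preprocessing: z projection and rigid drift correction.

Mirrors the standard time-lapse pipeline: collapse each z stack to a single
plane by maximum projection, then register the t stack to a reference frame
(translation only) so whole-cell movement does not masquerade as focus
motion. Drift is estimated by phase correlation with sub-pixel refinement
and removed by bilinear interpolation.

Coordinate convention: arrays are (row=y, col=x), 0-based, pixel centres at
integer coordinates; tables state x before y, in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .stack import ImageStack


@dataclass
class DriftEstimate:
    """Per-frame rigid translation relative to a reference frame.

    ``dx[t], dy[t]`` give frame ``t``'s displacement (px) with respect to the
    reference; the reference frame's offset is (0, 0) by construction.
    ``degenerate[t]`` flags frames where estimation was impossible
    (all-constant image) and the offset was defined as zero.
    """

    dx: np.ndarray
    dy: np.ndarray
    reference: int = 0
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.dx), dtype=bool)
        if len(self.dx) != len(self.dy):
            raise ValueError("dx and dy must have equal length")
        if not (np.all(np.isfinite(self.dx)) and np.all(np.isfinite(self.dy))):
            raise ValueError("drift offsets must be finite")

    def __len__(self) -> int:
        return len(self.dx)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"frame": np.arange(len(self)), "dx_px": self.dx, "dy_px": self.dy}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DriftEstimate":
        df = pd.read_csv(path, comment="#")
        return cls(dx=df.dx_px.to_numpy(), dy=df.dy_px.to_numpy())


def max_project_z(stack: ImageStack) -> ImageStack:
    """Collapse the z axis by per-pixel maximum.

    With ``n_z = 1`` this is the identity (apart from dropping the axis).
    """
    if not stack.has_z:
        raise ValueError("max_project_z requires a stack with a z axis")
    return ImageStack(
        data=stack.data.max(axis=1), channel=stack.channel, geometry=stack.geometry
    )


def _pairwise_shift(ref: np.ndarray, frame: np.ndarray, upsample_factor: int) -> tuple[float, float]:
    """(dx, dy) displacement of ``frame`` relative to ``ref`` via phase correlation."""
    # returned shift maps `frame` onto `ref`: frame sits at -shift
    shift, _err, _phase = phase_cross_correlation(
        ref, frame, upsample_factor=upsample_factor, normalization=None
    )
    return -float(shift[1]), -float(shift[0])


def estimate_drift(
    stack: ImageStack,
    reference: int = 0,
    upsample_factor: int = 20,
    mode: str = "sequential",
) -> DriftEstimate:
    """Estimate per-frame translation relative to ``reference`` by phase correlation.

    Offsets are reported in the convention that frame ``t`` equals the
    reference translated by ``(dx[t], dy[t])``; :func:`apply_drift` negates
    them to re-align the stack. Sub-pixel precision comes from upsampled
    cross-correlation around the integer peak.

    ``mode="sequential"`` (default) correlates each frame with its
    predecessor and accumulates the shifts — robust when the imaged foci
    themselves diffuse, because adjacent frames stay nearly identical.
    ``mode="direct"`` correlates every frame with the reference.
    All-constant frames cannot be registered; they inherit the previous
    offset (sequential) or get (0, 0) (direct), with ``degenerate`` set.
    """
    if stack.has_z:
        raise ValueError("estimate_drift requires a z-projected (2D) stack")
    if mode not in ("sequential", "direct"):
        raise ValueError("mode must be 'sequential' or 'direct'")
    n = stack.n_frames
    if not (0 <= reference < n):
        raise ValueError("reference frame out of range")
    dx = np.zeros(n)
    dy = np.zeros(n)
    degenerate = np.zeros(n, dtype=bool)
    if mode == "direct":
        ref = stack.data[reference]
        ref_constant = np.ptp(ref) == 0
        for t in range(n):
            if t == reference:
                continue
            frame = stack.data[t]
            if ref_constant or np.ptp(frame) == 0:
                degenerate[t] = True
                continue
            dx[t], dy[t] = _pairwise_shift(ref, frame, upsample_factor)
    else:
        step_dx = np.zeros(n)
        step_dy = np.zeros(n)
        for t in range(1, n):
            prev, cur = stack.data[t - 1], stack.data[t]
            if np.ptp(prev) == 0 or np.ptp(cur) == 0:
                degenerate[t] = True
                continue
            step_dx[t], step_dy[t] = _pairwise_shift(prev, cur, upsample_factor)
        dx = np.cumsum(step_dx)
        dy = np.cumsum(step_dy)
        dx -= dx[reference]
        dy -= dy[reference]
    return DriftEstimate(dx=dx, dy=dy, reference=reference, degenerate=degenerate)


def apply_drift(stack: ImageStack, drift: DriftEstimate) -> ImageStack:
    """Translate each frame by the negated offset, re-aligning it to the reference.

    Bilinear interpolation; pixels shifted in from outside the field are
    filled with the frame's border median (a robust background estimate).
    Integer offsets therefore reproduce an exact integer roll on the
    interior, and zero offsets are the identity.
    """
    if stack.has_z:
        raise ValueError("apply_drift requires a z-projected (2D) stack")
    if len(drift) != stack.n_frames:
        raise ValueError(
            f"drift has {len(drift)} offsets but stack has {stack.n_frames} frames"
        )
    out = np.empty_like(stack.data)
    for t in range(stack.n_frames):
        frame = stack.data[t]
        ddx, ddy = drift.dx[t], drift.dy[t]
        if ddx == 0 and ddy == 0:
            out[t] = frame
            continue
        border = np.concatenate([frame[0], frame[-1], frame[:, 0], frame[:, -1]])
        fill = float(np.median(border))
        # ndimage.shift moves content by +shift along each axis; undoing a
        # frame displacement (dx, dy) means shifting content by (-dy, -dx)
        out[t] = ndimage.shift(
            frame, (-ddy, -ddx), order=1, mode="constant", cval=fill, prefilter=False
        )
    return ImageStack(
        data=np.clip(out, 0, None), channel=stack.channel, geometry=stack.geometry
    )
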