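"""Convenience plots: ensemble MSD with error bars and track overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .mobility import MSDCurve
from .tracking import Track


def plot_msd(curves: dict[str, MSDCurve], ax=None):
    """Ensemble MSD (µm²) versus lag (min) per condition, ± weighted SEM."""
    if ax is None:
        _fig, ax = plt.subplots()
    for label, c in curves.items():
        sel = c.lags > 0
        ax.errorbar(c.lags[sel], c.msd[sel], yerr=c.sem[sel], label=label, capsize=2)
    ax.set_xlabel("lag (min)")
    ax.set_ylabel("MSD (µm²)")
    ax.legend()
    return ax


def plot_tracks(tracks: list[Track], ax=None, background: np.ndarray | None = None):
    """Overlay trajectories (px), optionally on top of an image frame."""
    if ax is None:
        _fig, ax = plt.subplots()
    if background is not None:
        ax.imshow(background, cmap="gray")
    for t in tracks:
        ax.plot(t.x, t.y, lw=0.8)
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_aspect("equal")
    return ax
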