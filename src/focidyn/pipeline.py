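"""End-to-end orchestration: simulate, analyze, compare conditions, write tables.

One :class:`RunConfig` drives everything. ``simulate`` mode emits rendered
stacks plus ground truth; ``analyze`` runs
project → register → detect → link → mobility statistics on existing stacks;
``end_to_end`` does both and joins the analysis back to the truth for
parameter-recovery metrics. Every CSV artifact carries a provenance header
(package version, config hash, seed) as a leading ``#`` comment line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import mannwhitneyu

from . import __version__
from .config import AcquisitionGeometry, SimulationConfig, simulation_config_from_dict
from .detection import assign_spots_to_nuclei, detect_spots_stack, segment_nuclei, spots_to_dataframe
from .mobility import (
    ClusterEvent,
    MSDCurve,
    compute_msd,
    detect_cluster_events,
    ensemble_msd,
    fit_msd_powerlaw,
    per_track_summary,
)
from .preprocess import apply_drift, estimate_drift, max_project_z
from .stack import ImageStack, read_stack, write_stack
from .synthetic import render_stack, simulate_trajectories, write_ground_truth
from .tracking import link_tracks, tracks_to_dataframe

logger = logging.getLogger("focidyn")

MODES = ("simulate", "analyze", "end_to_end")


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key."""


class InputError(ValueError):
    """Missing or unreadable input."""


@dataclass(frozen=True)
class AnalysisParams:
    """Detection / linking / mobility parameters (one per pipeline stage knob)."""

    expected_sigma: float = 1.5  # px, LoG scale
    quality_threshold: float = 15.0  # LoG response floor
    max_link_distance: float = 5.0  # px
    max_gap: int = 2  # frames
    min_track_length: int = 10  # records
    max_lag_fraction: float = 0.25
    colocalization_radius: float = 0.5  # µm
    min_cluster_duration: float = 10.0  # min
    reference_frame: int = 0
    register: bool = True

    def __post_init__(self) -> None:
        if self.expected_sigma < 0.5:
            raise ConfigError("params.expected_sigma must be >= 0.5 px")
        if self.max_link_distance <= 0:
            raise ConfigError("params.max_link_distance must be > 0")
        if self.max_gap < 0:
            raise ConfigError("params.max_gap must be >= 0")
        if not (0 < self.max_lag_fraction <= 1):
            raise ConfigError("params.max_lag_fraction must lie in (0, 1]")
        if self.colocalization_radius <= 0:
            raise ConfigError("params.colocalization_radius must be > 0")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``conditions`` maps a condition label to its :class:`SimulationConfig`
    (simulate / end_to_end modes) or to a stack path (analyze mode).
    """

    mode: str = "end_to_end"
    conditions: dict = field(default_factory=dict)
    params: AnalysisParams = field(default_factory=AnalysisParams)
    out_dir: str = "focidyn_out"
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not isinstance(self.conditions, dict) or not self.conditions:
            raise ConfigError("conditions must be a non-empty mapping")


def load_run_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    """Read a RunConfig from YAML; ``overrides`` (e.g. CLI flags) take precedence."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file {path} not found")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    mode = raw.get("mode", "end_to_end")
    conditions = {}
    for label, spec in (raw.get("conditions") or {}).items():
        if mode == "analyze":
            conditions[label] = spec  # a stack path
        else:
            try:
                conditions[label] = simulation_config_from_dict(spec)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"conditions.{label}: {exc}") from exc
    try:
        params = AnalysisParams(**(raw.get("params") or {}))
    except TypeError as exc:
        raise ConfigError(f"params: {exc}") from exc
    return RunConfig(
        mode=mode,
        conditions=conditions,
        params=params,
        out_dir=raw.get("out_dir", "focidyn_out"),
        seed=raw.get("seed"),
        log_level=raw.get("log_level", "INFO"),
    )


@dataclass
class ConditionSummary:
    """Per-condition analysis products."""

    label: str
    tracks: list
    ensemble: MSDCurve | None
    fitted_D: float | None
    fitted_alpha: float | None
    per_track: pd.DataFrame
    cluster_events: list[ClusterEvent]
    n_nuclei: int
    geometry: AcquisitionGeometry

    @property
    def events_per_nucleus_per_100min(self) -> float:
        if self.n_nuclei == 0:
            return 0.0
        window = self.geometry.total_time
        scale = 100.0 / window if window > 0 else 1.0
        return len(self.cluster_events) / self.n_nuclei * scale


@dataclass
class ConditionComparison:
    """Aligned summary tables and pairwise effect sizes across conditions."""

    summary: pd.DataFrame  # one row per condition
    pairwise: pd.DataFrame  # one row per ordered condition pair × metric


def _rank_biserial(a: np.ndarray, b: np.ndarray) -> float:
    """Rank-based effect size 2·AUC − 1 in [−1, 1]; 0 means stochastic equality."""
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 0.0
    u = mannwhitneyu(a, b, alternative="two-sided").statistic
    return float(2.0 * u / (len(a) * len(b)) - 1.0)


def analyze_stack(
    stack: ImageStack, params: AnalysisParams, label: str = "condition"
) -> ConditionSummary:
    """Run the analysis half on one stack: project, register, detect, link, measure."""
    geometry = stack.geometry
    if stack.has_z:
        stack = max_project_z(stack)
    if params.register and stack.n_frames >= 2:
        drift = estimate_drift(stack, reference=params.reference_frame)
        stack = apply_drift(stack, drift)
    spots = detect_spots_stack(stack, params.expected_sigma, params.quality_threshold)

    # per-timepoint nucleus context from the (registered) first frame
    mask = segment_nuclei(stack.data[0])
    assign_spots_to_nuclei(spots, mask)

    result = link_tracks(
        spots,
        max_link_distance=params.max_link_distance,
        max_gap=params.max_gap,
        min_track_length=params.min_track_length,
    )
    tracks = result.tracks
    curves = [
        compute_msd(t, geometry, params.max_lag_fraction) for t in tracks if len(t) >= 2
    ]
    ens = ensemble_msd(curves) if curves else None
    fitted_D = fitted_alpha = None
    if ens is not None and np.count_nonzero(ens.lags > 0) >= 3 and np.all(ens.msd[ens.lags > 0] > 0):
        fitted_D, fitted_alpha = fit_msd_powerlaw(ens)
    events = detect_cluster_events(
        tracks, geometry, params.colocalization_radius, params.min_cluster_duration
    )
    return ConditionSummary(
        label=label,
        tracks=tracks,
        ensemble=ens,
        fitted_D=fitted_D,
        fitted_alpha=fitted_alpha,
        per_track=per_track_summary(tracks, geometry),
        cluster_events=events,
        n_nuclei=max(mask.n_nuclei, 1),
        geometry=geometry,
    )


def compare_conditions(summaries: dict[str, ConditionSummary]) -> ConditionComparison:
    """Aligned per-condition summary tables plus pairwise effect sizes.

    Effect sizes are descriptive only: difference of means and the
    rank-biserial correlation (2·AUC − 1) for cumulative distance and mean
    velocity; no significance interpretation is attached.
    """
    if len(summaries) < 2:
        raise ValueError("compare_conditions requires >= 2 conditions")
    labels = list(summaries)
    if len(set(labels)) != len(labels):
        raise ValueError("condition labels must be distinct")
    rows = []
    for label, s in summaries.items():
        pt = s.per_track
        # cumulative distance is only comparable across conditions for tracks
        # spanning (most of) the observation window; restrict to >= 80% span
        full = pt[pt.n_frames >= 0.8 * s.geometry.n_frames] if len(pt) else pt
        rows.append(
            {
                "condition": label,
                "n_tracks": len(s.tracks),
                "fitted_D_um2_per_min": s.fitted_D,
                "fitted_alpha": s.fitted_alpha,
                "mean_cum_distance_um": pt.cum_distance_um.mean() if len(pt) else np.nan,
                "sem_cum_distance_um": pt.cum_distance_um.sem() if len(pt) > 1 else 0.0,
                "mean_cum_distance_full_um": full.cum_distance_um.mean()
                if len(full) else np.nan,
                "mean_velocity_um_min": pt.velocity_um_min.mean() if len(pt) else np.nan,
                "sem_velocity_um_min": pt.velocity_um_min.sem() if len(pt) > 1 else 0.0,
                "cluster_events_per_nucleus_100min": s.events_per_nucleus_per_100min,
            }
        )
    pair_rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            a, b = summaries[la].per_track, summaries[lb].per_track
            for metric in ("cum_distance_um", "velocity_um_min"):
                av = a[metric].to_numpy() if len(a) else np.array([])
                bv = b[metric].to_numpy() if len(b) else np.array([])
                pair_rows.append(
                    {
                        "condition_a": la,
                        "condition_b": lb,
                        "metric": metric,
                        "mean_difference": (np.mean(av) - np.mean(bv))
                        if len(av) and len(bv) else np.nan,
                        "rank_biserial": _rank_biserial(av, bv),
                    }
                )
    return ConditionComparison(
        summary=pd.DataFrame(rows),
        pairwise=pd.DataFrame(
            pair_rows,
            columns=["condition_a", "condition_b", "metric", "mean_difference", "rank_biserial"],
        ),
    )


def _config_hash(config: RunConfig) -> str:
    payload = {
        "mode": config.mode,
        "conditions": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else str(v))
            for k, v in config.conditions.items()
        },
        "params": dataclasses.asdict(config.params),
        "seed": config.seed,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


@dataclass
class PipelineResult:
    config: RunConfig
    summaries: dict[str, ConditionSummary]
    comparison: ConditionComparison | None
    out_dir: Path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute one run per ``config.mode``; write all CSV artifacts to ``out_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    header = f"# focidyn v{__version__} config={chash} seed={config.seed}\n"

    summaries: dict[str, ConditionSummary] = {}
    for i, (label, spec) in enumerate(config.conditions.items()):
        t0 = time.monotonic()
        cdir = out_dir / label
        cdir.mkdir(parents=True, exist_ok=True)
        if config.mode == "analyze":
            stack_path = Path(spec)
            if not stack_path.exists():
                raise InputError(f"conditions.{label}: stack {stack_path} not found")
            stack = read_stack(stack_path)
            summaries[label] = analyze_stack(stack, config.params, label)
        else:
            sim: SimulationConfig = spec
            if config.seed is not None:
                sim = dataclasses.replace(sim, seed=(int(config.seed) + 7919 * i) % (2**31))
            truth = simulate_trajectories(sim)
            stack = render_stack(truth, sim)
            write_stack(stack, cdir / "foci.tiff")
            write_ground_truth(truth, cdir)
            if config.mode == "simulate":
                logger.info("condition %s: simulated in %.1fs", label, time.monotonic() - t0)
                continue
            summaries[label] = analyze_stack(stack, config.params, label)
            _write_recovery(summaries[label], truth, sim, cdir, header)
        s = summaries[label]
        if s.ensemble is not None:
            _write_csv(s.ensemble.to_dataframe(), cdir / "msd_ensemble.csv", header)
        _write_csv(s.per_track, cdir / "per_track_summary.csv", header)
        _write_csv(tracks_to_dataframe(s.tracks), cdir / "tracks.csv", header)
        _write_csv(
            pd.DataFrame(
                [
                    {
                        "event_id": k,
                        "frame_start": ev.frame_start,
                        "frame_end": ev.frame_end,
                        "duration_min": ev.duration_min(s.geometry.frame_interval),
                        "n_members": len(ev.members),
                        "track_ids": ";".join(map(str, ev.members)),
                    }
                    for k, ev in enumerate(s.cluster_events)
                ],
                columns=["event_id", "frame_start", "frame_end", "duration_min",
                         "n_members", "track_ids"],
            ),
            cdir / "cluster_events.csv",
            header,
        )
        logger.info("condition %s: analyzed in %.1fs", label, time.monotonic() - t0)

    comparison = None
    if len(summaries) >= 2:
        comparison = compare_conditions(summaries)
        _write_csv(comparison.summary, out_dir / "condition_summary.csv", header)
        _write_csv(comparison.pairwise, out_dir / "condition_pairwise.csv", header)
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(
            {"version": __version__, "config_hash": chash, "seed": config.seed,
             "mode": config.mode, "conditions": list(config.conditions)},
            fh, indent=2,
        )
    return PipelineResult(
        config=config, summaries=summaries, comparison=comparison, out_dir=out_dir
    )


def _write_recovery(
    summary: ConditionSummary, truth, sim: SimulationConfig, cdir: Path, header: str
) -> None:
    """Join detected tracks back to truth and record simple recovery metrics."""
    rows = []
    if summary.fitted_D is not None:
        rows.append({"metric": "fitted_D_um2_per_min", "value": summary.fitted_D,
                     "truth": sim.motion.diffusion_coefficient})
        rows.append({"metric": "fitted_alpha", "value": summary.fitted_alpha,
                     "truth": sim.motion.alpha})
    rows.append({"metric": "n_tracks", "value": len(summary.tracks),
                 "truth": truth.trajectories.track_id.nunique()})
    rows.append({"metric": "n_cluster_events", "value": len(summary.cluster_events),
                 "truth": len(truth.merge_events)})
    _write_csv(pd.DataFrame(rows, columns=["metric", "value", "truth"]),
               cdir / "recovery.csv", header)
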