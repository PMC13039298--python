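"""Simulator correctness: motion models, rendering, determinism, micronuclei."""

import numpy as np
import pandas as pd
import pytest

from focidyn import (
    AcquisitionGeometry,
    MotionModel,
    SimulationConfig,
    render_stack,
    simulate_micronucleus_field,
    simulate_trajectories,
    tracks_from_truth,
)
from focidyn.mobility import compute_msd, ensemble_msd, fit_msd_powerlaw


def _big_field_config(motion, seed=1, n_nuclei=10, foci=20, n_frames=51):
    return SimulationConfig(
        geometry=AcquisitionGeometry(field_shape=(2048, 2048), n_frames=n_frames),
        n_nuclei=n_nuclei,
        foci_per_nucleus=foci,
        nucleus_radius=20.0,
        motion=motion,
        seed=seed,
    )


class TestMotionModels:
    def test_stationary_positions_never_move(self):
        cfg = SimulationConfig(
            n_nuclei=2, foci_per_nucleus=5, motion=MotionModel(kind="stationary"), seed=3
        )
        truth = simulate_trajectories(cfg)
        for _tid, sub in truth.trajectories.groupby("track_id"):
            assert sub.x.nunique() == 1 and sub.y.nunique() == 1

    def test_directed_pure_drift_is_exactly_ballistic(self):
        v = (0.03, -0.02)  # µm/min
        cfg = SimulationConfig(
            n_nuclei=1,
            foci_per_nucleus=4,
            geometry=AcquisitionGeometry(field_shape=(512, 512)),
            motion=MotionModel(kind="directed", diffusion_coefficient=0.0, drift_velocity=v),
            seed=4,
        )
        g = cfg.geometry
        truth = simulate_trajectories(cfg)
        for _tid, sub in truth.trajectories.groupby("track_id"):
            sub = sub.sort_values("frame")
            t_min = sub.frame.to_numpy() * g.frame_interval
            np.testing.assert_allclose(
                sub.x.to_numpy(), sub.x.iloc[0] + v[0] * t_min / g.pixel_size, atol=1e-9
            )
            np.testing.assert_allclose(
                sub.y.to_numpy(), sub.y.iloc[0] + v[1] * t_min / g.pixel_size, atol=1e-9
            )

    def test_brownian_ensemble_msd_matches_4_d_dt(self):
        D = 0.005
        cfg = _big_field_config(MotionModel(kind="brownian", diffusion_coefficient=D))
        truth = simulate_trajectories(cfg)
        tracks = tracks_from_truth(truth)
        assert len(tracks) == 200
        ens = ensemble_msd([compute_msd(t, cfg.geometry) for t in tracks])
        D_fit, _alpha = fit_msd_powerlaw(ens)
        assert abs(D_fit - D) / D < 0.15

    def test_fbm_alpha_one_is_brownian_in_loglog_slope(self):
        cfg = _big_field_config(
            MotionModel(kind="fbm", diffusion_coefficient=0.004, alpha=1.0), seed=9
        )
        truth = simulate_trajectories(cfg)
        ens = ensemble_msd(
            [compute_msd(t, cfg.geometry) for t in tracks_from_truth(truth)]
        )
        _D, alpha = fit_msd_powerlaw(ens)
        assert abs(alpha - 1.0) <= 0.1

    def test_confined_msd_plateaus_below_diameter_squared(self):
        R = 0.4  # µm
        cfg = _big_field_config(
            MotionModel(kind="confined", diffusion_coefficient=0.01, confinement_radius=R),
            seed=5,
        )
        truth = simulate_trajectories(cfg)
        ens = ensemble_msd(
            [compute_msd(t, cfg.geometry, max_lag_fraction=0.5) for t in tracks_from_truth(truth)]
        )
        assert ens.msd.max() <= (2 * R) ** 2
        # plateau: late-lag MSD well below the unconfined 4·D·Δt line
        late = ens.msd[ens.lags >= 30]
        assert np.all(late < 4 * 0.01 * 30)

    def test_confined_positions_stay_within_radius(self):
        R = 0.3
        cfg = SimulationConfig(
            n_nuclei=1,
            foci_per_nucleus=10,
            motion=MotionModel(kind="confined", diffusion_coefficient=0.02, confinement_radius=R),
            seed=6,
        )
        truth = simulate_trajectories(cfg)
        for _tid, sub in truth.trajectories.groupby("track_id"):
            sub = sub.sort_values("frame")
            d_um = np.hypot(sub.x - sub.x.iloc[0], sub.y - sub.y.iloc[0]) * cfg.geometry.pixel_size
            assert d_um.max() <= R + 1e-9

    def test_merged_tracks_share_positions_after_merge_frame(self):
        cfg = SimulationConfig(
            n_nuclei=1,
            foci_per_nucleus=6,
            merge_schedule=(((0, 1), 10), ((2, 3), 25)),
            merge_offset_px=0.0,
            seed=8,
        )
        truth = simulate_trajectories(cfg)
        traj = truth.trajectories
        for (a, b), start in [((0, 1), 10), ((2, 3), 25)]:
            pa = traj[traj.track_id == a].sort_values("frame")
            pb = traj[traj.track_id == b].sort_values("frame")
            sel = pa.frame >= start
            np.testing.assert_array_equal(
                pa[sel][["x", "y"]].to_numpy(), pb[sel.to_numpy()][["x", "y"]].to_numpy()
            )
        assert truth.merge_events == [(10, 50, (0, 1)), (25, 50, (2, 3))]

    def test_merged_tracks_stay_within_colocalization_radius(self):
        # default merge offset keeps the pair separable but colocalized (< 0.5 µm)
        cfg = SimulationConfig(
            n_nuclei=1, foci_per_nucleus=4, merge_schedule=(((0, 1), 10),), seed=8
        )
        truth = simulate_trajectories(cfg)
        pa = truth.positions(0)[10:]
        pb = truth.positions(1)[10:]
        d_px = np.hypot(*(pa - pb).T)
        np.testing.assert_allclose(d_px, cfg.merge_offset_px, atol=1e-9)
        assert d_px.max() * cfg.geometry.pixel_size <= 0.5

    def test_rejects_invalid_motion_parameters(self):
        with pytest.raises(ValueError):
            MotionModel(kind="fbm", alpha=2.5)
        with pytest.raises(ValueError):
            MotionModel(kind="confined", confinement_radius=None)
        with pytest.raises(ValueError):
            MotionModel(kind="levy")

    def test_rejects_unplaceable_foci(self):
        cfg = SimulationConfig(
            n_nuclei=1, foci_per_nucleus=500, nucleus_radius=1.0, seed=1
        )
        with pytest.raises(ValueError, match="could not place"):
            simulate_trajectories(cfg)

    def test_start_positions_lie_inside_their_nucleus(self):
        cfg = SimulationConfig(n_nuclei=3, foci_per_nucleus=10, seed=2,
                               geometry=AcquisitionGeometry(field_shape=(512, 512)))
        truth = simulate_trajectories(cfg)
        starts = truth.trajectories[truth.trajectories.frame == 0]
        for _, row in starts.iterrows():
            assert truth.nucleus_masks[int(round(row.y)), int(round(row.x))] == row.nucleus_id


class TestDeterminism:
    def test_identical_config_gives_bit_identical_truth_and_stack(self):
        cfg = SimulationConfig(n_nuclei=1, foci_per_nucleus=8, seed=42)
        t1, t2 = simulate_trajectories(cfg), simulate_trajectories(cfg)
        pd.testing.assert_frame_equal(t1.trajectories, t2.trajectories)
        s1, s2 = render_stack(t1, cfg), render_stack(t2, cfg)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_different_seed_changes_output(self):
        cfg1 = SimulationConfig(n_nuclei=1, foci_per_nucleus=8, seed=42)
        cfg2 = SimulationConfig(n_nuclei=1, foci_per_nucleus=8, seed=43)
        t1, t2 = simulate_trajectories(cfg1), simulate_trajectories(cfg2)
        assert not np.array_equal(t1.trajectories.x.to_numpy(), t2.trajectories.x.to_numpy())


class TestRendering:
    def test_zero_signal_field_is_poisson_background(self):
        cfg = SimulationConfig(
            n_nuclei=0, foci_per_nucleus=0, photon_budget=0.0,
            background_level=100.0, read_noise_sd=0.0,
            geometry=AcquisitionGeometry(field_shape=(512, 512), n_frames=2), seed=1,
        )
        truth = simulate_trajectories(cfg)
        stack = render_stack(truth, cfg)
        assert abs(stack.data[0].mean() - 100.0) / 100.0 < 0.01
        # Poisson: variance ≈ mean
        assert abs(stack.data[0].var() - 100.0) / 100.0 < 0.05

    def test_noiseless_point_source_conserves_photons_at_argmax(self):
        cfg = SimulationConfig(
            n_nuclei=1, foci_per_nucleus=1, motion=MotionModel(kind="stationary"),
            photon_budget=500.0, background_level=0.0, read_noise_sd=0.0,
            shot_noise=False, seed=2,
        )
        truth = simulate_trajectories(cfg)
        stack = render_stack(truth, cfg)
        x0, y0 = truth.trajectories[["x", "y"]].iloc[0]
        for t in range(cfg.geometry.n_frames):
            r, c = np.unravel_index(np.argmax(stack.data[t]), stack.data[t].shape)
            assert abs(c - x0) <= 0.5 + 1e-9 and abs(r - y0) <= 0.5 + 1e-9
            assert abs(stack.data[t].sum() - 500.0) < 1e-6

    def test_drift_moves_argmax_by_cumulative_rounded_shift(self):
        cfg = SimulationConfig(
            n_nuclei=1, foci_per_nucleus=1, motion=MotionModel(kind="stationary"),
            photon_budget=500.0, background_level=0.0, read_noise_sd=0.0,
            shot_noise=False, drift_per_frame=(1.0, 0.5), seed=3,
        )
        truth = simulate_trajectories(cfg)
        stack = render_stack(truth, cfg)
        x0, y0 = truth.trajectories[["x", "y"]].iloc[0]
        for t in range(0, cfg.geometry.n_frames, 10):
            r, c = np.unravel_index(np.argmax(stack.data[t]), stack.data[t].shape)
            assert c == round(x0 + 1.0 * t)
            assert r == round(y0 + 0.5 * t)

    def test_multi_z_stack_shape_and_projection_plane(self):
        cfg = SimulationConfig(
            n_nuclei=1, foci_per_nucleus=3,
            geometry=AcquisitionGeometry(n_z=3, n_frames=5, field_shape=(128, 128)),
            shot_noise=False, read_noise_sd=0.0, seed=4,
        )
        truth = simulate_trajectories(cfg)
        stack = render_stack(truth, cfg)
        assert stack.data.shape == (5, 3, 128, 128)
        # deeper planes carry attenuated signal
        sig = stack.data - cfg.background_level
        assert sig[:, 0].sum() > sig[:, 1].sum() > sig[:, 2].sum()


class TestMicronucleusField:
    def test_zero_micronuclei_gives_empty_truth(self):
        cfg = SimulationConfig(n_nuclei=1, nucleus_radius=5.0, seed=1)
        field = simulate_micronucleus_field(cfg, n_micronuclei=0)
        assert field.truth.micronuclei == []

    def test_count_and_flag_conservation(self):
        cfg = SimulationConfig(
            n_nuclei=2, nucleus_radius=5.0,
            geometry=AcquisitionGeometry(field_shape=(400, 400)), seed=2,
        )
        field = simulate_micronucleus_field(cfg, n_micronuclei=5, hp1a_positive=5)
        assert len(field.truth.micronuclei) == 5
        assert all(m["hp1a_positive"] for m in field.truth.micronuclei)
        mixed = simulate_micronucleus_field(cfg, n_micronuclei=7, hp1a_positive=4)
        assert sum(m["hp1a_positive"] for m in mixed.truth.micronuclei) == 4

    def test_micronuclei_placed_outside_main_nuclei(self):
        cfg = SimulationConfig(
            n_nuclei=2, nucleus_radius=5.0,
            geometry=AcquisitionGeometry(field_shape=(400, 400)), seed=3,
        )
        field = simulate_micronucleus_field(cfg, n_micronuclei=6)
        for m in field.truth.micronuclei:
            x, y = m["center"]
            assert field.truth.nucleus_masks[int(round(y)), int(round(x))] == 0
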