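"""MSD, ensemble weighting, power-law fits, distances, velocity, clustering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from focidyn import (
    AcquisitionGeometry,
    MotionModel,
    MSDCurve,
    SimulationConfig,
    Track,
    compute_msd,
    cumulative_distance,
    detect_cluster_events,
    ensemble_msd,
    fit_msd_powerlaw,
    foci_size_series,
    mean_velocity,
    simulate_trajectories,
    tracks_from_truth,
)


def _track(xs, ys, frames=None, tid=0):
    xs = np.asarray(xs, dtype=float)
    frames = np.arange(len(xs)) if frames is None else np.asarray(frames)
    return Track(track_id=tid, frames=frames, x=xs, y=np.asarray(ys, dtype=float),
                 intensity=np.ones(len(xs)))


def _brute_force_msd(track, geometry, max_lag):
    """Independent double-loop oracle over all (t, t+ℓ) frame pairs."""
    pos = {int(f): np.array([x, y]) * geometry.pixel_size
           for f, x, y in zip(track.frames, track.x, track.y)}
    out = {}
    for lag in range(1, max_lag + 1):
        sq = []
        for f in sorted(pos):
            if f + lag in pos:
                d = pos[f + lag] - pos[f]
                sq.append(d[0] ** 2 + d[1] ** 2)
        if sq:
            out[lag * geometry.frame_interval] = (sum(sq) / len(sq), len(sq))
    return out


class TestComputeMSD:
    def test_stationary_track_has_zero_msd(self, unit_geometry):
        c = compute_msd(_track([5] * 8, [3] * 8), unit_geometry, max_lag_fraction=0.5)
        assert np.allclose(c.msd, 0)

    def test_ballistic_track_msd_is_lag_squared(self, unit_geometry):
        c = compute_msd(_track([0, 1, 2, 3, 4], [0] * 5), unit_geometry, max_lag_fraction=0.75)
        assert c.lags.tolist() == [0.0, 1.0, 2.0, 3.0]
        assert c.msd.tolist() == [0.0, 1.0, 4.0, 9.0]
        assert c.n_pairs.tolist() == [5, 4, 3, 2]

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        g = AcquisitionGeometry(pixel_size=0.11, frame_interval=2.0, n_frames=max(n, 2))
        track = _track(rng.uniform(0, 50, n), rng.uniform(0, 50, n))
        c = compute_msd(track, g, max_lag_fraction=1.0)
        oracle = _brute_force_msd(track, g, max_lag=n - 1)
        got = {lag: (m, p) for lag, m, p in zip(c.lags[1:], c.msd[1:], c.n_pairs[1:])}
        assert set(got) == set(oracle)
        for lag in oracle:
            assert got[lag][1] == oracle[lag][1]
            assert got[lag][0] == pytest.approx(oracle[lag][0], rel=1e-12)

    def test_gap_frames_are_excluded_from_pairs(self, unit_geometry):
        track = _track([0, 1, 3], [0, 0, 0], frames=[0, 1, 3])
        c = compute_msd(track, unit_geometry, max_lag_fraction=1.0)
        got = dict(zip(c.lags, c.n_pairs))
        assert got[1.0] == 1  # only (0,1)
        assert got[2.0] == 1  # only (1,3)
        assert got[3.0] == 1  # only (0,3)

    def test_single_record_track_rejected(self, unit_geometry):
        with pytest.raises(ValueError):
            compute_msd(_track([1], [1]), unit_geometry)


class TestEnsembleMSD:
    def test_single_curve_is_its_own_ensemble_with_zero_sem(self, unit_geometry):
        c = compute_msd(_track([0, 1, 2, 3], [0] * 4), unit_geometry, max_lag_fraction=0.6)
        e = ensemble_msd([c])
        np.testing.assert_array_equal(e.msd, c.msd)
        assert np.allclose(e.sem, 0)

    def test_identical_curves_have_zero_sem(self, unit_geometry):
        c = compute_msd(_track([0, 1, 2, 3], [0] * 4), unit_geometry, max_lag_fraction=0.6)
        e = ensemble_msd([c, c])
        np.testing.assert_array_equal(e.msd, c.msd)
        assert np.allclose(e.sem, 0)

    def test_unequal_weights_match_hand_computed_mean(self):
        curves = [
            MSDCurve(lags=[0, 2.0], msd=[0, 1.0], n_pairs=[5, 4], sem=[0, 0]),
            MSDCurve(lags=[0, 2.0], msd=[0, 2.0], n_pairs=[5, 2], sem=[0, 0]),
            MSDCurve(lags=[0, 2.0], msd=[0, 4.0], n_pairs=[5, 1], sem=[0, 0]),
        ]
        e = ensemble_msd(curves)
        # (4·1 + 2·2 + 1·4) / 7 = 12/7
        assert e.msd[e.lags == 2.0][0] == pytest.approx(12 / 7)
        assert e.n_pairs[e.lags == 2.0][0] == 7

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ensemble_msd([])


class TestPowerLawFit:
    def test_exact_brownian_curve_recovered_to_machine_precision(self):
        lags = np.array([0, 1, 2, 3, 4, 5], dtype=float)
        c = MSDCurve(lags=lags, msd=4 * 0.01 * lags, n_pairs=[9] * 6, sem=np.zeros(6))
        D, alpha = fit_msd_powerlaw(c)
        assert alpha == pytest.approx(1.0, abs=1e-12)
        assert D == pytest.approx(0.01, rel=1e-12)

    def test_exact_subdiffusive_curve_recovered(self):
        lags = np.array([0, 1, 2, 3, 4, 5], dtype=float)
        c = MSDCurve(lags=lags, msd=4 * 0.02 * lags**0.5, n_pairs=[9] * 6, sem=np.zeros(6))
        D, alpha = fit_msd_powerlaw(c)
        assert alpha == pytest.approx(0.5, abs=1e-12)
        assert D == pytest.approx(0.02, rel=1e-12)

    def test_fbm_parameter_recovery_from_simulation(self):
        cfg = SimulationConfig(
            geometry=AcquisitionGeometry(field_shape=(2048, 2048)),
            n_nuclei=10, foci_per_nucleus=20, nucleus_radius=20.0,
            motion=MotionModel(kind="fbm", diffusion_coefficient=0.005, alpha=0.6),
            seed=2,
        )
        truth = simulate_trajectories(cfg)
        tracks = tracks_from_truth(truth)
        assert len(tracks) == 200
        D, alpha = fit_msd_powerlaw(
            ensemble_msd([compute_msd(t, cfg.geometry) for t in tracks])
        )
        assert abs(alpha - 0.6) <= 0.1
        assert abs(D - 0.005) / 0.005 <= 0.25

    def test_requires_three_positive_lags(self):
        c = MSDCurve(lags=[0, 1, 2], msd=[0, 1, 2], n_pairs=[3, 2, 1], sem=[0, 0, 0])
        with pytest.raises(ValueError):
            fit_msd_powerlaw(c)


class TestDistancesAndVelocity:
    def test_stationary_track_travels_nowhere(self, unit_geometry):
        assert cumulative_distance(_track([2, 2], [3, 3]), unit_geometry) == 0.0
        assert mean_velocity(_track([2, 2], [3, 3]), unit_geometry) == 0.0

    def test_three_four_five_step(self, unit_geometry):
        assert cumulative_distance(_track([0, 3], [0, 4]), unit_geometry) == pytest.approx(5.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_brute_force_step_sum_and_velocity_identity(self, seed):
        rng = np.random.default_rng(seed)
        g = AcquisitionGeometry(pixel_size=0.11, frame_interval=2.0)
        xs, ys = rng.uniform(0, 100, 10), rng.uniform(0, 100, 10)
        track = _track(xs, ys)
        brute = sum(
            math.hypot((xs[i] - xs[i - 1]) * 0.11, (ys[i] - ys[i - 1]) * 0.11)
            for i in range(1, 10)
        )
        cum = cumulative_distance(track, g)
        assert cum == pytest.approx(brute, rel=1e-12)
        span = (track.frames[-1] - track.frames[0]) * g.frame_interval
        assert mean_velocity(track, g) * span == pytest.approx(cum, abs=1e-9)
        # path length dominates net displacement
        net = math.hypot((xs[-1] - xs[0]) * 0.11, (ys[-1] - ys[0]) * 0.11)
        assert cum >= net - 1e-12

    def test_known_speed(self):
        g = AcquisitionGeometry(pixel_size=1.0, frame_interval=10.0)
        track = _track([0, 5], [0, 0])  # 5 µm over 10 min
        assert mean_velocity(track, g) == pytest.approx(0.5)

    def test_net_velocity_flag(self, unit_geometry):
        track = _track([0, 3, 0], [0, 4, 0])
        assert mean_velocity(track, unit_geometry, net=True) == 0.0
        assert mean_velocity(track, unit_geometry) == pytest.approx(10.0 / 2.0)


class TestClusterEvents:
    def _geometry(self):
        return AcquisitionGeometry(pixel_size=0.11, frame_interval=2.0, n_frames=20)

    def _pair(self, n_close, apart_px=20.0):
        """Two tracks colocalized (distance 0) for the last n_close frames."""
        n = 20
        x1 = np.full(n, 50.0)
        x2 = np.full(n, 50.0 + apart_px)
        x2[n - n_close:] = 50.0
        return [
            _track(x1, [50.0] * n, tid=0),
            _track(x2, [50.0] * n, tid=1),
        ]

    def test_twelve_minute_colocalization_is_one_event(self):
        g = self._geometry()
        events = detect_cluster_events(self._pair(6), g, 0.5, 10.0)  # 6 × 2 min = 12 min
        assert len(events) == 1
        assert events[0].members == (0, 1)
        assert events[0].duration_min(g.frame_interval) >= 10.0

    def test_eight_minute_colocalization_is_no_event(self):
        events = detect_cluster_events(self._pair(4), self._geometry(), 0.5, 10.0)
        assert events == []

    def test_radius_monotonicity_never_loses_colocalized_pairs(self):
        # growing the radius can merge events, but the set of track pairs
        # participating in any event can only grow
        g = self._geometry()
        rng = np.random.default_rng(3)
        tracks = [
            _track(rng.uniform(0, 40, 20), rng.uniform(0, 40, 20), tid=i) for i in range(8)
        ]
        prev_pairs: set = set()
        for r in (0.2, 0.5, 1.0, 2.0, 4.0):
            events = detect_cluster_events(tracks, g, r, 10.0)
            pairs = set()
            from focidyn.mobility import colocalization_episodes

            for s, e, pair in colocalization_episodes(tracks, g, r, 10.0):
                pairs.add(frozenset(pair))
            covered = set()
            for ev in events:
                for p in pairs:
                    if p <= set(ev.members):
                        covered.add(p)
            assert prev_pairs <= pairs
            assert pairs == covered  # every qualifying pair is inside some event
            prev_pairs = pairs

    def test_scheduled_merges_recovered_across_seeds(self):
        hits, total_true, matched_events, total_events = 0, 0, 0, 0
        for seed in range(20):
            g = AcquisitionGeometry(field_shape=(512, 512))
            merges = tuple((((2 * k), (2 * k + 1)), 10 + k) for k in range(5))
            cfg = SimulationConfig(
                geometry=g, n_nuclei=1, foci_per_nucleus=30, nucleus_radius=12.0,
                motion=MotionModel(kind="brownian", diffusion_coefficient=0.001),
                merge_schedule=merges, min_spacing_px=3 * 0.5 / 0.11, seed=seed,
            )
            truth = simulate_trajectories(cfg)
            events = detect_cluster_events(tracks_from_truth(truth), g, 0.5, 10.0)
            true_pairs = {frozenset(p) for (_s, _e, p) in truth.merge_events}
            matched = set()
            for ev in events:
                ok = False
                for pair in true_pairs:
                    if pair <= set(ev.members):
                        matched.add(pair)
                        ok = True
                matched_events += ok
            hits += len(matched)
            total_true += len(true_pairs)
            total_events += len(events)
        assert hits / total_true >= 0.9
        assert matched_events / total_events >= 0.9


class TestFociSizeSeries:
    def test_constant_intensity_track_is_flat(self):
        out = foci_size_series([_track([1, 2, 3], [1, 1, 1])])
        assert out.intensity.nunique() == 1

    def test_empty_track_list_gives_empty_table(self):
        out = foci_size_series([])
        assert len(out) == 0
        assert list(out.columns) == ["track_id", "frame", "intensity"]

    def test_merged_foci_intensity_is_additive_after_rendering(self):
        from focidyn import detect_spots
        from focidyn.synthetic import render_stack

        cfg = SimulationConfig(
            n_nuclei=1, foci_per_nucleus=2, nucleus_radius=5.0,
            geometry=AcquisitionGeometry(field_shape=(128, 128), n_frames=10),
            motion=MotionModel(kind="stationary"),
            merge_schedule=(((0, 1), 5),), merge_offset_px=0.0,
            photon_budget=1000.0, background_level=0.0, read_noise_sd=0.0,
            shot_noise=False, min_spacing_px=20.0, seed=9,
        )
        truth = simulate_trajectories(cfg)
        stack = render_stack(truth, cfg)
        pre = detect_spots(stack.data[0], 1.5, 1.0)
        post = detect_spots(stack.data[9], 1.5, 1.0)
        assert len(pre) == 2 and len(post) == 1
        assert post[0].intensity == pytest.approx(sum(s.intensity for s in pre), rel=0.15)
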