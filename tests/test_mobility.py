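"""MSD and radius-of-confinement mathematics."""
import numpy as np
import pytest

from dsbmotion import (
    PairedTracks,
    SimulationConfig,
    analyze_condition,
    compute_msd,
    correct_coordinates,
    ensemble_msd,
    radius_of_confinement,
    relative_track_from_arrays,
    simulate_confined_track,
)
from conftest import uniform_ball, uniform_disk


def _paired(focus, fiducial, frames=None):
    focus = np.asarray(focus, dtype=float)
    frames = np.arange(len(focus)) if frames is None else np.asarray(frames)
    return PairedTracks(cell_id="c", frames=frames, focus=focus, fiducial=np.asarray(fiducial, float))


def brute_force_msd(frames, coords, dims=2):
    """Independent all-pairs oracle: average over every observed (i, i+k)."""
    out = {}
    n = len(frames)
    for i in range(n):
        for j in range(i + 1, n):
            k = frames[j] - frames[i]
            d = coords[j, :dims] - coords[i, :dims]
            out.setdefault(k, []).append(float(d @ d))
    return {k: np.mean(v) for k, v in sorted(out.items())}


class TestCorrectCoordinates:
    def test_focus_equals_fiducial_gives_zero_track(self):
        pos = np.random.default_rng(0).normal(size=(10, 3)) + 10
        rel = correct_coordinates(_paired(pos, pos), 160.0, 300.0)
        assert np.allclose(rel.xyz, 0.0, atol=1e-12)

    def test_shared_offset_cancels(self, rng):
        foc = rng.normal(size=(20, 3)) + 10
        fid = rng.normal(size=(20, 3)) + 12
        offset = np.array([3.7, -1.2, 0.5])
        a = correct_coordinates(_paired(foc, fid), 160.0, 300.0)
        b = correct_coordinates(_paired(foc + offset, fid + offset), 160.0, 300.0)
        assert np.allclose(a.xyz, b.xyz, atol=1e-12)

    def test_pixel_to_micrometre_conversion(self):
        foc = np.array([[10.0, -10.0, 0.0], [0.0, 0.0, 0.0]])
        fid = np.zeros((2, 3))
        rel = correct_coordinates(_paired(foc, fid), 106.7, 300.0)
        # before centering the difference is (1.067, -1.067, 0) um; centering
        # over the two frames halves the spread symmetrically
        span = rel.xyz[0] - rel.xyz[1]
        assert np.allclose(span[:2], [1.067, -1.067], atol=1e-12)

    def test_mean_centred(self, rng):
        rel = correct_coordinates(
            _paired(rng.normal(size=(15, 3)) + 8, rng.normal(size=(15, 3)) + 5), 160.0, 300.0
        )
        assert np.allclose(rel.xyz.mean(axis=0), 0.0, atol=1e-12)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            correct_coordinates(_paired([[1, 1, 1]], [[0, 0, 0]], frames=[0]), 160.0, 300.0)


class TestComputeMSD:
    def test_stationary_track_zero_msd(self):
        tr = relative_track_from_arrays(np.ones((10, 3)), np.zeros((10, 3)))
        curve = compute_msd(tr)
        assert np.allclose(curve.msd_um2, 0.0)

    def test_linear_1d_track_quadratic_msd(self):
        """Positions 0,1,2,3: MSD(k) = k^2 averaged over all pairs."""
        pos = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        tr = relative_track_from_arrays(pos, np.zeros_like(pos), frame_interval_s=1.0)
        curve = compute_msd(tr, dims=2)
        assert np.allclose(curve.lags_s, [1.0, 2.0, 3.0])
        assert np.allclose(curve.msd_um2, [1.0, 4.0, 9.0])
        assert np.array_equal(curve.n_pairs, [3, 2, 1])

    def test_matches_brute_force_oracle_on_random_tracks(self, rng):
        """Vectorized implementation == double-loop oracle to 1e-12, gaps included."""
        for _ in range(100):
            n = rng.integers(5, 50)
            frames = np.sort(rng.choice(np.arange(2 * n), size=n, replace=False))
            coords = rng.normal(size=(n, 3))
            tr = relative_track_from_arrays(coords, np.zeros_like(coords), frames=frames)
            curve = compute_msd(tr, dims=2)
            oracle = brute_force_msd(frames, tr.xyz, dims=2)
            lags_frames = (curve.lags_s / 30.0).round().astype(int)
            assert set(lags_frames) == set(oracle)
            for k, msd in zip(lags_frames, curve.msd_um2):
                assert msd == pytest.approx(oracle[k], abs=1e-12)

    def test_non_overlapping_mode(self):
        pos = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        tr = relative_track_from_arrays(pos, np.zeros_like(pos), frame_interval_s=1.0)
        curve = compute_msd(tr, dims=2, overlapping=False)
        # lag 2: pairs (0,2),(2,4) only
        assert curve.n_pairs[1] == 2

    def test_excessive_lag_truncated_with_warning(self):
        pos = np.random.default_rng(1).normal(size=(6, 3))
        tr = relative_track_from_arrays(pos, np.zeros_like(pos))
        with pytest.warns(UserWarning, match="truncated"):
            curve = compute_msd(tr, max_lag_frames=50)
        assert len(curve.lags_s) == 5


class TestEnsembleMSD:
    def _curve(self, msd):
        pos = np.zeros((len(msd) + 1, 3))
        tr = relative_track_from_arrays(pos, np.zeros_like(pos))
        c = compute_msd(tr)
        c.msd_um2 = np.asarray(msd, dtype=float)
        return c

    def test_single_cell_mean_is_curve_sem_zero(self):
        c = self._curve([1.0, 2.0, 3.0])
        ens = ensemble_msd([c])
        assert np.allclose(ens.mean_msd_um2, c.msd_um2)
        assert np.allclose(ens.sem_um2, 0.0)

    def test_identical_cells_sem_zero(self):
        ens = ensemble_msd([self._curve([1.0, 2.0]), self._curve([1.0, 2.0])])
        assert np.allclose(ens.sem_um2, 0.0)
        assert np.array_equal(ens.n_cells, [2, 2])

    def test_free_diffusion_matches_4_d_dt(self):
        """2D MSD of free Brownian cells ~ 4*D*lag within 3 SEM."""
        D, dt = 2e-3, 30.0
        curves = []
        for seed in range(10):
            cfg = SimulationConfig(
                confinement_radius=1e6, diffusion_coeff=D, frame_interval=dt, seed=seed
            )
            track = simulate_confined_track(cfg, n_frames=200)
            tr = relative_track_from_arrays(track, np.zeros_like(track), frame_interval_s=dt)
            curves.append(compute_msd(tr, max_lag_frames=5, dims=2))
        ens = ensemble_msd(curves)
        for lag, mean, sem in zip(ens.lags_s, ens.mean_msd_um2, ens.sem_um2):
            assert abs(mean - 4 * D * lag) < 3 * sem + 1e-12

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            ensemble_msd([])


class TestRadiusOfConfinement:
    def test_hand_example(self):
        """(1,0),(-1,0),(1,0),(-1,0) um: sigma2=2/3, dr0^2=1, Rc=1.7078."""
        pos = np.array([[1.0, 0.0], [-1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        tr = relative_track_from_arrays(pos, np.zeros_like(pos))
        res = radius_of_confinement(tr)
        assert res.sigma2_um2 == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert res.dr0_2_um2 == pytest.approx(1.0, abs=1e-12)
        assert res.rc_um == pytest.approx(np.sqrt(1.25 * (4.0 / 3.0 + 1.0)), abs=1e-12)
        assert res.rc_um == pytest.approx(1.7078, abs=1e-4)

    def test_degenerate_track_flagged_zero(self):
        tr = relative_track_from_arrays(np.ones((5, 3)), np.zeros((5, 3)))
        res = radius_of_confinement(tr)
        assert res.rc_um == 0.0
        assert res.degenerate

    def test_uniform_ball_recovers_radius(self, rng):
        for R in (0.5, 1.0):
            pts = uniform_ball(100_000, R, rng)
            tr = relative_track_from_arrays(pts, np.zeros_like(pts))
            assert radius_of_confinement(tr).rc_um == pytest.approx(R, rel=0.01)

    def test_uniform_disk_gives_sqrt54_radius(self, rng):
        R = 0.8
        pts = uniform_disk(100_000, R, rng)
        tr = relative_track_from_arrays(pts, np.zeros_like(pts))
        assert radius_of_confinement(tr).rc_um == pytest.approx(np.sqrt(1.25) * R, rel=0.01)

    def test_scale_equivariance(self, rng):
        pos = rng.normal(size=(50, 3))
        tr1 = relative_track_from_arrays(pos, np.zeros_like(pos))
        tr2 = relative_track_from_arrays(3.0 * pos, np.zeros_like(pos))
        r1, r2 = radius_of_confinement(tr1), radius_of_confinement(tr2)
        assert r2.rc_um == pytest.approx(3.0 * r1.rc_um, rel=1e-12)
        c1 = compute_msd(tr1)
        c2 = compute_msd(tr2)
        assert np.allclose(c2.msd_um2, 9.0 * c1.msd_um2)

    def test_drift_added_to_both_channels_cancels(self, rng):
        """Shared per-frame drift changes MSD and Rc by < 1e-9 um."""
        foc = rng.normal(size=(40, 3))
        fid = rng.normal(scale=0.01, size=(40, 3))
        drift = np.cumsum(rng.normal(scale=0.5, size=(40, 3)), axis=0)
        a = relative_track_from_arrays(foc, fid)
        b = relative_track_from_arrays(foc + drift, fid + drift)
        ra, rb = radius_of_confinement(a), radius_of_confinement(b)
        assert abs(ra.rc_um - rb.rc_um) < 1e-9
        ca, cb = compute_msd(a), compute_msd(b)
        assert np.max(np.abs(ca.msd_um2 - cb.msd_um2)) < 1e-9

    def test_too_few_frames(self):
        tr = relative_track_from_arrays(np.ones((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            radius_of_confinement(tr)


class TestAnalyzeCondition:
    def _cohort(self, R, n_cells=12, n_frames=41, seed=0):
        tracks = []
        cfg = SimulationConfig(
            confinement_radius=R, diffusion_coeff=2e-3, n_frames=n_frames, seed=seed
        )
        root = np.random.default_rng(seed)
        for i, stream in enumerate(root.spawn(n_cells)):
            t = simulate_confined_track(cfg, rng=stream)
            tracks.append(
                relative_track_from_arrays(t, np.zeros_like(t), cell_id=f"c{i}")
            )
        return tracks

    def test_long_track_limit_recovers_radius(self):
        res = analyze_condition(self._cohort(0.8, n_cells=20, n_frames=2000), "WT")
        assert res.mean_rc == pytest.approx(0.8, rel=0.03)

    def test_rc_ordered_in_true_radius(self):
        lo = analyze_condition(self._cohort(0.6, seed=1), "lo")
        hi = analyze_condition(self._cohort(1.0, seed=2), "hi")
        assert lo.mean_rc < hi.mean_rc

    def test_warns_below_ten_cells(self):
        with pytest.warns(UserWarning, match="only 5 cells"):
            analyze_condition(self._cohort(0.8, n_cells=5), "few")

    def test_deterministic_summary(self):
        a = analyze_condition(self._cohort(0.8, seed=3), "WT")
        b = analyze_condition(self._cohort(0.8, seed=3), "WT")
        assert a.per_cell.equals(b.per_cell)

    def test_no_accepted_cells_raises_with_reasons(self):
        bad = relative_track_from_arrays(np.ones((2, 3)), np.zeros((2, 3)), cell_id="bad")
        with pytest.raises(ValueError, match="bad"):
            analyze_condition([bad], "empty")

    def test_plateau_consistency(self):
        """Rc^2 ~ (5/4) * MSD plateau on long confined tracks, within 5%."""
        tracks = self._cohort(0.8, n_cells=10, n_frames=3000, seed=4)
        rcs = [radius_of_confinement(t).rc_um for t in tracks]
        curves = [compute_msd(t, max_lag_frames=60) for t in tracks]
        ens = ensemble_msd(curves)
        plateau = float(np.mean(ens.mean_msd_um2[-20:]))
        assert np.mean(rcs) ** 2 == pytest.approx(1.25 * plateau, rel=0.05)
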