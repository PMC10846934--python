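"""Drift estimation and correction: null calibration, constructed shifts,
simulation recovery, fiducials, reliability assessment."""

import numpy as np
import pytest

import expalm
from expalm.drift import DriftTrajectory


def rmse2d(err):
    return float(np.sqrt(np.mean(np.sum(np.asarray(err) ** 2, axis=1))))


def static_field(rng, n_mol=400, frames=200, sigma=5.0, span=8000.0):
    """Molecules at fixed positions, re-detected every frame."""
    pos = rng.uniform(0, span, (n_mol, 2))
    f = np.repeat(np.arange(frames), n_mol)
    mol = np.tile(np.arange(n_mol), frames)
    obs = pos[mol] + rng.normal(0, sigma, (len(f), 2))
    return expalm.LocalizationTable(obs[:, 0], obs[:, 1], f,
                                    np.ones(len(f))), pos, mol


# ---------------------------------------------------------------------------
# cross-correlation

def test_xcorr_null_below_render_pixel(rng):
    table, _, _ = static_field(rng, frames=200)
    traj = expalm.drift_by_cross_correlation(table, substack_len=50,
                                             render_px=10.0)
    assert np.abs(traj.as_array()).max() < 10.0
    assert traj.dx[0] == 0.0 and traj.dy[0] == 0.0


def test_xcorr_recovers_constructed_shift(rng):
    """Second half of a dense static movie shifted by (+50, 0) nm: the
    trajectory steps from ~0 to ~50 nm across the boundary."""
    table, _, _ = static_field(rng, frames=200)
    shift = np.zeros((200, 2))
    shift[100:] = (50.0, 0.0)
    shifted = expalm.apply_drift(
        table, DriftTrajectory(shift[:, 0], shift[:, 1],
                               np.ones(200, np.int64)))
    traj = expalm.drift_by_cross_correlation(shifted, substack_len=50,
                                             render_px=10.0)
    assert traj.dx[30] == pytest.approx(0.0, abs=5.0)   # render_px / 2
    assert traj.dx[160] == pytest.approx(50.0, abs=5.0)
    assert np.abs(traj.dy).max() < 5.0


def test_xcorr_recovers_linear_drift(marker_field):
    """Linear drift of 1 nm/frame over 3000 frames recovered to < 10 nm."""
    table, drift = marker_field(11, velocity=(1.0, 0.0), step_sd=0.0)
    traj = expalm.drift_by_cross_correlation(table, substack_len=500,
                                             render_px=10.0)
    assert rmse2d(traj.as_array() - drift) < 10.0


def test_xcorr_empty_substack_interpolated(rng):
    table, _, _ = static_field(rng, frames=300)
    gap = table.select((table.frame < 100) | (table.frame >= 200))
    traj = expalm.drift_by_cross_correlation(gap, substack_len=100,
                                             render_px=10.0, n_frames=300)
    assert (traj.support[100:200] == 0).all()
    assert np.isfinite(traj.as_array()).all()


def test_xcorr_needs_two_substacks(rng):
    table, _, _ = static_field(rng, frames=50)
    with pytest.raises(ValueError, match="two sub-stacks"):
        expalm.drift_by_cross_correlation(table, substack_len=100)


# ---------------------------------------------------------------------------
# frame-to-frame

def test_frame_to_frame_single_track_exact():
    """One noiseless molecule seen every frame under 1 nm/frame drift:
    the unsmoothed cumulative trajectory is exact."""
    frames = np.arange(101)
    table = expalm.LocalizationTable(frames * 1.0, np.zeros(101), frames,
                                     np.ones(101))
    tracks, _ = expalm.link_tracks(table, max_dist=10.0)
    traj = expalm.drift_frame_to_frame(table, tracks, smooth_window=0)
    assert traj.dx[-1] == pytest.approx(100.0, abs=1e-9)
    assert np.allclose(traj.dy, 0.0)


def test_frame_to_frame_null_bound(rng):
    """Zero injected drift: trajectory stays within 3 sigma/sqrt(support)."""
    sigma = 10.0
    table, _, _ = static_field(rng, n_mol=200, frames=500, sigma=sigma)
    tracks, _ = expalm.link_tracks(table, max_dist=8 * sigma)
    traj = expalm.drift_frame_to_frame(table, tracks)
    bound = 3 * sigma / np.sqrt(np.median(traj.support))
    assert np.abs(traj.as_array()).max() < bound


def test_frame_to_frame_recovery(marker_field):
    """Linear + random-walk drift recovered to better than sigma_loc/2."""
    table, drift = marker_field(5, frames=1500, n_cells=2, n_mol=60)
    tracks, _ = expalm.link_tracks(table, max_dist=120.0)
    traj = expalm.drift_frame_to_frame(table, tracks, n_frames=1500)
    assert rmse2d(traj.as_array() - drift) < 14.0 / 2
    assert traj.support[1:].min() >= 0


def test_frame_to_frame_requires_tracks():
    table = expalm.LocalizationTable([0.0], [0.0], [0], [1.0])
    with pytest.raises(ValueError, match="no tracked support"):
        expalm.drift_frame_to_frame(table, [])


# ---------------------------------------------------------------------------
# fiducials

def make_fiducial_table(paths, frames):
    """paths: list of (frames, 2) arrays."""
    xs, ys, fs = [], [], []
    for p in paths:
        xs.append(p[:, 0])
        ys.append(p[:, 1])
        fs.append(np.arange(frames))
    return expalm.LocalizationTable(np.concatenate(xs), np.concatenate(ys),
                                    np.concatenate(fs),
                                    np.ones(frames * len(paths)))


def test_fiducial_known_path_exact():
    frames = 100
    drift = np.cumsum(np.full((frames, 2), 0.5), axis=0) - 0.5
    path = np.array([1000.0, 2000.0]) + drift
    table = make_fiducial_table([path], frames)
    traj = expalm.drift_from_fiducials(table, [(1000, 2000)], radius=200.0)
    np.testing.assert_allclose(traj.as_array(), drift, atol=1e-9)


def test_fiducial_offset_invariance():
    """Two fiducials on paths P and P + const give exactly P - P(0)."""
    frames = 80
    rng = np.random.default_rng(4)
    drift = np.cumsum(rng.normal(0, 1.0, (frames, 2)), axis=0)
    drift -= drift[0]
    p1 = np.array([0.0, 0.0]) + drift
    p2 = np.array([5000.0, 3000.0]) + drift
    table = make_fiducial_table([p1, p2], frames)
    traj = expalm.drift_from_fiducials(table, [(0, 0), (5000, 3000)],
                                       radius=200.0)
    np.testing.assert_allclose(traj.as_array(), drift, atol=1e-9)
    assert (traj.support == 2).all()


def test_fiducial_averaging_bound():
    """Three fiducials with 10 nm localization noise on a linear drift.

    Each per-frame error is mean(eps_t) - mean(eps_0) over 3 fiducials
    (anchoring at frame 0 doubles the variance), so the 2-D RMSE is
    sqrt(2 axes * 2 * sigma^2 / 3) ~ 11.5 nm; assert within 1.5x of it.
    """
    frames, sigma = 400, 10.0
    rng = np.random.default_rng(9)
    drift = np.arange(frames)[:, None] * np.array([0.5, 0.0])
    seeds = np.array([[0.0, 0.0], [4000.0, 0.0], [0.0, 4000.0]])
    paths = [s + drift + rng.normal(0, sigma, (frames, 2)) for s in seeds]
    table = make_fiducial_table(paths, frames)
    traj = expalm.drift_from_fiducials(table, seeds.tolist(), radius=300.0)
    analytic = np.sqrt(2 * 2 * sigma ** 2 / 3)
    assert rmse2d(traj.as_array() - drift) < 1.5 * analytic


def test_fiducial_coverage_precondition():
    table = expalm.LocalizationTable([0.0], [0.0], [0], [1.0])
    with pytest.raises(ValueError, match="fraction of frames"):
        expalm.drift_from_fiducials(table, [(5000, 5000)], radius=10.0,
                                    n_frames=100)


# ---------------------------------------------------------------------------
# applying corrections, reliability

def test_zero_trajectory_is_identity(rng):
    table, _, _ = static_field(rng, n_mol=20, frames=10)
    traj = DriftTrajectory.zero(10)
    out = expalm.apply_drift_correction(table, traj)
    assert out.allclose(table, tol=0.0)


def test_apply_then_correct_is_exact_inverse(rng):
    table, _, _ = static_field(rng, n_mol=20, frames=50)
    drift = np.cumsum(rng.normal(0, 2, (50, 2)), axis=0)
    drift -= drift[0]
    traj = DriftTrajectory(drift[:, 0], drift[:, 1],
                           np.ones(50, np.int64))
    out = expalm.apply_drift_correction(expalm.apply_drift(table, traj),
                                        traj)
    np.testing.assert_allclose(out.xy, table.xy, atol=1e-9)


def test_correction_requires_full_domain(rng):
    table, _, _ = static_field(rng, n_mol=5, frames=50)
    with pytest.raises(ValueError, match="cover"):
        expalm.apply_drift_correction(table, DriftTrajectory.zero(10))


def test_reliability_trailing_window():
    traj = DriftTrajectory(np.zeros(8), np.zeros(8),
                           np.array([10, 10, 10, 1, 0, 0, 0, 0]))
    assert expalm.assess_reliability(traj, min_support=3, window=1) == (0, 3)
    uniform = DriftTrajectory(np.zeros(6), np.zeros(6), np.full(6, 10))
    assert expalm.assess_reliability(uniform, min_support=3) == (0, 6)
    assert expalm.assess_reliability(traj, min_support=100,
                                     window=1) == (0, 0)


def test_reliability_excludes_bleached_tail():
    """A movie whose localization density decays loses its tail."""
    support = np.concatenate([np.full(300, 20),
                              np.round(20 * np.exp(-np.arange(300) / 60))])
    traj = DriftTrajectory(np.zeros(600), np.zeros(600), support)
    first, last = expalm.assess_reliability(traj, min_support=5, window=50)
    assert first == 0 and 300 < last < 560
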