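"""Covariate derivation: bearings, distances, wall features, speed, binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egospace import (Session, bin_covariates, compute_center_bearing,
                      compute_center_distance, compute_covariates,
                      compute_speed, compute_wall_features)
from egospace.session import DT, Trajectory, ang_diff_deg, wrap_deg


def _traj(x, y, hd):
    n = len(x)
    return Trajectory(np.arange(n) * DT, np.asarray(x, float),
                      np.asarray(y, float), np.asarray(hd, float))


@pytest.mark.parametrize("pos,hd,expected", [
    ((60, 0), 90, 0),     # facing the centroid
    ((60, 0), 0, 90),     # centroid due left under the CCW convention
    ((0, 60), 0, 0),      # centroid due East, facing East
])
def test_center_bearing_convention(sq_arena, pos, hd, expected):
    tr = _traj([pos[0]] * 2, [pos[1]] * 2, [hd] * 2)
    b = compute_center_bearing(tr, sq_arena)
    assert b[0] == pytest.approx(expected, abs=1e-9)


def test_center_bearing_nan_at_centroid(sq_arena):
    tr = _traj([60.0, 60.0], [60.0, 10.0], [0.0, 0.0])
    b = compute_center_bearing(tr, sq_arena)
    assert np.isnan(b[0]) and np.isfinite(b[1])


@pytest.mark.parametrize("pos,expected", [
    ((60, 0), 60.0),
    ((60, 60), 0.0),
    ((0, 0), 60 * np.sqrt(2)),
])
def test_center_distance(sq_arena, pos, expected):
    tr = _traj([pos[0]] * 2, [pos[1]] * 2, [0.0] * 2)
    assert compute_center_distance(tr, sq_arena)[0] == pytest.approx(expected)


def test_wall_features_ranking_and_bearing(sq_arena):
    tr = _traj([30.0, 60.0], [10.0, 10.0], [0.0, 90.0])
    bearing, dist = compute_wall_features(tr, sq_arena)
    # (30, 10): south wall at 10 cm, west wall at 30 cm
    assert dist[0, 0] == pytest.approx(10.0)
    assert dist[0, 1] == pytest.approx(30.0)
    # (60, 10) facing North: south wall directly behind
    assert bearing[1, 0] == pytest.approx(180.0)


def test_wall_features_match_bruteforce(sq_session, sq_covariates):
    """Ranked wall distances equal a dense-sampling minimum over each segment."""
    traj = sq_session.session.trajectory
    arena = sq_session.session.arena
    idx = np.arange(0, len(traj), 997)          # subsample frames
    _, dist = compute_wall_features(traj, arena)
    for i in idx:
        p = np.array([traj.x[i], traj.y[i]])
        brute = []
        for seg in arena.wall_segments:
            ts = np.linspace(0, 1, 2001)
            pts = seg[0] + ts[:, None] * (seg[1] - seg[0])
            brute.append(np.linalg.norm(pts - p, axis=1).min())
        brute = np.sort(brute)
        assert abs(dist[i, 0] - brute[0]) < 0.01
        assert abs(dist[i, 1] - brute[1]) < 0.01


def test_wall_tie_resolved_by_fixed_order(sq_arena):
    """At the exact center all four walls tie; the fixed enumeration wins."""
    tr = _traj([60.0, 60.0], [60.0, 60.0], [0.0, 0.0])
    bearing, dist = compute_wall_features(tr, sq_arena)
    assert dist[0, 0] == pytest.approx(60.0)
    assert dist[0, 1] == pytest.approx(60.0)
    # rank 1 = south wall (first in enumeration): nearest point (60, 0)
    assert bearing[0, 0] == pytest.approx(270.0)


def test_speed_examples():
    tr = _traj([0.0, 1.0, 1.0], [0.0, 0.0, 0.0], [0.0] * 3)
    sp = compute_speed(tr)
    assert sp[1] == pytest.approx(30.0)
    assert sp[0] == sp[1]               # first frame copies the second
    assert sp[2] == 0.0


def test_speed_of_simulated_trajectory(sq_trajectory):
    sp = compute_speed(sq_trajectory)
    assert np.all(sp >= 0)
    assert sp.max() < 46.0              # simulator speed cap plus rounding


def test_hd_rotation_shifts_bearing(sq_arena):
    """Rotating the head by delta decreases the center bearing by delta."""
    rng = np.random.default_rng(3)
    x = rng.uniform(5, 115, 50)
    y = rng.uniform(5, 115, 50)
    hd = rng.uniform(0, 360, 50)
    delta = 37.0
    b0 = compute_center_bearing(_traj(x, y, hd), sq_arena)
    b1 = compute_center_bearing(_traj(x, y, wrap_deg(hd + delta)), sq_arena)
    assert np.allclose(wrap_deg(b0 - delta), b1, atol=1e-9)


def test_l_shape_inserted_wall_shortens_distance(L_arena, sq_arena):
    """Near the blocked quadrant the nearest wall is an inserted one."""
    tr = _traj([55.0, 55.0], [90.0, 90.0], [0.0, 0.0])
    _, d_l = compute_wall_features(tr, L_arena)
    _, d_sq = compute_wall_features(tr, sq_arena)
    assert d_l[0, 0] == pytest.approx(5.0)      # inserted vertical wall at x=60
    assert d_l[0, 0] < d_sq[0, 0]


def test_bin_covariates_examples(sq_session):
    bnd = bin_covariates(sq_session.covariates)
    cov = sq_session.covariates
    hd_v = cov.hd[bnd.valid]
    cb_v = cov.center_bearing[bnd.valid]
    assert np.all(bnd.bin_idx["hd"][hd_v < 12.0] == 0)
    assert np.all(bnd.bin_idx["center_bearing"][cb_v >= 348.0] == 29)
    # each frame lands in exactly one bin per variable and counts add up
    for v in ("hd", "center_bearing", "center_distance", "speed"):
        counts = np.bincount(bnd.bin_idx[v], minlength=bnd.n_bins[v])
        assert counts.sum() == len(bnd)


def test_bin_covariates_uniform_hd_histogram():
    """HD bin occupancy of a uniform angular sweep matches the histogram oracle."""
    n = 3000
    hd = np.linspace(0, 360, n, endpoint=False)
    tr = _traj(np.full(n, 30.0), np.full(n, 30.0), hd)
    from egospace import square_arena
    cov = compute_covariates(Session(square_arena(), tr))
    bnd = bin_covariates(cov)
    counts = np.bincount(bnd.bin_idx["hd"], minlength=30)
    assert np.all(counts == n // 30)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(-720, 720, allow_nan=False), st.floats(-720, 720, allow_nan=False))
def test_angle_helpers(a, b):
    assert 0 <= wrap_deg(a) < 360
    d = ang_diff_deg(a, b)
    assert -180 < d <= 180
    assert abs(ang_diff_deg(b + d, a)) == pytest.approx(0.0, abs=1e-6)
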