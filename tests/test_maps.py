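"""Rate maps, inserted-wall change, spatial autocorrelation, grid score."""

import numpy as np
import pytest

from egospace import (CellSpec, grid_score, make_synthetic_session,
                      occupancy_ratemap, spatial_autocorr_2d,
                      wall_proximity_change)
from egospace.maps import RateMap, smooth_masked


def hex_map(spacing_bins=10, square=False, n=30):
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    if square:
        return (np.cos(2 * np.pi * xx / spacing_bins)
                + np.cos(2 * np.pi * yy / spacing_bins)) + 2.0
    k = 4 * np.pi / (np.sqrt(3) * spacing_bins)
    vals = sum(np.cos(k * (np.cos(t) * xx + np.sin(t) * yy))
               for t in (0.0, np.pi / 3, 2 * np.pi / 3))
    return vals - vals.min()


def test_ratemap_spike_mass_conservation(sq_session):
    sess = sq_session.session
    rm = occupancy_ratemap(sess, "bearing")
    spikes = np.nansum(np.where(rm.mask, rm.raw_rate * rm.occupancy, 0.0))
    assert spikes == pytest.approx(sess.cells["bearing"].n_spikes, rel=1e-9)


def test_ratemap_constant_cell_flat(sq_session):
    rm = occupancy_ratemap(sq_session.session, "noise")
    vals = rm.rate[rm.mask]
    assert np.nanmean(vals) == pytest.approx(3.0, rel=0.1)
    assert np.nanstd(vals) / np.nanmean(vals) < 0.2


def test_ratemap_l_shape_masks_blocked_quadrant(L_arena):
    syn = make_synthetic_session(L_arena, 600.0,
                                 {"c": CellSpec("noise", peak_rate=5.0)}, seed=51)
    rm = occupancy_ratemap(syn.session, "c")
    cx, cy = rm.bin_centers
    gx, gy = np.meshgrid(cx, cy)
    blocked = (gx > 62.0) & (gy > 62.0)
    assert not rm.mask[blocked].any()


def test_smoothing_preserves_spatial_mean(sq_session):
    rm = occupancy_ratemap(sq_session.session, "bearing")
    raw_mean = np.nanmean(rm.raw_rate[rm.mask])
    smooth_mean = np.nanmean(rm.rate[rm.mask])
    assert smooth_mean == pytest.approx(raw_mean, rel=0.02)


def _as_ratemap(vals, occ=1.0):
    mask = np.ones_like(vals, bool)
    n = vals.shape[0]
    edges = np.arange(n + 1) * 4.0
    return RateMap(vals.astype(float), vals.astype(float),
                   np.full_like(vals, occ, dtype=float), mask, edges, edges)


def test_wall_change_identical_maps_zero(L_arena):
    vals = np.random.default_rng(0).uniform(1, 5, (30, 30))
    near, far = wall_proximity_change(_as_ratemap(vals), _as_ratemap(vals), L_arena)
    assert near == pytest.approx(0.0, abs=1e-12)
    assert far == pytest.approx(0.0, abs=1e-12)


def test_wall_change_antisymmetric(L_arena):
    rng = np.random.default_rng(1)
    a = _as_ratemap(rng.uniform(1, 5, (30, 30)))
    b = _as_ratemap(rng.uniform(1, 5, (30, 30)))
    n1, f1 = wall_proximity_change(a, b, L_arena)
    n2, f2 = wall_proximity_change(b, a, L_arena)
    assert n1 == pytest.approx(-n2)
    assert f1 == pytest.approx(-f2)


def test_wall_change_detects_inserted_wall_field(L_arena):
    """A field appearing along the inserted walls raises the near mean only."""
    base = np.full((30, 30), 1.0)
    gained = base.copy()
    cx, cy = np.meshgrid((np.arange(30) + 0.5) * 4, (np.arange(30) + 0.5) * 4)
    near_ins = (np.abs(cx - 60) < 10) & (cy > 55) | (np.abs(cy - 60) < 10) & (cx > 55)
    gained[near_ins] += 4.0
    noise = np.random.default_rng(2).normal(0, 0.01, (30, 30))
    near, far = wall_proximity_change(_as_ratemap(base + noise),
                                      _as_ratemap(gained + noise), L_arena)
    assert near > 0.2
    assert abs(far) < 0.1


def test_spatial_autocorr_properties():
    vals = hex_map()
    ac = spatial_autocorr_2d(vals, mask=np.ones_like(vals, bool))
    c = (np.array(ac.shape) - 1) // 2
    assert ac[c[0], c[1]] == pytest.approx(1.0)
    # point symmetry where both sides are defined
    flipped = ac[::-1, ::-1]
    ok = np.isfinite(ac) & np.isfinite(flipped)
    assert np.allclose(ac[ok], flipped[ok], atol=1e-9)


def test_spatial_autocorr_constant_map_errors():
    with pytest.raises(ValueError):
        spatial_autocorr_2d(np.ones((30, 30)), mask=np.ones((30, 30), bool))


def test_grid_score_fixtures():
    ac_hex = spatial_autocorr_2d(hex_map(), mask=np.ones((30, 30), bool))
    g = grid_score(ac_hex)
    assert g.score > 0.4 and g.is_grid
    ac_sq = spatial_autocorr_2d(hex_map(square=True), mask=np.ones((30, 30), bool))
    g2 = grid_score(ac_sq)
    assert g2.score < 0.0 and not g2.is_grid


def test_grid_score_rotation_invariance():
    """The hexagonal fixture scores the same after a 60-degree rotation."""
    from scipy.ndimage import rotate
    vals = hex_map()
    rot = rotate(vals, 60.0, reshape=False, order=3, mode="reflect")
    s0 = grid_score(spatial_autocorr_2d(vals, mask=np.ones((30, 30), bool))).score
    s1 = grid_score(spatial_autocorr_2d(rot, mask=np.ones((30, 30), bool))).score
    assert abs(s0 - s1) < 0.25


def test_simulated_grid_cell_scores_as_grid(sq_arena, sq_trajectory):
    spec = CellSpec("grid", peak_rate=15.0, baseline_rate=0.3,
                    grid_spacing=40.0, grid_phase=(10.0, 20.0))
    syn = make_synthetic_session(sq_arena, 1200.0, {"g": spec}, seed=52,
                                 trajectory=sq_trajectory)
    rm = occupancy_ratemap(syn.session, "g")
    res = grid_score(spatial_autocorr_2d(rm))
    assert res.is_grid
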