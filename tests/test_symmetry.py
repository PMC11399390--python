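"""Rotational-symmetry scoring across the three analysis domains."""

import numpy as np
import pytest

from egospace import (CellSpec, circular_autocorr, diagonal_autocorr,
                      make_synthetic_session, symmetry_scores_from_autocorr)
from egospace.symmetry import (fit_rotation_model, hd_conditioned_ratemaps,
                               hd_location_corr_matrix)

DEG = np.arange(360.0)


def test_autocorr_closed_forms():
    ac4 = circular_autocorr(np.cos(np.radians(4 * DEG)), DEG)
    assert ac4.at(0) == pytest.approx(1.0)
    for lag in (90, 180, 270):
        assert ac4.at(lag) == pytest.approx(1.0, abs=1e-6)
    assert ac4.at(45) == pytest.approx(-1.0, abs=1e-6)
    ac1 = circular_autocorr(np.cos(np.radians(DEG)), DEG)
    assert ac1.at(180) == pytest.approx(-1.0, abs=1e-6)


def test_autocorr_constant_curve_errors():
    with pytest.raises(ValueError):
        circular_autocorr(np.ones(30))


def test_symmetry_scores_closed_forms():
    s4 = symmetry_scores_from_autocorr(circular_autocorr(np.cos(np.radians(4 * DEG)), DEG))
    assert s4[4] == pytest.approx(2.0, abs=1e-6)
    assert s4[1] == pytest.approx(0.0, abs=1e-6)
    s1 = symmetry_scores_from_autocorr(circular_autocorr(np.cos(np.radians(DEG)), DEG))
    assert s1[1] == pytest.approx(2.0, abs=1e-6)
    assert s1[4] == pytest.approx(-1.0 - np.cos(np.radians(45)), abs=1e-6)
    s2 = symmetry_scores_from_autocorr(circular_autocorr(np.cos(np.radians(2 * DEG)), DEG))
    assert s2[2] == pytest.approx(2.0, abs=1e-6)


def test_scores_invariant_to_curve_offset():
    curve = 2.0 + np.cos(np.radians(4 * DEG)) + 0.3 * np.cos(np.radians(DEG))
    a = symmetry_scores_from_autocorr(circular_autocorr(curve, DEG))
    b = symmetry_scores_from_autocorr(circular_autocorr(curve + 17.0, DEG))
    for k in (1, 2, 3, 4):
        assert a[k] == pytest.approx(b[k], abs=1e-9)
        assert -2.0 <= a[k] <= 2.0


def test_diagonal_autocorr_matches_bruteforce_oracle():
    """Banded diagonal autocorrelation equals an explicit double-loop oracle."""
    n = 120
    rng = np.random.default_rng(7)
    u = np.cos(np.radians(2 * np.arange(n) * 3.0)) + rng.normal(0, 0.2, n)
    m = np.outer(u, u)
    m = 0.5 * (m + m.T)
    ac = diagonal_autocorr(m)
    half = 15                               # +/- 45 degrees in 3-degree steps
    offs = range(-half, half + 1)
    band = np.array([[m[i, (i + d) % n] for i in range(n)] for d in offs])
    for s_deg in (0, 45, 90, 180):
        s = s_deg // 3
        shifted = np.array([[m[(i + s) % n, (i + s + d) % n] for i in range(n)]
                            for d in offs])
        expected = np.corrcoef(band.ravel(), shifted.ravel())[0, 1]
        assert ac.at(s_deg) == pytest.approx(expected, abs=1e-9)
    assert ac.at(0) == pytest.approx(1.0)


def test_diagonal_autocorr_four_block_matrix():
    """Four ~90-degree blocks on the diagonal give peaks at multiples of 90."""
    n = 120
    group = (np.arange(n) * 3.0 // 90).astype(int) % 4
    m = (group[:, None] == group[None, :]).astype(float)
    ac = diagonal_autocorr(m)
    for lag in (90, 180, 270):
        assert ac.at(lag) > 0.5
    assert ac.at(45) < 0.0


def test_diagonal_autocorr_constant_matrix_errors():
    with pytest.raises(ValueError):
        diagonal_autocorr(np.ones((120, 120)))


def test_hd_conditioned_maps_place_cell(sq_arena, sq_trajectory):
    """A location-only cell yields HD-conditioned maps that all agree."""
    spec = CellSpec("grid", peak_rate=12.0, baseline_rate=0.2,
                    grid_spacing=60.0, grid_phase=(20.0, 20.0))
    syn = make_synthetic_session(sq_arena, 1200.0, {"p": spec}, seed=41,
                                 trajectory=sq_trajectory)
    counts = syn.session.cells["p"].binned_counts(syn.session.n_frames)
    maps, masks, usable = hd_conditioned_ratemaps(syn.session, counts,
                                                  syn.covariates)
    assert maps.shape[0] == 120 and usable.all()
    mat = hd_location_corr_matrix(maps, masks)
    assert np.allclose(mat, mat.T, equal_nan=True)
    assert np.allclose(np.diag(mat), 1.0)
    off = mat[np.triu_indices(120, k=1)]
    assert np.nanmedian(off) > 0.7


def test_hd_window_overlap(sq_session):
    """Adjacent 3-degree map centers share most frames (+/-30 deg windows)."""
    cov = sq_session.covariates
    hd = cov.hd[cov.valid]
    in0 = np.abs((hd - 0 + 180) % 360 - 180) <= 30
    in3 = np.abs((hd - 3 + 180) % 360 - 180) <= 30
    shared = (in0 & in3).sum()
    assert shared / in0.sum() > 0.9


def test_rotation_model_detrend_identity(sq_session):
    """A center-referenced cell's rotation function hugs the identity line."""
    counts = sq_session.session.cells["bearing"].binned_counts(
        sq_session.session.n_frames)
    fit = fit_rotation_model(sq_session.session, counts, sq_session.covariates)
    assert np.all(np.abs(fit.detrended) <= 180.0)
    assert np.median(np.abs(fit.detrended)) < 45.0
    scores = symmetry_scores_from_autocorr(fit.autocorr)
    assert scores[4] < 1.0


def test_rotation_model_snaps_for_four_fold_cell(sq_arena, sq_trajectory):
    """A boundary-referenced cell drives a step-wise rotation function."""
    spec = CellSpec("conjunctive",
                    components=("wall_bearing_local", "wall_distance_local"),
                    peak_rate=15.0, baseline_rate=0.5, pref_angle=0.0,
                    kappa=4.0, pref_distance=5.0, distance_width=10.0)
    syn = make_synthetic_session(sq_arena, 1200.0, {"b": spec}, seed=42,
                                 trajectory=sq_trajectory)
    counts = syn.session.cells["b"].binned_counts(syn.session.n_frames)
    fit = fit_rotation_model(syn.session, counts, syn.covariates)
    scores = symmetry_scores_from_autocorr(fit.autocorr)
    assert scores[4] > 0.5
    assert np.ptp(fit.detrended) > 40.0
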