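"""Penalized Poisson GLM: likelihood, penalty, fitting, selection, shuffles."""

import numpy as np
import pytest

from egospace import (CellSpec, bin_covariates, classify_cell, crossval_models,
                      fit_glm, forward_select, make_synthetic_session,
                      poisson_log_likelihood, shuffle_spike_train,
                      smoothing_penalty, square_arena)
from egospace.glm import GLMConfig, GLM_VARIABLES


@pytest.mark.parametrize("n,r,expected", [
    (np.zeros(10), np.ones(10), -10.0),
    (np.ones(10), np.ones(10), -10.0),
    (np.array([2.0]), np.array([2.0]), np.log(2.0) - 2.0),
])
def test_poisson_log_likelihood_closed_forms(n, r, expected):
    assert poisson_log_likelihood(n, r) == pytest.approx(expected, abs=1e-12)


def test_poisson_log_likelihood_length_mismatch():
    with pytest.raises(ValueError):
        poisson_log_likelihood(np.zeros(3), np.ones(4))


def test_smoothing_penalty_closed_forms():
    b = {"v": np.array([0.0, 1.0, 0.0])}
    assert smoothing_penalty(b, {"v": True}, 20.0) == pytest.approx(20.0)
    const = {"v": np.full(7, 3.3)}
    assert smoothing_penalty(const, {"v": True}, 20.0) == 0.0
    # quadratic scaling
    b2 = {"v": 2.0 * b["v"]}
    assert smoothing_penalty(b2, {"v": True}, 20.0) == pytest.approx(80.0)
    # open-ended adjacency drops the wraparound term
    assert smoothing_penalty(b, {"v": False}, 20.0) == pytest.approx(20.0)
    edge = {"v": np.array([1.0, 0.0, 0.0])}
    assert smoothing_penalty(edge, {"v": False}, 20.0) == pytest.approx(10.0)
    assert smoothing_penalty(edge, {"v": True}, 20.0) == pytest.approx(20.0)


@pytest.fixture(scope="module")
def binned(sq_session):
    return bin_covariates(sq_session.covariates)


def test_fit_recovers_mean_rate(sq_session, binned):
    """A constant-rate cell fits to its mean rate within 1%."""
    sess = sq_session.session
    n = sess.cells["noise"].binned_counts(sess.n_frames)[binned.valid]
    fit = fit_glm(binned, n, GLMConfig())
    lin = sum(fit.betas[v][binned.bin_idx[v]] for v in GLM_VARIABLES)
    assert np.exp(lin).mean() == pytest.approx(n.mean(), rel=0.01)


def test_fit_recovers_bearing_kernel(sq_session, binned):
    sess = sq_session.session
    spec = sq_session.specs["bearing"]
    n = sess.cells["bearing"].binned_counts(sess.n_frames)[binned.valid]
    fit = fit_glm(binned, n, GLMConfig())
    beta = fit.betas["center_bearing"]
    centers = (np.arange(30) + 0.5) * 12.0
    kernel = np.exp(spec.kappa * (np.cos(np.radians(centers - spec.pref_angle)) - 1))
    est = np.exp(beta - beta.mean())
    cos = (est @ kernel) / (np.linalg.norm(est) * np.linalg.norm(kernel))
    assert cos > 0.9


def test_huge_smoothing_flattens_beta(sq_session, binned):
    sess = sq_session.session
    n = sess.cells["bearing"].binned_counts(sess.n_frames)[binned.valid]
    fit = fit_glm(binned, n, GLMConfig(smoothing=1e6))
    assert np.ptp(fit.betas["center_bearing"]) < 0.05


def test_crossval_table_enumerates_all_subsets(sq_session, binned):
    sess = sq_session.session
    n = sess.cells["noise"].binned_counts(sess.n_frames)[binned.valid]
    table = crossval_models(binned, n, GLMConfig())
    assert len(table.test_ll) == 16                     # 15 subsets + mean model
    assert all(len(v) == 10 for v in table.test_ll.values())


def test_forward_select_recovers_bearing_cell(sq_session, binned):
    sess = sq_session.session
    n = sess.cells["bearing"].binned_counts(sess.n_frames)[binned.valid]
    sel = forward_select(crossval_models(binned, n, GLMConfig()))
    assert sel != "unclassified" and "center_bearing" in sel


def test_forward_select_recovers_conjunctive_cell(sq_arena, sq_trajectory):
    spec = CellSpec("conjunctive", components=("center_bearing", "hd_unidirectional"),
                    peak_rate=15.0, baseline_rate=0.3, pref_angle=45.0, kappa=3.0)
    syn = make_synthetic_session(sq_arena, 1200.0, {"conj": spec}, seed=21,
                                 trajectory=sq_trajectory)
    bnd = bin_covariates(syn.covariates)
    n = syn.session.cells["conj"].binned_counts(syn.session.n_frames)[bnd.valid]
    sel = forward_select(crossval_models(bnd, n, GLMConfig()))
    assert sel != "unclassified"
    assert "center_bearing" in sel and "hd" in sel


def test_shuffle_preserves_count_and_bounds():
    rng = np.random.default_rng(0)
    times = np.sort(rng.uniform(0, 600.0, 500))
    for _ in range(5):
        shifted = shuffle_spike_train(times, 600.0, rng)
        assert len(shifted) == 500
        assert shifted.min() >= 0 and shifted.max() < 600.0
        # ISI multiset preserved up to the single wrap break
        isi0 = np.sort(np.diff(times))
        isi1 = np.sort(np.diff(shifted))
        assert np.sum(~np.isclose(isi0[:-1], isi1[:-1], atol=1e-6)) <= len(isi0)


def test_shuffle_rejects_short_session():
    with pytest.raises(ValueError):
        shuffle_spike_train(np.array([1.0]), 50.0, np.random.default_rng(0))


def test_classify_cell_thresholds(sq_session):
    """Strong HD cell classified; noise cell rejected; MVL beats its null."""
    cfg = GLMConfig(n_shuffles=100)
    sess = sq_session.session
    res_hd = classify_cell(sess, "hd", cfg, seed=7,
                           covariates=sq_session.covariates)
    assert res_hd.is_hd and not res_hd.is_eb
    assert res_hd.hd_mvl > res_hd.hd_mvl_threshold
    res_noise = classify_cell(sess, "noise", cfg, seed=8,
                              covariates=sq_session.covariates)
    assert not res_noise.is_eb and not res_noise.is_hd


def test_classify_low_rate_bearing_cell_fails_peak_criterion(sq_arena, sq_trajectory):
    """An EB-tuned cell whose curve never exceeds 1 Hz is rejected."""
    spec = CellSpec("center_bearing", peak_rate=0.5, baseline_rate=0.05,
                    pref_angle=0.0, kappa=3.0)
    syn = make_synthetic_session(sq_arena, 1200.0, {"dim": spec}, seed=22,
                                 trajectory=sq_trajectory)
    res = classify_cell(syn.session, "dim", GLMConfig(n_shuffles=50), seed=9,
                        covariates=syn.covariates)
    assert res.bearing_peak_hz < 1.0
    assert not res.is_eb
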