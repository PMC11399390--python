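"""Local (two-wall) vs. global (centroid) encoding-model contest.

Two Poisson GLMs with identical parameter counts are fit to each cell's
full session, unpenalized, and compared by raw log-likelihood:

* the *centroid* model — the four-variable classification GLM (center
  bearing, center distance, head direction, speed);
* the *two-wall* model — bearing and distance of the two walls closest
  to the animal, with one shared bearing curve and one shared distance
  curve re-used for both wall ranks, times head-direction and speed
  terms:  ``r = sum_j exp(Xd_j b_dist) exp(Xb_j b_bear) * exp(sum_i X_i b_i)``.

Each model's likelihood is expressed as its gain over a mean-rate-only
model in bits/spike, and the two gains are contrasted by the Globality
Index ``GI = (l_center - l_two_wall) / (l_center + l_two_wall)``, positive
for center-referenced (global) tuning and negative for wall-referenced
(local) tuning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .glm import GLMConfig, fit_glm, poisson_log_likelihood
from .session import (Covariates, Session, bin_covariates,
                      compute_covariates, N_BINS_ANGULAR, N_BINS_LINEAR)

__all__ = [
    "WallModelFit", "GlobalityResult", "fit_two_wall_model",
    "fit_centroid_model", "globality_index", "globality_for_cell",
    "WALL_DIST_RANGE_CM",
]

WALL_DIST_RANGE_CM = (0.0, 60.0)   # max perpendicular wall distance in these arenas


@dataclass
class WallModelFit:
    """Fitted two-wall model (shared betas across wall ranks)."""

    beta_bearing: np.ndarray       # 30 bins
    beta_dist: np.ndarray          # 10 bins
    beta_hd: np.ndarray
    beta_speed: np.ndarray
    log_likelihood: float          # nats, full session
    gain_bits_per_spike: float     # over the mean-rate model
    converged: bool


@dataclass
class GlobalityResult:
    """Model-contest outcome for one cell in one session."""

    ll_center: float               # bits/spike gain of the centroid model
    ll_two_wall: float             # bits/spike gain of the two-wall model
    gi: float                      # NaN when both gains <= 0
    reason: str = ""


def _bits_per_spike(ll_model: float, ll_mean: float, n_spikes: float) -> float:
    if n_spikes <= 0:
        return float("nan")
    return (ll_model - ll_mean) / (np.log(2.0) * n_spikes)


def _mean_model_ll(n: np.ndarray, floor: float) -> float:
    r0 = np.full(len(n), max(n.mean(), floor))
    return poisson_log_likelihood(n, r0)


def _wall_bins(cov: Covariates):
    """Bin indices (valid frames) for the two-wall design."""
    m = cov.valid
    width = 360.0 / N_BINS_ANGULAR
    bb = np.minimum((np.mod(cov.wall_bearing[m], 360.0) / width).astype(int),
                    N_BINS_ANGULAR - 1)
    lo, hi = WALL_DIST_RANGE_CM
    db = np.clip(((cov.wall_distance[m] - lo) / (hi - lo) * N_BINS_LINEAR).astype(int),
                 0, N_BINS_LINEAR - 1)
    hdb = np.minimum((np.mod(cov.hd[m], 360.0) / width).astype(int), N_BINS_ANGULAR - 1)
    sp = cov.speed[m]
    slo, shi = float(sp.min()), float(max(sp.max(), sp.min() + 1e-9))
    spb = np.clip(((sp - slo) / (shi - slo) * N_BINS_LINEAR).astype(int),
                  0, N_BINS_LINEAR - 1)
    return bb, db, hdb, spb


def fit_two_wall_model(session: Session, cell: str,
                       config: GLMConfig = GLMConfig(),
                       covariates: Covariates | None = None) -> WallModelFit:
    """Fit the two-closest-walls model to a cell's full session (no penalty)."""
    cov = covariates if covariates is not None else compute_covariates(session)
    n = session.cells[cell].binned_counts(session.n_frames)[cov.valid].astype(float)
    bb, db, hdb, spb = _wall_bins(cov)
    nb_b, nb_d = N_BINS_ANGULAR, N_BINS_LINEAR
    nb_h, nb_s = N_BINS_ANGULAR, N_BINS_LINEAR
    off = np.cumsum([0, nb_d, nb_b, nb_h, nb_s])
    floor = config.rate_floor

    def objective(x):
        bd, bbear = x[off[0]:off[1]], x[off[1]:off[2]]
        bhd, bsp = x[off[2]:off[3]], x[off[3]:off[4]]
        a1 = np.exp(np.clip(bd[db[:, 0]] + bbear[bb[:, 0]], -30, 30))
        a2 = np.exp(np.clip(bd[db[:, 1]] + bbear[bb[:, 1]], -30, 30))
        e = np.exp(np.clip(bhd[hdb] + bsp[spb], -30, 30))
        r = (a1 + a2) * e
        rf = np.maximum(r, floor)
        nll = float(rf.sum() - n @ np.log(rf))
        common = 1.0 - n / rf
        grad = np.empty_like(x)
        grad[off[0]:off[1]] = (np.bincount(db[:, 0], weights=common * e * a1, minlength=nb_d)
                               + np.bincount(db[:, 1], weights=common * e * a2, minlength=nb_d))
        grad[off[1]:off[2]] = (np.bincount(bb[:, 0], weights=common * e * a1, minlength=nb_b)
                               + np.bincount(bb[:, 1], weights=common * e * a2, minlength=nb_b))
        grad[off[2]:off[3]] = np.bincount(hdb, weights=common * r, minlength=nb_h)
        grad[off[3]:off[4]] = np.bincount(spb, weights=common * r, minlength=nb_s)
        return nll, grad

    x0 = np.zeros(off[-1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": config.max_iter, "gtol": config.gtol})
    bd, bbear = res.x[off[0]:off[1]], res.x[off[1]:off[2]]
    bhd, bsp = res.x[off[2]:off[3]], res.x[off[3]:off[4]]
    a1 = np.exp(bd[db[:, 0]] + bbear[bb[:, 0]])
    a2 = np.exp(bd[db[:, 1]] + bbear[bb[:, 1]])
    r = np.maximum((a1 + a2) * np.exp(bhd[hdb] + bsp[spb]), floor)
    ll = poisson_log_likelihood(n, r)
    gain = _bits_per_spike(ll, _mean_model_ll(n, floor), n.sum())
    return WallModelFit(bbear, bd, bhd, bsp, ll, gain, bool(res.success))


def fit_centroid_model(session: Session, cell: str,
                       config: GLMConfig = GLMConfig(),
                       covariates: Covariates | None = None):
    """Fit the unpenalized four-variable centroid model to the full session.

    Returns ``(GLMFit, gain_bits_per_spike)``.
    """
    cov = covariates if covariates is not None else compute_covariates(session)
    bnd = bin_covariates(cov)
    n = session.cells[cell].binned_counts(session.n_frames)[bnd.valid].astype(float)
    fit = fit_glm(bnd, n, config, penalized=False)
    gain = _bits_per_spike(fit.log_likelihood,
                           _mean_model_ll(n, config.rate_floor), n.sum())
    return fit, gain


def globality_index(ll_center: float, ll_two_wall: float) -> float:
    """Globality Index from the two models' bits/spike gains.

    Undefined (NaN) when the gains sum to a non-positive value — a cell
    neither model explains better than its mean rate.
    """
    denom = ll_center + ll_two_wall
    if not np.isfinite(denom) or denom <= 0:
        return float("nan")
    return (ll_center - ll_two_wall) / denom


def globality_for_cell(session: Session, cell: str,
                       config: GLMConfig = GLMConfig(),
                       covariates: Covariates | None = None) -> GlobalityResult:
    """Run the full model contest for one cell in one session."""
    cov = covariates if covariates is not None else compute_covariates(session)
    _, gc = fit_centroid_model(session, cell, config, cov)
    wall = fit_two_wall_model(session, cell, config, cov)
    gi = globality_index(gc, wall.gain_bits_per_spike)
    reason = "" if np.isfinite(gi) else "non-positive combined gain"
    return GlobalityResult(gc, wall.gain_bits_per_spike, gi, reason)
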