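"""Three-domain rotational-symmetry analysis for egocentric bearing cells.

A cell tuned to the local geometry of a square arena (walls, corners)
should repeat its firing every 90 degrees; a cell referenced to the
arena center should not. Symmetry is quantified in three domains:

1. the autocorrelation of the HD tuning curve;
2. the autocorrelation, along its main diagonal, of the matrix of
   pairwise correlations between HD-conditioned location rate maps
   (one map per 3-degree HD step, each using frames within +/- 30
   degrees of its center);
3. the autocorrelation of the detrended rotation function of a GLM that
   reconstructs the spike train from a 1-D projected-distance function
   rotated about the arena center by an HD-dependent angle.

From each autocorrelation, 1- to 4-fold symmetry scores are computed at
fixed lag sets, summed across domains into an aggregate score, and
compared with a spike-train time-shift shuffle null (95th percentile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import minimize

from .glm import GLMConfig, shuffle_spike_train
from .maps import smooth_masked
from .session import (DT, Covariates, Session, SpikeTrain, ang_diff_deg,
                      compute_covariates, wrap_deg)
from .tuning import angular_tuning_curve

__all__ = [
    "AutocorrFunction", "SymmetryScores", "RotationModelFit",
    "circular_autocorr", "symmetry_scores_from_autocorr",
    "hd_conditioned_ratemaps", "hd_location_corr_matrix",
    "diagonal_autocorr", "fit_rotation_model", "aggregate_symmetry",
    "domain_scores",
]

FOLD_ORDERS = (1, 2, 3, 4)
SCORE_LAGS = {
    4: ((90, 180, 270), (45, 135, 225, 315)),
    3: ((120, 240), (60, 180, 300)),
    2: ((180,), (90, 270)),
    1: ((0,), (180,)),
}


@dataclass
class AutocorrFunction:
    """Circular autocorrelation at 1-degree lags (lag 0 -> correlation 1)."""

    lags: np.ndarray       # deg, 0..359
    values: np.ndarray

    def at(self, lag_deg: int) -> float:
        return float(self.values[int(lag_deg) % 360])


def _resample_1deg(values: np.ndarray, centers_deg: np.ndarray) -> np.ndarray:
    """Linear circular interpolation of a binned curve onto 0..359 degrees."""
    v = np.asarray(values, float)
    ok = np.isfinite(v)
    if ok.sum() < 3:
        raise ValueError("too few valid bins to resample")
    grid = np.arange(360.0)
    return np.interp(grid, centers_deg[ok], v[ok], period=360.0)


def circular_autocorr(values: np.ndarray,
                      centers_deg: np.ndarray | None = None) -> AutocorrFunction:
    """Pearson autocorrelation of a circular curve at all 1-degree lags.

    The curve (any even angular binning; NaN bins interpolated through)
    is first resampled to 1-degree resolution so that the score lags
    (45, 60, 90, ... degrees) are exactly representable.
    """
    v = np.asarray(values, float)
    if centers_deg is None:
        width = 360.0 / len(v)
        centers_deg = (np.arange(len(v)) + 0.5) * width
    x = _resample_1deg(v, np.asarray(centers_deg, float))
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("constant curve: autocorrelation undefined")
    # all circular lags at once via FFT
    f = np.fft.rfft(x)
    ac = np.fft.irfft(f * np.conj(f), n=360) / denom
    return AutocorrFunction(np.arange(360), ac)


def symmetry_scores_from_autocorr(ac: AutocorrFunction) -> dict:
    """1- to 4-fold symmetry scores at the fixed lag sets.

    n-fold score = (lowest correlation at the n-fold lags) - (highest
    correlation at the interleaved off lags); each lies in [-2, 2].
    """
    out = {}
    for k, (on, off) in SCORE_LAGS.items():
        out[k] = min(ac.at(l) for l in on) - max(ac.at(l) for l in off)
    return out


# ---------------------------------------------------------------------------
# domain 2: HD-conditioned rate maps

HD_STEP_DEG = 3
HD_WINDOW_DEG = 30
N_HD_MAPS = 360 // HD_STEP_DEG        # 120


def hd_conditioned_ratemaps(session: Session, counts: np.ndarray,
                            cov: Covariates,
                            bin_cm: float = 4.0,
                            occ_min_s: float = 0.1,
                            sigma_bins: float = 1.5,
                            min_valid_bins: int = 10):
    """Location rate maps conditioned on head direction.

    One map per 3-degree HD step; each map uses only frames whose HD lies
    within +/- 30 degrees of the step center. Returns ``(maps, masks,
    usable)`` with ``maps`` shaped (120, ny, nx) (NaN outside masks).
    """
    traj = session.trajectory
    m = cov.valid
    x, y, hd, c = traj.x[m], traj.y[m], cov.hd[m], np.asarray(counts, float)[m]
    pts = session.arena.wall_segments.reshape(-1, 2)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    nx = int(np.ceil((hi[0] - lo[0]) / bin_cm))
    ny = int(np.ceil((hi[1] - lo[1]) / bin_cm))
    xb = np.clip(((x - lo[0]) / bin_cm).astype(int), 0, nx - 1)
    yb = np.clip(((y - lo[1]) / bin_cm).astype(int), 0, ny - 1)
    hb = np.minimum((hd / HD_STEP_DEG).astype(int), N_HD_MAPS - 1)

    occ = np.zeros((N_HD_MAPS, ny, nx))
    spk = np.zeros((N_HD_MAPS, ny, nx))
    np.add.at(occ, (hb, yb, xb), 1.0)
    np.add.at(spk, (hb, yb, xb), c)
    occ *= DT
    # +/- 30 degrees = 21 HD slices of 3 degrees, circular window sum
    win = 2 * (HD_WINDOW_DEG // HD_STEP_DEG) + 1
    occ = uniform_filter1d(occ, size=win, axis=0, mode="wrap") * win
    spk = uniform_filter1d(spk, size=win, axis=0, mode="wrap") * win

    masks = occ >= occ_min_s
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(masks, spk / np.where(masks, occ, 1.0), 0.0)
    num = np.empty_like(raw)
    for i in range(N_HD_MAPS):          # mask-aware smoothing per map
        num[i] = smooth_masked(raw[i], masks[i], sigma_bins)
    usable = masks.reshape(N_HD_MAPS, -1).sum(axis=1) >= min_valid_bins
    return num, masks, usable


def hd_location_corr_matrix(maps: np.ndarray, masks: np.ndarray,
                            min_shared_bins: int = 10) -> np.ndarray:
    """Pairwise Pearson correlations between HD-conditioned rate maps.

    Entry (i, j) correlates maps i and j over bins valid in both; pairs
    sharing fewer than ``min_shared_bins`` bins are NaN. Symmetric with
    unit diagonal.
    """
    n = maps.shape[0]
    flat = maps.reshape(n, -1)
    mflat = masks.reshape(n, -1) & np.isfinite(flat)
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            ok = mflat[i] & mflat[j]
            if ok.sum() < min_shared_bins:
                continue
            a, b = flat[i][ok], flat[j][ok]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            v = float((a - a.mean()) @ (b - b.mean())) / (len(a) * sa * sb)
            out[i, j] = out[j, i] = v
    return out


def diagonal_autocorr(corr_matrix: np.ndarray,
                      band_deg: float = 45.0,
                      step_deg: float = HD_STEP_DEG,
                      max_missing_frac: float = 0.5) -> AutocorrFunction:
    """Autocorrelation of a correlation matrix along its main diagonal.

    The band of entries within ``band_deg`` of the main diagonal (the
    matrix's central 90 degrees) is correlated with the same band of the
    matrix shifted by (s, s) for every circular 3-degree shift s, then
    resampled to 1-degree lags.
    """
    m = np.asarray(corr_matrix, float)
    n = m.shape[0]
    half = int(round(band_deg / step_deg))
    offs = np.arange(-half, half + 1)
    i = np.arange(n)
    band = np.stack([m[i, (i + d) % n] for d in offs])      # (n_off, n)
    if np.isnan(band).mean() > max_missing_frac:
        raise ValueError("too many missing entries in the diagonal band")
    vals = np.empty(n)
    for s in range(n):
        shifted = np.roll(band, -s, axis=1)
        ok = np.isfinite(band) & np.isfinite(shifted)
        a, b = band[ok], shifted[ok]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            raise ValueError("constant diagonal band: autocorrelation undefined")
        vals[s] = float((a - a.mean()) @ (b - b.mean())) / (len(a) * sa * sb)
    centers = np.arange(n) * step_deg
    grid = np.arange(360.0)
    res = np.interp(grid, centers, vals, period=360.0)
    return AutocorrFunction(np.arange(360), res)


# ---------------------------------------------------------------------------
# domain 3: projected-distance / rotation GLM

N_ROT_BINS = 30        # HD bins carrying one rotation angle each
N_DIST_BINS = 30
ROT_CANDIDATE_STEP_DEG = 3.0
MVL_PENALTY_WEIGHT = 10.0


@dataclass
class RotationModelFit:
    """Fitted projected-distance/rotation GLM for one cell."""

    distance_function: np.ndarray       # log-rate over 30 signed-projection bins
    hd_function: np.ndarray             # nuisance HD tuning (log-rate)
    rotation_function: np.ndarray       # deg in [0, 360), one per HD bin
    detrended: np.ndarray               # deviation from the identity line, deg
    autocorr: AutocorrFunction
    converged: bool = True


def _proj_bins(dist, phi, rot_per_frame, r_max):
    # projections are clipped at +/- r_max (the centroid-to-wall inradius)
    # so every axis direction sees the same usable range; otherwise axes
    # pointing at corners gain resolution and attract the rotation function
    s = np.clip(dist * np.cos(np.radians(phi - rot_per_frame)), -r_max, r_max)
    return np.clip(((s + r_max) / (2 * r_max) * N_DIST_BINS).astype(int),
                   0, N_DIST_BINS - 1)


def _mvl_of_angles(deg: np.ndarray) -> float:
    z = np.exp(1j * np.radians(deg))
    return float(np.abs(z.mean()))


def fit_rotation_model(session: Session, counts: np.ndarray,
                       cov: Covariates,
                       config: GLMConfig = GLMConfig(),
                       mvl_weight: float = MVL_PENALTY_WEIGHT,
                       n_outer: int = 3) -> RotationModelFit:
    """Fit the radial-symmetry GLM by alternating optimization.

    Model: ``log r_t = f(sbin_t) + h(hdbin_t)`` where ``s_t`` is the
    signed projection of the animal's position (relative to the arena
    center) onto an axis rotated by ``g(hdbin_t)``. ``f`` and ``h`` are
    fit by penalized Poisson likelihood given ``g``; each ``g`` entry is
    then updated by a 3-degree grid search including a penalty
    ``w * MVL(g)`` that discourages all rotations collapsing onto one
    angle. The returned rotation function is detrended against the
    identity line (offset chosen to minimize circular squared deviation).
    """
    m = cov.valid
    traj = session.trajectory
    cx, cy = session.arena.centroid
    dx, dy = traj.x[m] - cx, traj.y[m] - cy
    dist = np.hypot(dx, dy)
    phi = np.degrees(np.arctan2(dy, dx))
    n = np.asarray(counts, float)[m]
    hdb = np.minimum((cov.hd[m] / (360.0 / N_ROT_BINS)).astype(int), N_ROT_BINS - 1)
    r_max = float(session.arena.wall_distances(cx, cy)[0].min())
    hd_centers = (np.arange(N_ROT_BINS) + 0.5) * (360.0 / N_ROT_BINS)
    # two deterministic starts: the identity line, and the spike-weighted
    # mean position direction per HD bin (identity-like for
    # center-referenced cells, snapped for wall-referenced cells); the
    # alternating refinement keeps whichever basin fits better
    g_identity = hd_centers.copy()
    g_moment = hd_centers.copy()
    zx = np.bincount(hdb, weights=n * dx, minlength=N_ROT_BINS)
    zy = np.bincount(hdb, weights=n * dy, minlength=N_ROT_BINS)
    nsp = np.bincount(hdb, weights=n, minlength=N_ROT_BINS)
    has = nsp > 0
    g_moment[has] = wrap_deg(np.degrees(np.arctan2(zy[has], zx[has])))
    S = config.smoothing
    log_floor = np.log(config.rate_floor)

    # precompute frame lists and candidate projections per HD bin
    frames_in = [np.nonzero(hdb == b)[0] for b in range(N_ROT_BINS)]
    cand = np.arange(0.0, 360.0, ROT_CANDIDATE_STEP_DEG)
    cand_bins = []                      # per HD bin: (n_cand, n_frames_b) proj bins
    for b in range(N_ROT_BINS):
        f_idx = frames_in[b]
        s = np.clip(dist[f_idx][None, :]
                    * np.cos(np.radians(phi[f_idx][None, :] - cand[:, None])),
                    -r_max, r_max)
        cand_bins.append(np.clip(((s + r_max) / (2 * r_max) * N_DIST_BINS).astype(int),
                                 0, N_DIST_BINS - 1))

    def fit_f_h(rot_per_frame):
        sbin = _proj_bins(dist, phi, rot_per_frame, r_max)
        d_open = np.diff(np.eye(N_DIST_BINS), axis=0)
        p_f = S * (d_open.T @ d_open)
        d_circ = np.diff(np.eye(N_ROT_BINS), axis=0)
        d_circ = np.vstack([d_circ, np.eye(N_ROT_BINS)[0] - np.eye(N_ROT_BINS)[-1]])
        p_h = S * (d_circ.T @ d_circ)

        def obj(x):
            f, h = x[:N_DIST_BINS], x[N_DIST_BINS:]
            lin = np.clip(f[sbin] + h[hdb], log_floor, 30.0)
            r = np.exp(lin)
            nll = float(r.sum() - n @ lin)
            resid = r - n
            grad = np.concatenate([
                np.bincount(sbin, weights=resid, minlength=N_DIST_BINS) + p_f @ f,
                np.bincount(hdb, weights=resid, minlength=N_ROT_BINS) + p_h @ h,
            ])
            pen = 0.5 * float(f @ (p_f @ f)) + 0.5 * float(h @ (p_h @ h))
            return nll + pen, grad

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(obj, np.zeros(N_DIST_BINS + N_ROT_BINS), jac=True,
                           method="L-BFGS-B",
                           options={"maxiter": config.max_iter, "gtol": config.gtol})
        return (res.x[:N_DIST_BINS], res.x[N_DIST_BINS:], bool(res.success),
                float(res.fun))

    def run_from(g0):
        g = g0.copy()
        converged = True
        f = h = obj_val = None
        for _ in range(n_outer):
            f, h, ok, obj_val = fit_f_h(g[hdb])
            converged = converged and ok
            # coordinate-wise grid update of the rotation function
            for b in range(N_ROT_BINS):
                f_idx = frames_in[b]
                if len(f_idx) == 0:
                    continue
                nb = n[f_idx]
                lin = np.clip(f[cand_bins[b]] + h[b], log_floor, 30.0)  # (n_cand, nf)
                ll = (nb[None, :] * lin - np.exp(lin)).sum(axis=1)
                # MVL penalty: resultant of the other bins plus each candidate
                others = np.exp(1j * np.radians(np.delete(g, b))).sum()
                res_len = np.abs(others + np.exp(1j * np.radians(cand))) / N_ROT_BINS
                score = ll - mvl_weight * res_len
                g[b] = cand[int(np.argmax(score))]
        f, h, ok, obj_val = fit_f_h(g[hdb])
        converged = converged and ok
        total = obj_val + mvl_weight * _mvl_of_angles(g)
        return g, f, h, converged, total

    g_i, f_i, h_i, conv_i, obj_i = run_from(g_identity)
    g_m, f_m, h_m, conv_m, obj_m = run_from(g_moment)
    if obj_m < obj_i:                   # ties favor the identity start
        g, f, h, converged = g_m, f_m, h_m, conv_m
    else:
        g, f, h, converged = g_i, f_i, h_i, conv_i

    # unvisited HD bins: interpolate circularly
    visited = np.array([len(fi) > 0 for fi in frames_in])
    if not visited.all():
        if visited.sum() < 3:
            raise ValueError("too few visited HD bins for the rotation model")
        dev = ang_diff_deg(g, hd_centers)
        dev[~visited] = np.interp(hd_centers[~visited], hd_centers[visited],
                                  dev[visited], period=360.0)
        g = wrap_deg(hd_centers + dev)

    offset = np.degrees(np.angle(np.exp(1j * np.radians(g - hd_centers)).mean()))
    detrended = ang_diff_deg(g, hd_centers + offset)
    ac = circular_autocorr(detrended, hd_centers)
    return RotationModelFit(f, h, g, detrended, ac, converged)


# ---------------------------------------------------------------------------
# aggregate scoring with shuffle null

@dataclass
class SymmetryScores:
    """Per-domain and aggregate 1- to 4-fold symmetry scores."""

    hd_curve: dict
    hd_location: dict
    rotation: dict
    aggregate: dict
    thresholds: dict = field(default_factory=dict)     # fold -> aggregate 95th pct
    significant: dict = field(default_factory=dict)
    domain_thresholds: dict = field(default_factory=dict)
    incomplete: bool = False


def domain_scores(session: Session, counts: np.ndarray, cov: Covariates,
                  config: GLMConfig = GLMConfig()) -> tuple[dict, dict, dict]:
    """Run the three symmetry domains for one spike-count vector."""
    hd_curve = angular_tuning_curve(cov.hd, counts, valid=cov.valid)
    s1 = symmetry_scores_from_autocorr(circular_autocorr(hd_curve.rate,
                                                         hd_curve.bin_centers))
    maps, masks, _usable = hd_conditioned_ratemaps(session, counts, cov)
    mat = hd_location_corr_matrix(maps, masks)
    s2 = symmetry_scores_from_autocorr(diagonal_autocorr(mat))
    rot = fit_rotation_model(session, counts, cov, config)
    s3 = symmetry_scores_from_autocorr(rot.autocorr)
    return s1, s2, s3


def aggregate_symmetry(session: Session, cell: str,
                       n_shuffles: int = 100,
                       seed: int = 0,
                       config: GLMConfig = GLMConfig(),
                       covariates: Covariates | None = None) -> SymmetryScores:
    """Three-domain symmetry scores with a spike-shift shuffle null.

    The aggregate score for each fold order sums the three domain scores;
    significance compares it with the 95th percentile of the same
    aggregate computed on time-shifted surrogate spike trains.
    """
    cov = covariates if covariates is not None else compute_covariates(session)
    st = session.cells[cell]
    counts = st.binned_counts(session.n_frames)
    try:
        s1, s2, s3 = domain_scores(session, counts, cov, config)
    except ValueError:
        return SymmetryScores({}, {}, {}, {}, incomplete=True)
    agg = {k: s1[k] + s2[k] + s3[k] for k in FOLD_ORDERS}

    rng = np.random.default_rng(seed)
    null = {k: [] for k in FOLD_ORDERS}
    null_dom = {d: {k: [] for k in FOLD_ORDERS} for d in range(3)}
    for _ in range(n_shuffles):
        shifted = shuffle_spike_train(st.spike_times, session.duration, rng)
        c = SpikeTrain(shifted).binned_counts(session.n_frames)
        try:
            t1, t2, t3 = domain_scores(session, c, cov, config)
        except ValueError:
            continue
        for k in FOLD_ORDERS:
            null[k].append(t1[k] + t2[k] + t3[k])
            for d, t in enumerate((t1, t2, t3)):
                null_dom[d][k].append(t[k])
    thr = {k: (float(np.percentile(null[k], 95)) if null[k] else float("nan"))
           for k in FOLD_ORDERS}
    dom_thr = {d: {k: (float(np.percentile(null_dom[d][k], 95)) if null_dom[d][k]
                       else float("nan")) for k in FOLD_ORDERS}
               for d in range(3)}
    sig = {k: bool(np.isfinite(thr[k]) and agg[k] > thr[k]) for k in FOLD_ORDERS}
    return SymmetryScores(s1, s2, s3, agg, thr, sig, dom_thr)
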