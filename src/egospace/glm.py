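"""Penalized Poisson GLM classification of spatial tuning.

The encoding model expresses a cell's per-frame firing rate as
``r = exp(sum_i X_i^T beta_i)`` over up to four binned behavioral
variables (head direction, center bearing, center distance, speed). Each
``beta_i`` is a binned tuning curve in log-rate space, estimated by
minimizing ``P - l`` where ``l`` is the Poisson log-likelihood of the
spike train and ``P`` a quadratic roughness penalty on adjacent bins
(with wraparound adjacency for circular variables).

Classification uses 10-fold cross-validation: the full four-variable
model is fit on each training split, sub-models are evaluated on the held
out split, and a forward-selection procedure with one-sided Wilcoxon
signed-rank tests across folds picks the most parsimonious variable set
that significantly beats a mean-rate-only model. Significance thresholds
for tuning-strength statistics come from spike-train time-shift shuffles.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import wilcoxon

from .session import (DT, BinnedCovariates, Covariates, Session, SpikeTrain,
                      bin_covariates, compute_covariates)
from .tuning import angular_tuning_curve

__all__ = [
    "GLMConfig", "GLMFit", "CrossvalTable", "CellClassification",
    "poisson_log_likelihood", "smoothing_penalty", "fit_glm",
    "crossval_models", "forward_select", "shuffle_spike_train",
    "shuffle_mvl_null", "classify_cell",
]

GLM_VARIABLES = ("hd", "center_bearing", "center_distance", "speed")


@dataclass(frozen=True)
class GLMConfig:
    """Hyperparameters of the classification GLM."""

    smoothing: float = 20.0        # roughness hyperparameter S
    n_folds: int = 10
    alpha: float = 0.05            # selection test level
    rate_floor: float = 1e-8       # spikes/bin floor inside the likelihood
    gtol: float = 1e-6
    max_iter: int = 1000
    mvl_floor_eb: float = 0.10     # bearing-MVL minimum for EB cells
    mvl_floor_hd: float = 0.15     # HD-MVL minimum for HD cells
    peak_rate_floor_hz: float = 1.0
    n_shuffles: int = 400
    shuffle_percentile: float = 99.0

    def __post_init__(self):
        if self.smoothing < 0 or self.n_folds < 2:
            raise ValueError("need smoothing >= 0 and >= 2 folds")


# ---------------------------------------------------------------------------
# likelihood and penalty

def poisson_log_likelihood(n: np.ndarray, r: np.ndarray) -> float:
    """Poisson log-likelihood of counts ``n`` under per-bin means ``r``.

    ``l = sum_t [n_t ln r_t - r_t - ln(n_t!)]``; ``r`` must be positive.
    """
    n = np.asarray(n)
    r = np.asarray(r, float)
    if n.shape != r.shape:
        raise ValueError("n and r must have equal length")
    return float(np.sum(n * np.log(r) - r - gammaln(n + 1.0)))


def _diff_op(n_bins: int, circular: bool) -> np.ndarray:
    """First-difference operator over bins (wraps for circular variables)."""
    rows = n_bins if circular else n_bins - 1
    d = np.zeros((rows, n_bins))
    for j in range(rows):
        d[j, j] = -1.0
        d[j, (j + 1) % n_bins] = 1.0
    return d


def smoothing_penalty(betas: dict, circular: dict, smoothing: float) -> float:
    """Quadratic roughness penalty ``P = S * sum_i sum_j (b_{j+1}-b_j)^2 / 2``."""
    p = 0.0
    for name, b in betas.items():
        d = np.diff(b)
        if circular[name]:
            d = np.append(d, b[0] - b[-1])
        p += 0.5 * smoothing * float(d @ d)
    return p


# ---------------------------------------------------------------------------
# fitting

@dataclass
class GLMFit:
    """Result of one penalized (or plain) Poisson GLM fit."""

    betas: dict                    # variable -> beta vector (log-rate space)
    log_likelihood: float          # nats, incl. ln(n!) term, at the optimum
    converged: bool
    mean_log_rate: float           # fitted log mean spikes/frame (mean-only model)
    n_iter: int = 0


def _pack(betas: dict, variables) -> np.ndarray:
    return np.concatenate([betas[v] for v in variables])


def _unpack(x: np.ndarray, binned: BinnedCovariates, variables) -> dict:
    out, i = {}, 0
    for v in variables:
        nb = binned.n_bins[v]
        out[v] = x[i:i + nb]
        i += nb
    return out


def fit_glm(binned: BinnedCovariates, n: np.ndarray, config: GLMConfig,
            variables=GLM_VARIABLES, penalized: bool = True,
            sample_mask: np.ndarray | None = None) -> GLMFit:
    """Fit ``r = exp(sum_i X_i beta_i)`` by minimizing ``P - l``.

    ``n`` is the spike count per retained frame (aligned with ``binned``).
    ``sample_mask`` restricts the fit to a subset of frames (for
    cross-validation). Deterministic: initialized at beta = 0, solved with
    L-BFGS-B and the analytic gradient.
    """
    variables = tuple(variables)
    n = np.asarray(n, float)
    if len(n) != len(binned):
        raise ValueError("spike counts not aligned with binned covariates")
    if sample_mask is not None:
        idx = {v: binned.bin_idx[v][sample_mask] for v in variables}
        n_fit = n[sample_mask]
    else:
        idx = {v: binned.bin_idx[v] for v in variables}
        n_fit = n
    nb = [binned.n_bins[v] for v in variables]
    offsets = np.concatenate([[0], np.cumsum(nb)])
    log_floor = np.log(config.rate_floor)

    # penalty as a block-diagonal quadratic form S * D^T D
    pmats = []
    for v in variables:
        d = _diff_op(binned.n_bins[v], binned.circular[v])
        pmats.append(config.smoothing * (d.T @ d) if penalized else np.zeros((d.shape[1],) * 2))

    def objective(x):
        lin = np.zeros(len(n_fit))
        for k, v in enumerate(variables):
            lin += x[offsets[k]:offsets[k + 1]][idx[v]]
        lin = np.clip(lin, log_floor, 30.0)
        r = np.exp(lin)
        nll = float(r.sum() - n_fit @ lin)
        grad = np.empty_like(x)
        resid = r - n_fit
        pen = 0.0
        for k, v in enumerate(variables):
            b = x[offsets[k]:offsets[k + 1]]
            g = np.bincount(idx[v], weights=resid, minlength=len(b))
            pb = pmats[k] @ b
            pen += 0.5 * float(b @ pb)
            grad[offsets[k]:offsets[k + 1]] = g + pb
        return nll + pen, grad

    x0 = np.zeros(offsets[-1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": config.max_iter, "gtol": config.gtol})
    betas = _unpack(res.x, binned, variables)
    lin = np.zeros(len(n_fit))
    for v in variables:
        lin += betas[v][idx[v]]
    r = np.exp(np.clip(lin, log_floor, 30.0))
    ll = poisson_log_likelihood(n_fit, r)
    mean_rate = max(float(n_fit.mean()), config.rate_floor)
    return GLMFit(betas, ll, bool(res.success), float(np.log(mean_rate)),
                  n_iter=int(res.nit))


# ---------------------------------------------------------------------------
# cross-validation and model selection

@dataclass
class CrossvalTable:
    """Held-out log-likelihoods per variable subset and fold.

    ``test_ll[subset]`` is a length-``n_folds`` array; subsets are sorted
    tuples of variable names, with the empty tuple for the mean-rate-only
    model. Values are nats per test fold (``ln(n!)`` terms included, so
    they cancel in paired comparisons).
    """

    test_ll: dict
    fold_flags: list = field(default_factory=list)   # zero-spike folds

    def subsets(self):
        return [s for s in self.test_ll if s]


def _contiguous_folds(n_frames: int, k: int):
    edges = np.linspace(0, n_frames, k + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(k)]


def crossval_models(binned: BinnedCovariates, n: np.ndarray,
                    config: GLMConfig = GLMConfig()) -> CrossvalTable:
    """10-fold cross-validated log-likelihoods for all variable subsets.

    Per fold the *full* four-variable model is fit once on the training
    frames; each subset's held-out likelihood reuses those fitted betas,
    with dropped variables contributing their occupancy-weighted mean
    (training-fold) value as a constant so that sub-models differ only by
    the dropped tuning structure. The mean-rate-only model uses the
    training mean rate.
    """
    n = np.asarray(n, float)
    folds = _contiguous_folds(len(n), config.n_folds)
    subsets = [tuple(sorted(c)) for size in range(1, 5)
               for c in itertools.combinations(GLM_VARIABLES, size)]
    table = {s: np.empty(config.n_folds) for s in subsets}
    table[()] = np.empty(config.n_folds)
    flags = []
    log_floor = np.log(config.rate_floor)
    for f, (lo, hi) in enumerate(folds):
        test = np.zeros(len(n), bool)
        test[lo:hi] = True
        train = ~test
        if n[test].sum() == 0:
            flags.append(f)
        fit = fit_glm(binned, n, config, GLM_VARIABLES, penalized=True,
                      sample_mask=train)
        contrib_test = {}
        mean_contrib = {}
        for v in GLM_VARIABLES:
            per_frame_train = fit.betas[v][binned.bin_idx[v][train]]
            mean_contrib[v] = float(per_frame_train.mean())
            contrib_test[v] = fit.betas[v][binned.bin_idx[v][test]]
        n_test = n[test]
        for s in subsets:
            lin = np.zeros(test.sum())
            for v in GLM_VARIABLES:
                lin += contrib_test[v] if v in s else mean_contrib[v]
            r = np.exp(np.clip(lin, log_floor, 30.0))
            table[s][f] = poisson_log_likelihood(n_test, r)
        r0 = np.full(test.sum(), np.exp(fit.mean_log_rate))
        table[()][f] = poisson_log_likelihood(n_test, r0)
    return CrossvalTable(table, flags)


def _signed_rank_greater(a: np.ndarray, b: np.ndarray, alpha: float) -> bool:
    """One-sided paired test: is ``a`` significantly greater than ``b``?"""
    d = np.asarray(a) - np.asarray(b)
    if np.allclose(d, 0.0):
        return False
    p = wilcoxon(d, alternative="greater", zero_method="zsplit").pvalue
    return bool(p < alpha)


def forward_select(table: CrossvalTable, alpha: float = 0.05):
    """Forward model selection over the cross-validated likelihood table.

    The best model of each size (by mean held-out likelihood) enters a
    ladder of one-sided Wilcoxon signed-rank tests across folds; a larger
    model is kept only while significantly better. The final model must in
    turn significantly beat the mean-rate-only model, otherwise the cell
    is ``"unclassified"``.
    """
    by_size = {}
    for s in table.subsets():
        by_size.setdefault(len(s), []).append(s)
    # ties in mean ll break toward the earlier (fixed-order) enumeration
    best = {k: max(v, key=lambda s: (np.mean(table.test_ll[s]),)) for k, v in by_size.items()}
    current = best[1]
    for size in range(2, max(by_size) + 1):
        cand = best[size]
        if _signed_rank_greater(table.test_ll[cand], table.test_ll[current], alpha):
            current = cand
        else:
            break
    if _signed_rank_greater(table.test_ll[current], table.test_ll[()], alpha):
        return current
    return "unclassified"


# ---------------------------------------------------------------------------
# shuffling and classification

def shuffle_spike_train(spike_times: np.ndarray, session_len: float,
                        rng, min_shift: float = 30.0) -> np.ndarray:
    """Circularly time-shift a spike train by at least ``min_shift`` seconds.

    The shift is uniform on [min_shift, session_len - min_shift]; spike
    times past the session end wrap to the beginning. Preserves the spike
    count and (up to the single wrap break) the inter-spike structure.
    """
    if session_len <= 2 * min_shift:
        raise ValueError("session too short to shuffle")
    shift = rng.uniform(min_shift, session_len - min_shift)
    return np.sort(np.mod(np.asarray(spike_times) + shift, session_len))


def shuffle_mvl_null(angle_per_frame: np.ndarray, spike_times: np.ndarray,
                     session_len: float, n_shuffles: int, rng,
                     valid: np.ndarray | None = None,
                     n_bins: int = 30) -> np.ndarray:
    """MVL of the shuffled-spike tuning curve, per shuffle."""
    out = np.empty(n_shuffles)
    n_frames = int(round(session_len / DT))
    for i in range(n_shuffles):
        shifted = shuffle_spike_train(spike_times, session_len, rng)
        counts = SpikeTrain(shifted).binned_counts(n_frames)
        curve = angular_tuning_curve(angle_per_frame, counts, n_bins=n_bins,
                                     valid=valid)
        out[i] = curve.mvl
    return out


@dataclass
class CellClassification:
    """Final per-cell classification and the evidence behind it."""

    selected: tuple | str
    is_eb: bool
    is_hd: bool
    bearing_mvl: float
    bearing_mvl_threshold: float
    bearing_peak_hz: float
    hd_mvl: float
    hd_mvl_threshold: float
    hd_pfd: float
    crossval: CrossvalTable | None = None


def classify_cell(session: Session, cell: str,
                  config: GLMConfig = GLMConfig(),
                  seed: int = 0,
                  covariates: Covariates | None = None,
                  binned: BinnedCovariates | None = None) -> CellClassification:
    """Run the full classification pipeline for one cell.

    An egocentric-bearing (EB) cell must (i) be GLM-selected for center
    bearing, (ii) have a bearing-curve MVL above the larger of the 99th
    shuffle percentile and 0.10, and (iii) a bearing-curve peak above
    1 Hz. An HD cell must be GLM-selected for head direction with MVL
    above the larger of the 99th shuffle percentile and 0.15.
    """
    cov = covariates if covariates is not None else compute_covariates(session)
    bnd = binned if binned is not None else bin_covariates(cov)
    st = session.cells[cell]
    n_all = st.binned_counts(session.n_frames)
    n = n_all[bnd.valid]
    table = crossval_models(bnd, n, config)
    selected = forward_select(table, config.alpha)
    sel_set = selected if isinstance(selected, tuple) else ()

    bearing_curve = angular_tuning_curve(cov.center_bearing, n_all,
                                         valid=cov.valid)
    hd_curve = angular_tuning_curve(cov.hd, n_all, valid=cov.valid)
    rng = np.random.default_rng(seed)
    null_b = shuffle_mvl_null(cov.center_bearing, st.spike_times,
                              session.duration, config.n_shuffles, rng,
                              valid=cov.valid)
    null_h = shuffle_mvl_null(cov.hd, st.spike_times, session.duration,
                              config.n_shuffles, rng, valid=cov.valid)
    thr_b = max(float(np.percentile(null_b, config.shuffle_percentile)),
                config.mvl_floor_eb)
    thr_h = max(float(np.percentile(null_h, config.shuffle_percentile)),
                config.mvl_floor_hd)
    is_eb = ("center_bearing" in sel_set and bearing_curve.mvl > thr_b
             and bearing_curve.peak_rate > config.peak_rate_floor_hz)
    is_hd = "hd" in sel_set and hd_curve.mvl > thr_h
    return CellClassification(selected, bool(is_eb), bool(is_hd),
                              bearing_curve.mvl, thr_b, bearing_curve.peak_rate,
                              hd_curve.mvl, thr_h, hd_curve.pfd, table)
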