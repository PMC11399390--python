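"""Directional tuning curves, bidirectionality, von Mises fits, waveforms.

Covers the head-direction side of the analysis: occupancy-normalized
angular tuning curves with mean vector length (MVL) and preferred firing
direction (PFD), the angle-doubling bidirectionality index used for the
cue-duplication experiment, upright/inverted and bidirectional von Mises
curve fits, the per-cue modulation indices derived from those fits, and
spline-based extracellular waveform width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

from .session import DT, wrap_deg, ang_diff_deg

__all__ = [
    "TuningCurve", "VonMisesFit", "angular_tuning_curve",
    "bidirectionality_index", "bidirectionality_from_frames",
    "fit_von_mises", "fit_bidirectional_von_mises", "classify_peak_trough",
    "modulation_indices", "waveform_width",
]

N_BINS_TUNING = 30    # 12-degree bins


@dataclass
class TuningCurve:
    """Occupancy-normalized angular tuning curve (12-degree bins)."""

    bin_centers: np.ndarray      # deg
    rate: np.ndarray             # Hz; NaN where occupancy is zero
    occupancy: np.ndarray        # s per bin
    mvl: float
    pfd: float                   # mean angle of the rate-weighted resultant, deg

    @property
    def peak_rate(self) -> float:
        return float(np.nanmax(self.rate)) if np.any(np.isfinite(self.rate)) else 0.0

    @property
    def peak_direction(self) -> float:
        return float(self.bin_centers[np.nanargmax(self.rate)])


def _resultant(rate: np.ndarray, centers_deg: np.ndarray):
    ok = np.isfinite(rate)
    total = np.sum(rate[ok])
    if total <= 0:
        return 0.0, 0.0
    z = np.sum(rate[ok] * np.exp(1j * np.radians(centers_deg[ok]))) / total
    return float(np.abs(z)), float(wrap_deg(np.degrees(np.angle(z))))


def angular_tuning_curve(angle_per_frame: np.ndarray, counts_per_frame: np.ndarray,
                         n_bins: int = N_BINS_TUNING,
                         valid: np.ndarray | None = None) -> TuningCurve:
    """Bin spikes and occupancy by an angular covariate and normalize.

    ``rate = spike count / occupancy time`` per bin; bins never occupied
    are NaN and excluded from the MVL/PFD resultant.
    """
    ang = np.asarray(angle_per_frame, float)
    cnt = np.asarray(counts_per_frame, float)
    if valid is not None:
        keep = np.asarray(valid, bool) & np.isfinite(ang)
    else:
        keep = np.isfinite(ang)
    ang, cnt = ang[keep], cnt[keep]
    width = 360.0 / n_bins
    idx = np.minimum((wrap_deg(ang) / width).astype(int), n_bins - 1)
    occ = np.bincount(idx, minlength=n_bins) * DT
    spikes = np.bincount(idx, weights=cnt, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ > 0, spikes / np.where(occ > 0, occ, 1.0), np.nan)
    centers = (np.arange(n_bins) + 0.5) * width
    mvl, pfd = _resultant(rate, centers)
    return TuningCurve(centers, rate, occ, mvl, pfd)


# ---------------------------------------------------------------------------
# bidirectionality

def bidirectionality_from_frames(hd_per_frame: np.ndarray,
                                 counts_per_frame: np.ndarray,
                                 valid: np.ndarray | None = None,
                                 min_mvl_sum: float = 0.02) -> float:
    """Bidirectionality index from per-frame head direction and spikes.

    Two tuning curves are built — one from the actual HD, one after
    doubling all angles (which folds two opposite lobes onto one) — and
    contrasted: ``BI = (MVL_doubled - MVL_normal) / (MVL_doubled +
    MVL_normal)``. Returns NaN for untuned cells (MVL sum below
    ``min_mvl_sum``).
    """
    normal = angular_tuning_curve(hd_per_frame, counts_per_frame, valid=valid)
    doubled = angular_tuning_curve(wrap_deg(2.0 * np.asarray(hd_per_frame, float)),
                                   counts_per_frame, valid=valid)
    denom = doubled.mvl + normal.mvl
    if denom < min_mvl_sum:
        return float("nan")
    return (doubled.mvl - normal.mvl) / denom


def bidirectionality_index(session, cell: str,
                           covariates=None) -> float:
    """Bidirectionality index of one cell's HD tuning in a session."""
    from .session import compute_covariates
    cov = covariates if covariates is not None else compute_covariates(session)
    counts = session.cells[cell].binned_counts(session.n_frames)
    return bidirectionality_from_frames(cov.hd, counts, valid=cov.valid)


# ---------------------------------------------------------------------------
# von Mises fits

@dataclass
class VonMisesFit:
    """Least-squares von Mises fit to a binned tuning curve.

    ``model(theta) = baseline + sum_k amp_k * exp(kappa (cos(theta - mu_k) - 1))``
    with one lobe (unidirectional) or two lobes exactly 180 degrees apart
    (bidirectional, shared kappa). Amplitudes are >= 0 for ``upright``
    fits and <= 0 for ``inverted`` (trough) fits.
    """

    orientation: str             # "upright" | "inverted"
    mu: float                    # deg
    kappa: float
    amplitudes: tuple            # one or two amplitudes, Hz
    baseline: float              # Hz
    r_squared: float
    bidirectional: bool = False

    def predict(self, theta_deg) -> np.ndarray:
        th = np.asarray(theta_deg, float)
        out = np.full(th.shape, self.baseline, dtype=float)
        for k, a in enumerate(self.amplitudes):
            mu = self.mu + 180.0 * k
            out = out + a * np.exp(self.kappa * (np.cos(np.radians(th - mu)) - 1.0))
        return out


def _fit_vm(curve: TuningCurve, orientation: str, bidirectional: bool) -> VonMisesFit:
    ok = np.isfinite(curve.rate)
    if ok.sum() < 5:
        raise ValueError("too few valid bins for a von Mises fit")
    th = curve.bin_centers[ok]
    y = curve.rate[ok]
    if np.ptp(y) == 0:
        raise ValueError("constant tuning curve")
    sign = 1.0 if orientation == "upright" else -1.0
    span = max(np.ptp(y), 1e-9)
    n_amp = 2 if bidirectional else 1

    def resid(p):
        b, mu, kappa = p[0], p[1], p[2]
        amps = p[3:3 + n_amp]
        pred = np.full_like(y, b)
        for k, a in enumerate(amps):
            pred = pred + sign * a * np.exp(kappa * (np.cos(np.radians(th - mu - 180.0 * k)) - 1.0))
        return pred - y

    lo = [-np.inf, -np.inf, 0.05] + [0.0] * n_amp
    hi = [np.inf, np.inf, 100.0] + [np.inf] * n_amp
    best = None
    for mu0 in np.arange(0.0, 360.0, 30.0):            # 12 multistarts
        p0 = [float(np.min(y) if sign > 0 else np.max(y)), mu0, 3.0] + [span] * n_amp
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("von Mises fit failed")
    ss_res = 2.0 * best.cost
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    b, mu, kappa = best.x[0], wrap_deg(best.x[1]), best.x[2]
    amps = tuple(float(sign * a) for a in best.x[3:3 + n_amp])
    return VonMisesFit(orientation, float(mu), float(kappa), amps, float(b),
                       float(r2), bidirectional)


def fit_von_mises(curve: TuningCurve, orientation: str = "upright") -> VonMisesFit:
    """Fit a single upright (peak) or inverted (trough) von Mises curve."""
    if orientation not in ("upright", "inverted"):
        raise ValueError("orientation must be 'upright' or 'inverted'")
    return _fit_vm(curve, orientation, bidirectional=False)


def fit_bidirectional_von_mises(curve: TuningCurve,
                                orientation: str = "upright") -> VonMisesFit:
    """Fit two von Mises lobes exactly 180 degrees apart (shared kappa)."""
    if orientation not in ("upright", "inverted"):
        raise ValueError("orientation must be 'upright' or 'inverted'")
    return _fit_vm(curve, orientation, bidirectional=True)


def faces_cue(direction_deg: float) -> bool:
    """Whether a maximal firing direction points toward the familiar cue.

    The cue card sits on the south wall, so directions in the open sector
    (180, 360) face it and directions in (0, 180) face away.
    """
    d = wrap_deg(direction_deg)
    return 180.0 < d < 360.0


def classify_peak_trough(curve: TuningCurve):
    """Compare upright vs. inverted von Mises fits.

    Returns ``(label, r2_upright - r2_inverted, fits)`` where label is
    ``"peak"`` when the upright fit wins.
    """
    up = fit_von_mises(curve, "upright")
    inv = fit_von_mises(curve, "inverted")
    diff = up.r_squared - inv.r_squared
    return ("peak" if diff >= 0 else "trough"), diff, (up, inv)


# ---------------------------------------------------------------------------
# cue modulation

def modulation_indices(fit: VonMisesFit, pfd_a1: float,
                       trough: bool = False) -> tuple[float, float]:
    """Per-cue modulation indices from a bidirectional von Mises fit.

    The fitted lobe closest to the cell's single-cue (A1) preferred
    direction is attributed to cue A, the opposite lobe to cue B. For
    peak cells ``MI = (lobe peak - curve min) / curve max``; for trough
    cells ``MI = (curve max - lobe trough) / curve max``.
    """
    if not fit.bidirectional:
        raise ValueError("need a bidirectional fit")
    grid = np.arange(0.0, 360.0, 1.0)
    vals = fit.predict(grid)
    vmax, vmin = float(vals.max()), float(vals.min())
    if vmax <= 0:
        return float("nan"), float("nan")
    lobes = np.array([fit.mu, wrap_deg(fit.mu + 180.0)])
    d = np.abs(ang_diff_deg(lobes, pfd_a1))
    a_lobe, b_lobe = (0, 1) if d[0] <= d[1] else (1, 0)
    out = []
    for lobe in (a_lobe, b_lobe):
        fr = float(fit.predict(lobes[lobe]))
        if trough:
            out.append((vmax - fr) / vmax)
        else:
            out.append((fr - vmin) / vmax)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# waveform width

WAVEFORM_FS_HZ = 32_000.0
UPSAMPLE = 100


def waveform_width(mean_waveform: np.ndarray,
                   fs_hz: float = WAVEFORM_FS_HZ) -> tuple[float, str]:
    """Peak-to-trough latency of a mean extracellular waveform.

    The 32-sample waveform is interpolated with a cubic spline at 100x
    resolution; the peak is the global maximum and the trough the global
    minimum occurring after it. Returns ``(latency_us, klass)`` with
    ``klass = "narrow"`` below 200 us, else ``"wide"``. Raises if no
    trough follows the peak.
    """
    wf = np.asarray(mean_waveform, float)
    s = np.arange(len(wf))
    fine = np.arange(0, len(wf) - 1 + 1e-12, 1.0 / UPSAMPLE)
    y = CubicSpline(s, wf)(fine)
    ipeak = int(np.argmax(y))
    after = y[ipeak:]
    if len(after) < 2 or np.all(np.diff(after) >= 0):
        raise ValueError("no trough after the waveform peak")
    itrough = ipeak + int(np.argmin(after))
    latency_us = (fine[itrough] - fine[ipeak]) / fs_hz * 1e6
    return float(latency_us), ("narrow" if latency_us < 200.0 else "wide")
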