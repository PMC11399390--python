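"""Synthetic foraging sessions with known ground-truth tuning.

The simulator produces everything a recorded session would provide — a
smooth foraging trajectory, Poisson spike trains driven by parametric
tuning to behavioral covariates, and mean extracellular waveforms — so
every analysis stage can be validated against known generative
parameters.

Trajectory model: the heading follows a correlated random walk (an
Ornstein-Uhlenbeck-style persistent turner with ~1 s relaxation), the
running speed an OU process around 15 cm/s, and proposed steps that would
leave the arena polygon are reflected off the nearest wall. Long sessions
(>= 15 min) cover more than 80% of 4-cm spatial bins, matching the
uniform-coverage criterion imposed on the real foraging behavior.

Tuning model: the firing rate is baseline + (peak - baseline) times a
product of class-specific kernels (von Mises for angular variables,
Gaussian for distance and speed, a Gaussian lattice for grid cells), and
spikes are drawn per 1/30 s frame from a Poisson distribution — the
multiplicative structure mirrors the exponential-sum GLM family used for
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .arena import ArenaGeometry
from .session import (DT, Covariates, Session, SpikeTrain, Trajectory,
                      compute_covariates, wrap_deg)

__all__ = [
    "CellSpec", "SyntheticSession", "simulate_trajectory", "generative_rate",
    "sample_spikes", "synth_waveform", "make_synthetic_session",
    "make_cue_experiment",
]

CELL_CLASSES = (
    "center_bearing", "center_distance", "wall_bearing_local",
    "wall_distance_local", "hd_unidirectional", "hd_bidirectional",
    "hd_trough", "grid", "speed", "conjunctive", "noise",
)

MEAN_SPEED_CM_S = 15.0
HEADING_RELAXATION_S = 1.0
HEAD_SCAN_SD_DEG = 25.0       # stationary sd of the lateral head-scan process
HEAD_SCAN_TAU_S = 1.5


@dataclass(frozen=True)
class CellSpec:
    """Generative tuning parameters for one synthetic cell.

    ``cell_class="noise"`` gives a constant-rate (untuned) Poisson cell at
    ``peak_rate``. ``conjunctive`` multiplies the kernels listed in
    ``components``. ``modulation_fraction`` is the relative amplitude of
    the second (180-degree-opposite) lobe of a bidirectional HD cell.
    """

    cell_class: str
    peak_rate: float = 10.0        # Hz
    baseline_rate: float = 0.5     # Hz
    pref_angle: float = 0.0        # deg, for angular kernels
    kappa: float = 4.0             # von Mises concentration
    pref_distance: float = 30.0    # cm
    distance_width: float = 15.0   # cm
    pref_speed: float = 20.0       # cm/s
    speed_width: float = 15.0      # cm/s
    grid_spacing: float = 40.0     # cm
    grid_orientation: float = 0.0  # deg
    grid_field_width: float | None = None   # cm sd; default 0.32 * spacing
    grid_phase: tuple = (0.0, 0.0)
    modulation_fraction: float = 1.0
    components: tuple = ()

    def __post_init__(self):
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if not (self.peak_rate > self.baseline_rate >= 0):
            raise ValueError("need peak rate > baseline >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not (0.0 <= self.modulation_fraction <= 1.0):
            raise ValueError("modulation fraction must lie in [0, 1]")


@dataclass
class SyntheticSession:
    """A simulated session plus its per-cell ground truth."""

    session: Session
    specs: dict = field(default_factory=dict)   # name -> CellSpec
    rates: dict = field(default_factory=dict)   # name -> per-frame Hz
    covariates: Covariates | None = None


# ---------------------------------------------------------------------------
# trajectory

def _random_interior_point(arena: ArenaGeometry, rng, margin: float = 5.0):
    lo = arena.wall_segments.reshape(-1, 2).min(axis=0) + margin
    hi = arena.wall_segments.reshape(-1, 2).max(axis=0) - margin
    for _ in range(1000):
        p = rng.uniform(lo, hi)
        if arena.contains(p[0], p[1]) and arena.wall_distances(p[0], p[1])[0].min() > margin:
            return p
    raise RuntimeError("could not place a start point inside the arena")


def _smooth_heading_circular(heading_deg: np.ndarray, win: int = 5) -> np.ndarray:
    rad = np.radians(heading_deg)
    c = np.convolve(np.pad(np.cos(rad), win // 2, mode="edge"), np.ones(win) / win, "valid")
    s = np.convolve(np.pad(np.sin(rad), win // 2, mode="edge"), np.ones(win) / win, "valid")
    return wrap_deg(np.degrees(np.arctan2(s, c)))


def simulate_trajectory(arena: ArenaGeometry, duration_s: float, seed: int) -> Trajectory:
    """Simulate a 30 Hz foraging path inside the arena.

    Head direction is the (smoothed) heading of motion plus a small
    independent jitter, mimicking the decoupling of head and body axes.
    """
    if duration_s < 60:
        raise ValueError("simulate at least 60 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / DT))
    x = np.empty(n)
    y = np.empty(n)
    heading = np.empty(n)

    # precomputed scalar geometry (fast inner loop)
    from matplotlib.path import Path as _Path
    poly = _Path(arena.polygon_vertices)
    seg_a = arena.wall_segments[:, 0, :]
    seg_ab = arena.wall_segments[:, 1, :] - seg_a
    seg_len2 = np.einsum("wd,wd->w", seg_ab, seg_ab)
    wall_ang = np.degrees(np.arctan2(seg_ab[:, 1], seg_ab[:, 0]))

    def _wall_dists(p):
        t = np.clip(((p - seg_a) * seg_ab).sum(axis=1) / seg_len2, 0.0, 1.0)
        near = seg_a + t[:, None] * seg_ab
        return np.hypot(*(p - near).T)

    def _ok(p, margin):
        return poly.contains_point(p, radius=1e-9) and _wall_dists(p).min() >= margin

    pos = _random_interior_point(arena, rng)
    h = rng.uniform(0.0, 360.0)
    v = MEAN_SPEED_CM_S
    sigma_h = 60.0 / np.sqrt(HEADING_RELAXATION_S)   # deg / sqrt(s)
    tau_v, sigma_v, v_max = 0.7, 14.0, 45.0
    sqdt = np.sqrt(DT)
    wall_margin = 1.0

    turn_noise = rng.standard_normal(n)
    speed_noise = rng.standard_normal(n)
    for i in range(n):
        x[i], y[i], heading[i] = pos[0], pos[1], h
        v += (MEAN_SPEED_CM_S - v) * DT / tau_v + sigma_v * sqdt * speed_noise[i]
        v = min(max(v, 0.0), v_max)
        h = (h + sigma_h * sqdt * turn_noise[i]) % 360.0
        hr = np.radians(h)
        nxt = pos + np.array([np.cos(hr), np.sin(hr)]) * (v * DT)
        if not _ok(nxt, wall_margin):
            # reflect heading off the nearest wall and add jitter
            wa = wall_ang[int(np.argmin(_wall_dists(pos)))]
            h = (2 * wa - h + rng.normal(0.0, 10.0)) % 360.0
            hr = np.radians(h)
            nxt = pos + np.array([np.cos(hr), np.sin(hr)]) * (v * DT)
            if not _ok(nxt, wall_margin):
                nxt = pos                      # stay put this frame
        pos = nxt

    # head direction = smoothed heading + slow lateral scanning + fast jitter;
    # rats swing the head about the movement axis, so HD is only loosely
    # coupled to the path direction
    scan = np.empty(n)
    scan[0] = rng.normal(0.0, HEAD_SCAN_SD_DEG)
    a = DT / HEAD_SCAN_TAU_S
    noise = rng.standard_normal(n) * HEAD_SCAN_SD_DEG * np.sqrt(2 * a)
    for i in range(1, n):
        scan[i] = scan[i - 1] * (1 - a) + noise[i]
    hd = wrap_deg(_smooth_heading_circular(heading) + scan
                  + rng.normal(0.0, 5.0, size=n))
    t = np.arange(n) * DT
    return Trajectory(t, x, y, hd)


# ---------------------------------------------------------------------------
# tuning kernels

def _vm_kernel(theta_deg, mu_deg, kappa):
    """von Mises bump normalized to a maximum of 1."""
    return np.exp(kappa * (np.cos(np.radians(theta_deg - mu_deg)) - 1.0))


def _gauss_kernel(v, mu, sigma):
    return np.exp(-0.5 * ((v - mu) / sigma) ** 2)


def _grid_kernel(x, y, spec: CellSpec):
    """Sum-of-Gaussians hexagonal lattice, max 1 at field centers."""
    spacing = spec.grid_spacing
    sd = spec.grid_field_width or 0.32 * spacing
    th = np.radians(spec.grid_orientation)
    b1 = spacing * np.array([np.cos(th), np.sin(th)])
    b2 = spacing * np.array([np.cos(th + np.pi / 3), np.sin(th + np.pi / 3)])
    lo = min(x.min(), y.min()) - spacing
    hi = max(x.max(), y.max()) + spacing
    m = int(np.ceil((hi - lo) / spacing)) + 2
    ij = np.mgrid[-m:m + 1, -m:m + 1].reshape(2, -1).T
    centers = ij @ np.stack([b1, b2]) + np.asarray(spec.grid_phase)
    keep = ((centers[:, 0] > lo) & (centers[:, 0] < hi)
            & (centers[:, 1] > lo) & (centers[:, 1] < hi))
    centers = centers[keep]
    d2 = (x[:, None] - centers[None, :, 0]) ** 2 + (y[:, None] - centers[None, :, 1]) ** 2
    return np.exp(-0.5 * d2 / sd ** 2).max(axis=1)


def _class_kernel(cls: str, spec: CellSpec, cov: Covariates, trajectory: Trajectory | None):
    if cls == "center_bearing":
        k = _vm_kernel(cov.center_bearing, spec.pref_angle, spec.kappa)
        return np.nan_to_num(k, nan=0.0)
    if cls == "center_distance":
        return _gauss_kernel(cov.center_distance, spec.pref_distance, spec.distance_width)
    if cls == "wall_bearing_local":
        return _vm_kernel(cov.wall_bearing[:, 0], spec.pref_angle, spec.kappa)
    if cls == "wall_distance_local":
        return _gauss_kernel(cov.wall_distance[:, 0], spec.pref_distance,
                             spec.distance_width)
    if cls == "hd_unidirectional":
        return _vm_kernel(cov.hd, spec.pref_angle, spec.kappa)
    if cls == "hd_bidirectional":
        k = (_vm_kernel(cov.hd, spec.pref_angle, spec.kappa)
             + spec.modulation_fraction
             * _vm_kernel(cov.hd, spec.pref_angle + 180.0, spec.kappa))
        return np.minimum(k, 1.0)
    if cls == "speed":
        return _gauss_kernel(cov.speed, spec.pref_speed, spec.speed_width)
    if cls == "grid":
        if trajectory is None:
            raise ValueError("grid kernel needs the trajectory for position")
        return _grid_kernel(trajectory.x, trajectory.y, spec)
    raise ValueError(f"no kernel for class {cls!r}")


def generative_rate(spec: CellSpec, cov: Covariates,
                    trajectory: Trajectory | None = None) -> np.ndarray:
    """Per-frame generative firing rate (Hz) for a cell spec.

    Multiplicative combination: baseline + (peak - baseline) * product of
    kernels. Trough HD cells dip from the peak toward the baseline at the
    preferred angle instead. Rates are floored at zero.
    """
    if spec.cell_class == "noise":
        rate = np.full(len(cov), spec.peak_rate)
    elif spec.cell_class == "hd_trough":
        rate = spec.peak_rate - (spec.peak_rate - spec.baseline_rate) * _vm_kernel(
            cov.hd, spec.pref_angle, spec.kappa)
    else:
        classes = spec.components if spec.cell_class == "conjunctive" else (spec.cell_class,)
        if not classes:
            raise ValueError("conjunctive cell needs components")
        kernel = np.ones(len(cov))
        for cls in classes:
            kernel = kernel * _class_kernel(cls, spec, cov, trajectory)
        rate = spec.baseline_rate + (spec.peak_rate - spec.baseline_rate) * kernel
    return np.clip(rate, 0.0, None)


def sample_spikes(rate_hz: np.ndarray, seed, dt: float = DT) -> SpikeTrain:
    """Draw a Poisson spike train from a per-frame rate vector.

    Counts per frame are Poisson(rate * dt); spike times are placed
    uniformly within their frame.
    """
    rng = np.random.default_rng(seed)
    rate_hz = np.asarray(rate_hz, float)
    if not np.all(np.isfinite(rate_hz)) or np.any(rate_hz < 0):
        raise ValueError("rate must be finite and non-negative")
    counts = rng.poisson(rate_hz * dt)
    frames = np.repeat(np.arange(len(rate_hz)), counts)
    times = (frames + rng.uniform(size=len(frames))) * dt
    return SpikeTrain(times)


# ---------------------------------------------------------------------------
# waveforms

WAVEFORM_FS_HZ = 32_000.0
WAVEFORM_N_SAMPLES = 32
_PEAK_SAMPLE = 10


def synth_waveform(width_class: str, seed: int,
                   latency_us: float | None = None,
                   noise_sd: float = 0.01):
    """Synthesize a 32-sample (1 ms at 32 kHz) mean extracellular waveform.

    A biphasic Gaussian template with the positive peak at sample 10 and
    the trough ``latency`` later. Defaults: 156.25 us (5 samples) for
    ``narrow``, 250 us (8 samples) for ``wide``. Returns
    ``(waveform, true_latency_us)``.
    """
    if width_class not in ("narrow", "wide"):
        raise ValueError("width_class must be 'narrow' or 'wide'")
    if latency_us is None:
        latency_us = 156.25 if width_class == "narrow" else 250.0
    lag_samples = latency_us * WAVEFORM_FS_HZ / 1e6
    rng = np.random.default_rng(seed)
    s = np.arange(WAVEFORM_N_SAMPLES, dtype=float)
    wf = (np.exp(-0.5 * ((s - _PEAK_SAMPLE) / 1.1) ** 2)
          - 0.8 * np.exp(-0.5 * ((s - _PEAK_SAMPLE - lag_samples) / 1.2) ** 2))
    if noise_sd > 0:
        wf = wf + rng.normal(0.0, noise_sd, size=len(wf))
    return wf, latency_us


# ---------------------------------------------------------------------------
# whole-session assembly

def make_synthetic_session(arena: ArenaGeometry, duration_s: float,
                           cell_specs: dict, seed: int,
                           label: str = "",
                           trajectory: Trajectory | None = None) -> SyntheticSession:
    """Simulate a full session for a roster of cell specs.

    An existing trajectory may be supplied (e.g. to share behavior across
    cell rosters); otherwise one is simulated from the seed.
    """
    ss = np.random.SeedSequence(seed)
    traj_seed, *cell_seeds = ss.spawn(1 + len(cell_specs))
    if trajectory is None:
        trajectory = simulate_trajectory(arena, duration_s, traj_seed)
    session = Session(arena, trajectory, {}, label=label)
    cov = compute_covariates(session)
    out = SyntheticSession(session, {}, {}, covariates=cov)
    for (name, spec), cseed in zip(cell_specs.items(), cell_seeds):
        rate = generative_rate(spec, cov, trajectory)
        session.cells[name] = sample_spikes(rate, cseed)
        out.specs[name] = spec
        out.rates[name] = rate
    return out


CUE_RESIDUAL_FRACTION = 0.2


def make_cue_experiment(hd_specs: dict, seed: int,
                        duration_s: float = 1200.0,
                        modulation_fraction: float = 0.5) -> dict:
    """Simulate the three-session cue-duplication experiment (A1, AB, A2).

    The duplicated visual cue is emulated by re-parameterizing HD tuning:
    unidirectional in A1, bidirectional with the stated second-lobe
    fraction in AB, and weakly bidirectional (residual fraction 0.2 of the
    AB modulation) in A2. Each session gets an independent trajectory.
    """
    from .arena import square_arena
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(3)
    out = {}
    fractions = {"A1": 0.0, "AB": modulation_fraction,
                 "A2": CUE_RESIDUAL_FRACTION * modulation_fraction}
    for (lbl, frac), sseed in zip(fractions.items(), seeds):
        specs = {}
        for name, spec in hd_specs.items():
            if frac == 0.0:
                specs[name] = replace(spec, cell_class="hd_unidirectional")
            else:
                specs[name] = replace(spec, cell_class="hd_bidirectional",
                                      modulation_fraction=frac)
        arena = square_arena(cue_b=(lbl == "AB"))
        out[lbl] = make_synthetic_session(arena, duration_s, specs,
                                          int(sseed.generate_state(1)[0] % (2**31)),
                                          label=lbl)
    return out
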