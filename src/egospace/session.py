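"""Session containers and behavioral covariates.

A session couples an arena, a 30 Hz tracking trajectory (position + head
direction) and one or more spike trains. From the trajectory we derive the
behavioral covariates the encoding models consume: allocentric head
direction, egocentric bearing and distance of the arena centroid,
egocentric bearing and distance of the nearest point on each of the two
closest walls, and linear speed.

Angle convention: degrees, East = 0, counterclockwise positive, wrapped to
[0, 360). An egocentric bearing of 0 means the reference is dead ahead and
90 means it is to the animal's left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arena import ArenaGeometry

FRAME_RATE_HZ = 30.0
DT = 1.0 / FRAME_RATE_HZ

# binning used by the classification GLM
N_BINS_ANGULAR = 30   # head direction, bearings
N_BINS_LINEAR = 10    # distances, speed

__all__ = [
    "Trajectory", "SpikeTrain", "Session", "Covariates", "BinnedCovariates",
    "compute_center_bearing", "compute_center_distance", "compute_wall_features",
    "compute_speed", "compute_covariates", "bin_covariates",
    "wrap_deg", "ang_diff_deg", "FRAME_RATE_HZ", "DT",
]


def wrap_deg(a):
    """Wrap angles (deg) into [0, 360)."""
    r = np.mod(a, 360.0)
    # np.mod(-eps, 360) can round to exactly 360.0
    return np.where(r >= 360.0, 0.0, r) if np.ndim(r) else (0.0 if r >= 360.0 else r)


def ang_diff_deg(a, b):
    """Signed circular difference a - b in (-180, 180]."""
    d = np.mod(np.asarray(a, float) - np.asarray(b, float), 360.0)
    return np.where(d > 180.0, d - 360.0, d)


@dataclass
class Trajectory:
    """30 Hz tracking: time (s), position (cm) and head direction (deg)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hd: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.hd = wrap_deg(np.asarray(self.hd, float))
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.hd) == n):
            raise ValueError("trajectory fields have unequal lengths")
        if n >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, DT, atol=1e-4):
                raise ValueError("trajectory is not uniformly sampled at 30 Hz")
        if not np.all(np.isfinite(self.hd)):
            raise ValueError("head direction contains non-finite values")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return len(self) * DT


@dataclass
class SpikeTrain:
    """Sorted spike times (s) for one cell."""

    spike_times: np.ndarray

    def __post_init__(self):
        st = np.sort(np.asarray(self.spike_times, float).ravel())
        self.spike_times = st

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    def binned_counts(self, n_frames: int) -> np.ndarray:
        """Spikes per video frame; spikes at/after the session end are dropped."""
        idx = np.floor(self.spike_times / DT).astype(int)
        idx = idx[(idx >= 0) & (idx < n_frames)]
        return np.bincount(idx, minlength=n_frames)


@dataclass
class Session:
    """One recording session: arena + trajectory + spike trains."""

    arena: ArenaGeometry
    trajectory: Trajectory
    cells: dict = field(default_factory=dict)   # name -> SpikeTrain
    label: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.trajectory)

    @property
    def duration(self) -> float:
        return self.trajectory.duration


# ---------------------------------------------------------------------------
# covariates

CENTROID_EXCLUSION_CM = 0.1


def compute_center_bearing(trajectory: Trajectory, arena: ArenaGeometry) -> np.ndarray:
    """Egocentric bearing of the arena centroid, deg in [0, 360).

    Frames where the animal sits on the centroid (closer than 0.1 cm) have
    no defined bearing and are returned as NaN.
    """
    dx = arena.centroid[0] - trajectory.x
    dy = arena.centroid[1] - trajectory.y
    allo = np.degrees(np.arctan2(dy, dx))
    bearing = wrap_deg(allo - trajectory.hd)
    bearing[np.hypot(dx, dy) < CENTROID_EXCLUSION_CM] = np.nan
    return bearing


def compute_center_distance(trajectory: Trajectory, arena: ArenaGeometry) -> np.ndarray:
    """Euclidean distance (cm) from the animal to the arena centroid."""
    return np.hypot(arena.centroid[0] - trajectory.x, arena.centroid[1] - trajectory.y)


def compute_wall_features(trajectory: Trajectory, arena: ArenaGeometry, k: int = 2):
    """Bearing and distance of the k closest walls, per frame.

    Walls are ranked by the distance from the animal to the nearest point on
    each wall segment; ties are broken by the arena's fixed wall order. For
    each rank the egocentric bearing of that nearest point is returned.

    Returns
    -------
    bearing, distance : arrays of shape (n_frames, k), deg and cm.
    """
    if k > arena.n_walls:
        raise ValueError(f"arena has {arena.n_walls} walls, cannot rank {k}")
    dist, nearest = arena.wall_distances(trajectory.x, trajectory.y)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]   # stable -> fixed-order ties
    rows = np.arange(len(dist))[:, None]
    d_k = dist[rows, order]
    near_k = nearest[rows, order]                            # (N, k, 2)
    dx = near_k[..., 0] - trajectory.x[:, None]
    dy = near_k[..., 1] - trajectory.y[:, None]
    bearing = wrap_deg(np.degrees(np.arctan2(dy, dx)) - trajectory.hd[:, None])
    return bearing, d_k


def compute_speed(trajectory: Trajectory, smooth: bool = False) -> np.ndarray:
    """Linear speed (cm/s) by forward difference; first frame copies the second.

    ``smooth=True`` applies a 5-frame boxcar after differencing.
    """
    if len(trajectory) < 2:
        raise ValueError("need at least 2 frames for speed")
    disp = np.hypot(np.diff(trajectory.x), np.diff(trajectory.y))
    speed = np.empty(len(trajectory))
    speed[1:] = disp / DT
    speed[0] = speed[1]
    if smooth:
        kernel = np.ones(5) / 5.0
        pad = np.pad(speed, 2, mode="edge")
        speed = np.convolve(pad, kernel, mode="valid")
    return speed


@dataclass
class Covariates:
    """Per-frame behavioral state consumed by the encoding models.

    ``valid`` marks frames usable for model fitting (inside the arena, off
    the centroid); invalid frames are excluded listwise downstream.
    """

    hd: np.ndarray
    center_bearing: np.ndarray
    center_distance: np.ndarray
    wall_bearing: np.ndarray      # (n_frames, 2)
    wall_distance: np.ndarray     # (n_frames, 2)
    speed: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.hd)


def compute_covariates(session: Session, speed_smooth: bool = False) -> Covariates:
    """Derive all behavioral covariates for a session."""
    traj, arena = session.trajectory, session.arena
    cb = compute_center_bearing(traj, arena)
    cd = compute_center_distance(traj, arena)
    wb, wd = compute_wall_features(traj, arena, k=2)
    sp = compute_speed(traj, smooth=speed_smooth)
    valid = arena.contains(traj.x, traj.y) & np.isfinite(cb)
    return Covariates(traj.hd.copy(), cb, cd, wb, wd, sp, valid)


# ---------------------------------------------------------------------------
# binning

GLM_VARIABLES = ("hd", "center_bearing", "center_distance", "speed")


def _angular_bin(a: np.ndarray, n_bins: int) -> np.ndarray:
    return np.minimum((wrap_deg(a) / (360.0 / n_bins)).astype(int), n_bins - 1)


def _linear_bin(v: np.ndarray, n_bins: int, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        hi = lo + 1e-9
    idx = ((v - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


@dataclass
class BinnedCovariates:
    """Bin indices per frame for each GLM variable, restricted to valid frames.

    ``bin_idx[var]`` maps each retained frame to one bin (the one-hot design
    matrix in index form); ``n_bins[var]`` gives the column count and
    ``circular[var]`` whether adjacency wraps.
    """

    bin_idx: dict
    n_bins: dict
    circular: dict
    valid: np.ndarray             # mask into the original frame axis
    edges: dict                   # (lo, hi) for linear variables

    def __len__(self) -> int:
        return len(next(iter(self.bin_idx.values())))


def bin_covariates(cov: Covariates,
                   n_angular: int = N_BINS_ANGULAR,
                   n_linear: int = N_BINS_LINEAR) -> BinnedCovariates:
    """Discretize covariates for the classification GLM.

    30 bins for head direction and center bearing, 10 for center distance
    and speed; distance/speed bin edges span the observed (valid-frame)
    range. Invalid frames are dropped jointly from all variables.
    """
    m = cov.valid
    if not m.any():
        raise ValueError("no valid frames to bin")
    idx, nb, circ, edges = {}, {}, {}, {}
    idx["hd"] = _angular_bin(cov.hd[m], n_angular)
    idx["center_bearing"] = _angular_bin(cov.center_bearing[m], n_angular)
    for name, vals in (("center_distance", cov.center_distance[m]),
                       ("speed", cov.speed[m])):
        lo, hi = float(vals.min()), float(vals.max())
        idx[name] = _linear_bin(vals, n_linear, lo, hi)
        edges[name] = (lo, hi)
    for name in ("hd", "center_bearing"):
        nb[name], circ[name] = n_angular, True
    for name in ("center_distance", "speed"):
        nb[name], circ[name] = n_linear, False
    return BinnedCovariates(idx, nb, circ, m.copy(), edges)
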