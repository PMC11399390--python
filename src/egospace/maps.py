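"""Occupancy-normalized rate maps, inserted-wall firing change, grid scores.

Rate maps use 4 x 4 cm spatial bins over the arena bounding box, mask
bins occupied for less than 100 ms, and apply mask-aware Gaussian
smoothing (sigma = 1.5 bins). The inserted-wall analysis contrasts
range-normalized square vs. L-shape maps near (< 20 cm) and far from the
inserted walls. Grid scoring follows the standard rotational-correlation
recipe on the 2-D spatial autocorrelogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter

from .arena import ArenaGeometry
from .session import DT, Session

__all__ = [
    "RateMap", "GridScoreResult", "occupancy_ratemap", "smooth_masked",
    "wall_proximity_change", "spatial_autocorr_2d", "grid_score",
    "BIN_CM", "SMOOTH_SIGMA_BINS", "OCC_MIN_S",
]

BIN_CM = 4.0
SMOOTH_SIGMA_BINS = 1.5
OCC_MIN_S = 0.1
GRID_SCORE_THRESHOLD = 0.4


@dataclass
class RateMap:
    """Occupancy-normalized spatial firing rate map."""

    rate: np.ndarray          # smoothed Hz, NaN outside mask; shape (ny, nx)
    raw_rate: np.ndarray      # unsmoothed Hz, NaN outside mask
    occupancy: np.ndarray     # s per bin
    mask: np.ndarray          # bins with >= 100 ms occupancy
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def bin_centers(self):
        cx = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        cy = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        return cx, cy


def smooth_masked(values: np.ndarray, mask: np.ndarray,
                  sigma: float = SMOOTH_SIGMA_BINS) -> np.ndarray:
    """Gaussian smoothing that renormalizes the kernel over valid bins."""
    v = np.where(mask, values, 0.0)
    num = gaussian_filter(v, sigma, mode="constant")
    den = gaussian_filter(mask.astype(float), sigma, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(mask & (den > 0), num / np.where(den > 0, den, 1.0), np.nan)
    return out


def _arena_edges(arena: ArenaGeometry, bin_cm: float):
    pts = arena.wall_segments.reshape(-1, 2)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    nx = int(np.ceil((hi[0] - lo[0]) / bin_cm))
    ny = int(np.ceil((hi[1] - lo[1]) / bin_cm))
    return (np.linspace(lo[0], lo[0] + nx * bin_cm, nx + 1),
            np.linspace(lo[1], lo[1] + ny * bin_cm, ny + 1))


def occupancy_ratemap(session: Session, cell: str,
                      counts: np.ndarray | None = None,
                      frame_mask: np.ndarray | None = None,
                      bin_cm: float = BIN_CM,
                      sigma_bins: float = SMOOTH_SIGMA_BINS,
                      occ_min_s: float = OCC_MIN_S) -> RateMap:
    """Build a smoothed, occupancy-normalized rate map for one cell.

    ``counts`` may supply precomputed per-frame spike counts (e.g. from a
    shuffled train); ``frame_mask`` restricts which frames contribute
    (used for HD-conditioned maps).
    """
    traj = session.trajectory
    if counts is None:
        counts = session.cells[cell].binned_counts(session.n_frames)
    xe, ye = _arena_edges(session.arena, bin_cm)
    if frame_mask is None:
        x, y, c = traj.x, traj.y, counts
    else:
        x, y, c = traj.x[frame_mask], traj.y[frame_mask], counts[frame_mask]
    occ = np.histogram2d(y, x, bins=(ye, xe))[0] * DT
    spk = np.histogram2d(y, x, bins=(ye, xe), weights=c.astype(float))[0]
    mask = occ >= occ_min_s
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(mask, spk / np.where(mask, occ, 1.0), np.nan)
    rate = smooth_masked(np.nan_to_num(raw), mask, sigma_bins)
    return RateMap(rate, raw, occ, mask, xe, ye)


# ---------------------------------------------------------------------------
# inserted-wall firing change

def _dist_to_segments(px, py, segments):
    a = segments[:, 0, :]
    ab = segments[:, 1, :] - a
    den = np.einsum("wd,wd->w", ab, ab)
    p = np.stack([px.ravel(), py.ravel()], axis=1)
    t = np.clip(np.einsum("nwd,wd->nw", p[:, None, :] - a, ab) / den, 0, 1)
    near = a + t[..., None] * ab
    return np.linalg.norm(p[:, None, :] - near, axis=-1).min(axis=1).reshape(px.shape)


def wall_proximity_change(map_square: RateMap, map_l: RateMap,
                          arena_l: ArenaGeometry,
                          near_cm: float = 20.0) -> tuple[float, float]:
    """Mean firing-rate change near vs. far from the inserted walls.

    Both maps are jointly range-normalized to [0, 1]; cells whose firing
    is highest in the center and lowest along the boundaries are inverted
    (value -> max - value) so that boundary-referenced change is measured
    on a common footing. The change ``L - square`` is then averaged over
    bins of the common valid region within ``near_cm`` of the inserted
    wall segments, and beyond it.
    """
    if not arena_l.inserted_wall_idx:
        raise ValueError("arena_l has no inserted walls")
    common = map_square.mask & map_l.mask
    if not common.any():
        return float("nan"), float("nan")
    a = map_square.rate.copy()
    b = map_l.rate.copy()
    both = np.concatenate([a[common], b[common]])
    lo, hi = np.nanmin(both), np.nanmax(both)
    if hi <= lo:
        a = np.zeros_like(a)
        b = np.zeros_like(b)
    else:
        a = (a - lo) / (hi - lo)
        b = (b - lo) / (hi - lo)

    cx, cy = map_l.bin_centers
    gx, gy = np.meshgrid(cx, cy)
    mean_map = 0.5 * (a + b)
    d_cen = np.hypot(gx - arena_l.centroid[0], gy - arena_l.centroid[1])
    d_wall = _dist_to_segments(gx, gy, arena_l.wall_segments)
    cen_zone = common & (d_cen <= near_cm)
    wall_zone = common & (d_wall <= near_cm)
    if cen_zone.any() and wall_zone.any() and \
            np.nanmean(mean_map[cen_zone]) > np.nanmean(mean_map[wall_zone]):
        a, b = 1.0 - a, 1.0 - b        # center-preferring cell: invert

    delta = b - a
    ins = arena_l.wall_segments[list(arena_l.inserted_wall_idx)]
    d_ins = _dist_to_segments(gx, gy, ins)
    near = common & (d_ins <= near_cm)
    far = common & (d_ins > near_cm)
    near_mean = float(np.nanmean(delta[near])) if near.any() else float("nan")
    far_mean = float(np.nanmean(delta[far])) if far.any() else float("nan")
    return near_mean, far_mean


# ---------------------------------------------------------------------------
# spatial autocorrelation and grid score

MIN_OVERLAP_BINS = 20


def spatial_autocorr_2d(rate_map: RateMap | np.ndarray,
                        mask: np.ndarray | None = None) -> np.ndarray:
    """Pearson 2-D spatial autocorrelogram over pairwise-valid bins.

    Accepts a RateMap or a plain (masked-with-NaN) array. Shifts with
    fewer than 20 overlapping valid bins are NaN. Output shape is
    ``(2*ny - 1, 2*nx - 1)`` with zero shift at the center.
    """
    if isinstance(rate_map, RateMap):
        vals = rate_map.rate
        msk = rate_map.mask
    else:
        vals = np.asarray(rate_map, float)
        msk = mask if mask is not None else np.isfinite(vals)
    v = np.where(msk, vals, np.nan)
    if np.nanstd(v) == 0:
        raise ValueError("constant rate map: autocorrelation undefined")
    ny, nx = v.shape
    out = np.full((2 * ny - 1, 2 * nx - 1), np.nan)
    for dy in range(-(ny - 1), ny):
        ya1, ya2 = max(0, dy), min(ny, ny + dy)
        yb1, yb2 = max(0, -dy), min(ny, ny - dy)
        for dx in range(-(nx - 1), nx):
            a = v[ya1:ya2, max(0, dx):min(nx, nx + dx)]
            b = v[yb1:yb2, max(0, -dx):min(nx, nx - dx)]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < MIN_OVERLAP_BINS:
                continue
            aa, bb = a[ok], b[ok]
            sa, sb = aa.std(), bb.std()
            if sa == 0 or sb == 0:
                continue
            out[dy + ny - 1, dx + nx - 1] = ((aa - aa.mean()) @ (bb - bb.mean())) / (len(aa) * sa * sb)
    return out


@dataclass
class GridScoreResult:
    """Grid score and the intermediate quantities used to compute it."""

    score: float
    is_grid: bool
    inner_radius_bins: float
    outer_radius_bins: float
    rotational_corr: np.ndarray = field(repr=False, default=None)   # offsets 0..180 step 3
    autocorrelogram: np.ndarray = field(repr=False, default=None)


def _radial_profile(ac: np.ndarray):
    ny, nx = ac.shape
    cy, cx = (ny - 1) // 2, (nx - 1) // 2
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - cy, xx - cx)
    rbin = r.astype(int)
    prof = np.full(rbin.max() + 1, np.nan)
    for k in range(len(prof)):
        sel = (rbin == k) & np.isfinite(ac)
        if sel.any():
            prof[k] = ac[sel].mean()
    return prof


def grid_score(ac: np.ndarray) -> GridScoreResult:
    """Grid score from a 2-D autocorrelogram.

    The inner annulus radius is the first local minimum of the radially
    averaged autocorrelogram beyond the central peak; the outer radius
    encloses the six peaks nearest the center plus one field radius
    (falling back to 1.25x the modal peak radius when fewer than six
    peaks are found). The annulus is resampled on a polar grid and
    correlated with rotated copies of itself at 3-degree offsets;
    ``score = min(r60, r120) - max(r30, r90, r150)``, grid if > 0.4.
    """
    ac = np.asarray(ac, float)
    ny, nx = ac.shape
    cy, cx = (ny - 1) // 2, (nx - 1) // 2
    prof = _radial_profile(ac)
    inner = None
    for k in range(1, len(prof) - 1):
        if np.isfinite(prof[k - 1:k + 2]).all() and prof[k] <= prof[k - 1] and prof[k] <= prof[k + 1]:
            inner = float(k)
            break
    if inner is None:
        return GridScoreResult(float("nan"), False, float("nan"), float("nan"),
                               None, ac)

    # local maxima outside the central field
    filled = np.nan_to_num(ac, nan=-1.0)
    peaks = (maximum_filter(filled, size=3) == filled) & (filled > 0.1)
    yy, xx = np.nonzero(peaks)
    rr = np.hypot(yy - cy, xx - cx)
    sel = rr > inner
    rr = np.sort(rr[sel])
    if len(rr) >= 6:
        outer = float(rr[:6].max() + inner)
    elif len(rr) >= 1:
        outer = float(1.25 * np.median(rr[:6]))
    else:
        outer = float(min(cy, cx) - 1)
    outer = min(outer, float(min(cy, cx)) - 1e-9)
    if outer <= inner + 1:
        outer = inner + 2.0

    # polar resampling of the annulus (bilinear, NaN treated as 0)
    filled0 = np.nan_to_num(ac, nan=0.0)
    angles = np.radians(np.arange(0, 360, 3))
    radii = np.linspace(inner, outer, 25)
    A, R = np.meshgrid(angles, radii, indexing="ij")
    px = cx + R * np.cos(A)
    py = cy + R * np.sin(A)
    from scipy.ndimage import map_coordinates
    ring = map_coordinates(filled0, [py.ravel(), px.ravel()], order=1).reshape(A.shape)

    flat = ring - ring.mean()
    denom = float(np.sqrt((flat ** 2).sum()))
    offsets = np.arange(0, 181, 3)
    rot = np.empty(len(offsets))
    for i, off in enumerate(offsets):
        shifted = np.roll(ring, off // 3, axis=0)
        sflat = shifted - shifted.mean()
        rot[i] = float((flat * sflat).sum()) / (denom * float(np.sqrt((sflat ** 2).sum())))
    at = {o: rot[i] for i, o in enumerate(offsets)}
    score = min(at[60], at[120]) - max(at[30], at[90], at[150])
    return GridScoreResult(float(score), bool(score > GRID_SCORE_THRESHOLD),
                           inner, outer, rot, ac)
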