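"""Arena geometry: wall polygons, centroids, and point/segment queries.

Two arena configurations are supported: a 120 x 120 cm square open field,
and the same box with two 60 cm walls inserted to block off one quadrant,
turning the navigable region into an L. Walls are the (ordered) edges of
the navigable polygon; in the L configuration the two inserted segments
are distinct walls appended after the four outer walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path

SIDE_CM = 120.0
QUADRANT_CM = 60.0

__all__ = ["ArenaGeometry", "square_arena", "l_arena", "SIDE_CM"]


@dataclass(frozen=True)
class ArenaGeometry:
    """Navigable polygon of an open-field arena.

    Parameters
    ----------
    shape_tag:
        ``"square"`` or ``"L"``.
    wall_segments:
        ``(n_walls, 2, 2)`` array of segment endpoints in cm, ordered
        south, east, north, west, then any inserted walls.
    centroid:
        Center of mass of the navigable region, cm.
    inserted_wall_idx:
        Indices into ``wall_segments`` of walls present only in the L
        configuration (empty for the square).
    cue_positions:
        Optional mapping of cue label -> (wall index, (start, stop) span
        in cm along that wall). Cue A sits on the south wall; cue B, when
        present, on the north wall.
    """

    shape_tag: str
    wall_segments: np.ndarray
    centroid: np.ndarray
    inserted_wall_idx: tuple[int, ...] = ()
    cue_positions: dict = field(default_factory=dict)

    def __post_init__(self):
        segs = np.asarray(self.wall_segments, dtype=float)
        if segs.ndim != 3 or segs.shape[1:] != (2, 2):
            raise ValueError("wall_segments must have shape (n, 2, 2)")
        object.__setattr__(self, "wall_segments", segs)
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        # closed-polygon check: each wall ends where the next begins
        ordered = self._boundary_order()
        if not np.allclose(ordered[:, 1, :], np.roll(ordered[:, 0, :], -1, axis=0)):
            raise ValueError("wall segments do not form a closed polygon")

    def _boundary_order(self) -> np.ndarray:
        """Walls reordered so consecutive segments share endpoints."""
        if self.shape_tag == "square":
            return self.wall_segments
        # L: south, east, inserted-1, inserted-2, north, west
        return self.wall_segments[[0, 1, 4, 5, 2, 3]]

    @property
    def polygon_vertices(self) -> np.ndarray:
        return self._boundary_order()[:, 0, :]

    @property
    def n_walls(self) -> int:
        return len(self.wall_segments)

    def contains(self, x, y, tol: float = 1e-9) -> np.ndarray:
        """Vectorized point-in-navigable-region test (boundary counts as inside)."""
        pts = np.column_stack([np.asarray(x, float).ravel(), np.asarray(y, float).ravel()])
        path = Path(self.polygon_vertices)
        inside = path.contains_points(pts, radius=2 * tol) | path.contains_points(pts, radius=-2 * tol)
        return inside.reshape(np.shape(x))

    def wall_distances(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Distance and nearest point on every wall for points (x, y).

        Returns ``(dist, nearest)`` with shapes ``(n_pts, n_walls)`` and
        ``(n_pts, n_walls, 2)``.
        """
        p = np.column_stack([np.asarray(x, float).ravel(), np.asarray(y, float).ravel()])
        a = self.wall_segments[:, 0, :]          # (W, 2)
        b = self.wall_segments[:, 1, :]
        ab = b - a                               # (W, 2)
        denom = np.einsum("wd,wd->w", ab, ab)
        ap = p[:, None, :] - a[None, :, :]       # (N, W, 2)
        t = np.einsum("nwd,wd->nw", ap, ab) / denom
        t = np.clip(t, 0.0, 1.0)
        nearest = a[None] + t[..., None] * ab[None]
        dist = np.linalg.norm(p[:, None, :] - nearest, axis=-1)
        return dist, nearest


def _cue_a() -> dict:
    # white cue card centered on the south wall
    return {"A": (0, (40.0, 80.0))}


def square_arena(cue_b: bool = False) -> ArenaGeometry:
    """The 120 x 120 cm square box.

    With ``cue_b=True`` the arena descriptor carries a duplicate cue card
    on the north wall (the two-cue condition); geometry is unchanged.
    """
    s = SIDE_CM
    walls = np.array([
        [[0, 0], [s, 0]],      # south
        [[s, 0], [s, s]],      # east
        [[s, s], [0, s]],      # north
        [[0, s], [0, 0]],      # west
    ], dtype=float)
    cues = _cue_a()
    if cue_b:
        cues["B"] = (2, (40.0, 80.0))
    return ArenaGeometry("square", walls, np.array([s / 2, s / 2]), (), cues)


def l_arena() -> ArenaGeometry:
    """The square with its northeast 60 x 60 cm quadrant walled off."""
    s, q = SIDE_CM, QUADRANT_CM
    walls = np.array([
        [[0, 0], [s, 0]],        # south
        [[s, 0], [s, q]],        # east (shortened)
        [[q, s], [0, s]],        # north (shortened)
        [[0, s], [0, 0]],        # west
        [[s, q], [q, q]],        # inserted-1 (horizontal)
        [[q, q], [q, s]],        # inserted-2 (vertical)
    ], dtype=float)
    # area-weighted centroid: full square minus the blocked quadrant
    a1, a2 = s * s, q * q
    c = (a1 * np.array([s / 2, s / 2]) - a2 * np.array([s - q / 2, s - q / 2])) / (a1 - a2)
    return ArenaGeometry("L", walls, c, (4, 5), _cue_a())
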