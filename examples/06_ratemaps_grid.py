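"""Rate maps, grid scores, and the inserted-wall firing-change control.

Simulates a grid cell and a boundary-referenced cell in the square and
L-shaped arenas, scores the grid cell's hexagonal periodicity from the
2-D spatial autocorrelogram, and measures the change in normalized
firing near (< 20 cm) vs. far from the inserted walls. Boundary cells
gain firing along the new walls; grid cells do not.
"""

import numpy as np

from egospace import (CellSpec, grid_score, l_arena, make_synthetic_session,
                      occupancy_ratemap, spatial_autocorr_2d, square_arena,
                      wall_proximity_change)

specs = {
    "grid": CellSpec("grid", peak_rate=15.0, baseline_rate=0.3,
                     grid_spacing=40.0, grid_phase=(10.0, 20.0)),
    "boundary": CellSpec("conjunctive",
                         components=("wall_bearing_local", "wall_distance_local"),
                         peak_rate=10.0, baseline_rate=0.5, pref_angle=0.0,
                         kappa=2.0, pref_distance=5.0, distance_width=10.0),
}
sq = make_synthetic_session(square_arena(), 900.0, specs, seed=8)
lsh = make_synthetic_session(l_arena(), 900.0, specs, seed=9)

rm = occupancy_ratemap(sq.session, "grid")
res = grid_score(spatial_autocorr_2d(rm))
print(f"grid cell: score {res.score:.2f} (threshold 0.4) -> "
      f"{'grid' if res.is_grid else 'not a grid'}; "
      f"annulus radii {res.inner_radius_bins:.0f}-{res.outer_radius_bins:.0f} bins")
print(f"peak firing rate in map: {np.nanmax(rm.rate):.1f} Hz")

for name in specs:
    near, far = wall_proximity_change(occupancy_ratemap(sq.session, name),
                                      occupancy_ratemap(lsh.session, name),
                                      lsh.session.arena)
    print(f"{name}: normalized rate change near inserted walls {near:+.3f}, "
          f"far {far:+.3f}")
print("(positive near-wall change with ~zero far change = gained firing "
      "along the inserted walls)")
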