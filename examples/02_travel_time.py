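"""Slope-corrected speeds and a travel-time surface on a toy landscape.

Shows the scenario speed model (walking everywhere; cycling on roads;
minibus on national/district roads), the slope corrections, and the
60-minute anisotropic travel-time surface around one facility.
"""

import numpy as np

from accessgrid import (Facility, Grid, effective_speed, speed_for,
                        travel_time_from)

print("speed model (class, scenario -> km/h, mode):")
for code, label in [(9, "cultivated land"), (14, "national road"),
                    (16, "rural/feeder road"), (11, "water")]:
    row = [speed_for(code, s) for s in (1, 2, 3)]
    print(f"  {label:18s} " + "  ".join(f"S{s}: {v:4.1f} {m or 'barrier':9s}"
                                        for s, (v, m) in zip((1, 2, 3), row)))

print("\nslope correction (walking on a road, base 5 km/h):")
for slope in (-0.10, -0.05, 0.0, 0.10, 0.25):
    v = effective_speed(14, 1, slope)
    print(f"  slope {slope:+.2f} -> {v:5.2f} km/h")

# a 21x21 flat grid of cultivated land with a facility in the middle
n = 21
lc = Grid(np.full((n, n), 9, dtype=np.int64), origin_y=n * 90.0,
          nodata=-1, kind="categorical")
dem = lc.like(np.zeros((n, n)), kind="continuous")
x, y = lc.cell_center(n // 2, n // 2)
facility = Facility("HC1", float(x), float(y), capacity=10_000,
                    row=n // 2, col=n // 2)
surface = travel_time_from([facility], lc, dem, scenario=1)

t = surface.minutes
print(f"\ntravel time on flat cultivated land (1.67 km/h walking):")
print(f"  facility cell: {t[n//2, n//2]:.2f} min")
print(f"  one cell east (90 m): {t[n//2, n//2 + 1]:.2f} min")
print(f"  reachable within 60 min: {int(surface.reachable_mask().sum())} "
      f"of {n * n} cells")
print("\nCells beyond the 60-minute cap are nodata: the one-hour access norm")
print("defines the outer limit of a facility's candidate catchment.")
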