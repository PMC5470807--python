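"""Where does the signal of a hemispherical tower observation come from?

Builds the per-ring contribution table of a cosine-corrected sensor and the
footprint summary for a 20 m mast: the zenith cone that bounds 90% of the
irradiance, its ground radius, and the share of the field of view a 5 m tower
body blocks.
"""

import numpy as np

import hemisif as hs

HEIGHT = 20.0  # sensor height above the canopy, m

centers, contrib = hs.ring_table(1.0)
peak = centers[np.argmax(contrib)]
print(f"peak ring contribution at {peak:.1f} deg "
      f"({100 * contrib.max():.2f}% of the signal per 1-deg ring)")

for limit in (30.0, 45.0, 60.0, 72.0, 85.0):
    s = hs.FootprintSummary.from_zenith_limit(HEIGHT, limit)
    print(f"zenith limit {limit:5.1f} deg -> fraction {s.cumulative_fraction:6.4f}, "
          f"ground radius {s.ground_radius:7.2f} m")

limit_90 = hs.zenith_for_fraction(0.90)
print(f"\n90% of the signal lies within {limit_90:.2f} deg "
      f"(radius {hs.ground_radius(HEIGHT, limit_90):.2f} m at H = {HEIGHT:.0f} m)")

block = hs.obstruction_angle(5.0, HEIGHT)
print(f"a 5 m tower projection blocks {block:.2f} deg, "
      f"{100 * block / 180:.1f}% of the 180-deg field of view")
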