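"""Overlap between spectral footprints and the eddy-covariance flux footprint.

Computes the 2-D FFP flux footprint (Kljun et al. 2015) for a convective,
light-wind case at a 20 m receptor and asks how much of the flux source
weight falls inside the tower-centred footprint circles of a hemispherical
(72-deg limit) and a conical (25-deg FOV) spectral observation.
"""

import hemisif as hs

r = hs.run_footprint_comparison(grid_step=1.0)
print(f"flux footprint peak at x = {r.peak_location[0]:.1f} m upwind")
print(f"hemispherical circle: radius {r.hemispherical_radius:.2f} m "
      f"(zenith limit {r.zenith_limit:.0f} deg, "
      f"{100 * r.captured_irradiance_fraction:.1f}% of the spectral signal)")
print(f"  -> contains {100 * r.hemispherical_fraction:.2f}% of the flux signal")
print(f"conical circle: radius {r.conical_radius:.2f} m")
print(f"  -> contains {100 * r.conical_fraction:.5f}% of the flux signal")

fp = hs.ffp_2d(hs.TOWER_FFP_PARAMS, grid_step=1.0)
at_peak = hs.fraction_within_radius(fp, r.conical_radius, center=fp.peak_location)
print(f"(the same conical circle centred on the footprint peak would hold "
      f"{100 * at_peak:.2f}%)")
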