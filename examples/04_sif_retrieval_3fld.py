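"""3FLD SIF retrieval from a synthetic scene, with and without correction.

Generates one directional canopy scene, propagates its upwelling radiance to
a 20 m sensor through the O2-A absorption, and retrieves SIF by the 3FLD
method from four versions of the spectrum: top of canopy, uncorrected
at-sensor, and at-sensor corrected with equivalent paths H and 2H.
"""

import numpy as np

import hemisif as hs

HEIGHT = 20.0
model = hs.TransmittanceModel.o2a_default()
bands = hs.ThreeBandSet()
scene = hs.generate_scene(hs.SceneParams(cab=40.0, lai=4.0, lidf="spherical"))

reference = hs.hemispherical_irradiance(scene.sif.at_wavelength(bands.lambda_in)) / np.pi
print(f"injected SIF (hemispheric mean at {bands.lambda_in} nm): "
      f"{reference:.4f} mW m-2 nm-1 sr-1")

I_b = hs.sample_bands(scene.wavelengths, scene.downwelling, bands)
variants = {}
for name, ratio in (("TOC", None), ("uncorrected", 0.0), ("corr H", 1.0), ("corr 2H", 2.0)):
    L_b = []
    for wl in (bands.lambda_left, bands.lambda_in, bands.lambda_right):
        field = scene.radiance.at_wavelength(wl)
        if name == "TOC":
            e = hs.hemispherical_irradiance(field)
        else:
            t = lambda th: model.transmittance(
                HEIGHT / np.cos(np.radians(np.asarray(th, float))), wl
            )
            e = hs.hemispherical_irradiance(field, t)
            if ratio:
                e = hs.correct_hemispherical_irradiance(e, HEIGHT, model, wl, ratio)
        L_b.append(e / np.pi)
    sif = hs.threefld(hs.RetrievalInput(*I_b, *L_b), bands)
    variants[name] = sif
    print(f"SIF {name:12s}: {sif:8.4f}   (error {sif - reference:+.4f})")

print("\nwithout correction the attenuated in-band radiance mimics *negative*")
print("fluorescence; a 2H equivalent path restores it to within a few percent")
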