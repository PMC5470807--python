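# Methods

`hemisif` models tower-based *hemispherical* (cosine-corrected) spectral
observations of solar-induced chlorophyll fluorescence (SIF) and their
relationship to eddy-covariance flux measurements. This note documents the
models, their assumptions, the defaults and the numerical choices.

## 1. Footprint geometry of a cosine-corrected sensor

A cosine-corrected foreoptic at height H collects irradiance

E(θmax) = ∫₀^{2π} ∫₀^{θmax} L(θ, φ) T↑(θ) cos θ sin θ dθ dφ.

For a homogeneous Lambertian surface and absorption-free bands this collapses
to π L T sin²(θmax): the **cumulative fraction** of the hemispherical signal
inside a zenith cone is sin²(θmax), the per-ring density cos θ sin θ peaks at
45°, and 90% of the signal arrives from within ≈72° (ground radius
H tan 72° ≈ 3.08 H). Everything in `hemisif.geometry` is closed-form; the
only convention to fix is that a "zenith limit" is the half-cone view zenith
angle (instrument spec sheets quoting a full-cone FOV are converted with
`half_cone_from_full_fov`). Assumptions: Lambertian, homogeneous target; no
terrain slope or sensor tilt.

## 2. Transmittance model

Upwelling path transmittance is monochromatic Beer–Lambert,
T(p, λ) = exp(−κ(λ) p), with p = H sec θ the slant path. The default O2-A
extinction is anchored so that an equivalent transmittance of 0.924
corresponds to an equivalent path of 37.7 m — κ(761.1 nm) =
−ln(0.924)/37.7 ≈ 2.097×10⁻³ m⁻¹, a representative calibration for
instrument heights of tens of metres. The spectral variant uses a Gaussian
extinction line (σ = 0.6 nm) centred at 761.1 nm, interpreted as the
*effective* band-averaged extinction at instrument resolution; continuum
bands a few nm away have κ ≈ 0 and are unaffected by path length.

Key property: over tower-scale paths (20–65 m) the exponential is nearly
straight (R² > 0.999 for the default κ), which is what licenses describing a
hemispherical observation by a single equivalent path. An absorption-free
(κ = 0) band yields a *degenerate* flat fit, reported as a flagged perfect
fit rather than an error so absorption-free pipelines run unchanged.

Surface–atmosphere coupling (spherical albedo S, path radiance L_path) is
carried explicitly in `SurfaceCoupling` so the full at-sensor relation
L_H = L₀ T/(1 − ρS) + L_path and its inverse are implemented, but both terms
default to zero: over a few tens of metres the scattering contribution of the
intervening layer is negligible against its absorption.

## 3. Equivalent radiance transfer path length (ERTPL)

The equivalent transmittance of a hemispherical observation is
T̄ = Ecos/E₀. Two idealisations give the closed form: if the surface is
isotropic, T̄ = 2∫ T(θ) cos θ sin θ dθ; if additionally T is *linear in
path*, the equivalent path is the cosine-weighted mean slant path

ERTPL = 2 ∫₀^{π/2} H sec θ cos θ sin θ dθ = 2H.

Numerically (`ertpl_from_fields`), T̄ is computed from the directional field
by quadrature and inverted through a straight-line fit of T against p
restricted to θ ≤ 72° (the cone carrying >90% of the signal, where the
T–p relation stays close to linear; fit sampling 1°).

Two real-world departures move the ratio away from 2 in *opposite*
directions:

* **transmittance curvature** — exp(−κp) is convex, so the
  irradiance-weighted mean transmittance corresponds to a path *shorter*
  than the mean path (isotropic default case: 1.91 H);
* **bowl anisotropy** — canopy radiance rising with view zenith angle gives
  extra weight to long slant paths and pushes the equivalent path back
  *up* toward (and, for extreme amplitudes or weak absorption, past) 2H.

With the default extinction and the generator's leaf-angle-dependent bowl
amplitudes the 80-scene grid spans ratios 1.94–2.00 (mean 1.97), and
correcting hemispherical irradiance with the modelled ratio 2.0 leaves
sub-percent residuals (0.18% RRMSE over the grid, vs 0.04% using each
scene's own fitted ratio).

### Quadrature

Field samples live at the centres of a (Δθ = 1°, Δφ = 10°) grid. Ring
integrals of T(θ) cos θ sin θ use 8-point Gauss–Legendre nodes *inside each
ring* rather than a midpoint value times an analytic weight. The distinction
matters at the horizon: for T linear in H sec θ the integrand is
a cos θ sin θ + bH sin θ — smooth up to 90° — so the GL scheme reproduces
the closed-form 2H identity to machine precision, needs no exclusion of
near-horizon rings, and evaluates Beer–Lambert transmittances (bounded by 1)
without ever touching the sec θ singularity. Without a transmittance factor
the exact per-ring weight sin²θhi − sin²θlo is used. An idealised *linear*
transmittance model inevitably extrapolates below zero near grazing angles;
the quadrature deliberately accepts such values (upper bound 1 is still
enforced) because clipping would break the exact 2H identity.

## 4. Flux footprint and overlap

The eddy-covariance footprint uses the two-dimensional FFP parameterisation
of Kljun, Calanca, Rotach & Schmid (2015, Geosci. Model Dev. 8, 3695–3713):
the crosswind-integrated footprint of their Eq. (14) with the fitted
constants of Eq. (17), the x ↔ X* scaling of Eqs. (5)–(9) (with the
log-profile term expressed as k u(zm)/u\*), and the Gaussian crosswind spread
of Eq. (18) with the stability factor of Eq. (19). The scaled tail is cut at
X* = 30 (>95% of the weight captured for the reference case); the stated
validity bound zm/L ≥ −15.5 is enforced. No wind direction enters: the
footprint is laid along +x, and all tower-centred circular overlap metrics
are rotation-invariant.

The default overlap metric is the **integrated footprint weight inside a
tower-centred circle** — the fraction of the flux signal that originates
inside the spectral footprint. Because the parameterised footprint density
vanishes at the receptor and peaks upwind (x_peak ≈ 15 m for the reference
convective light-wind case: zm = 20 m, L = −100 m, σv = 0.45 m s⁻¹,
u\* = 0.3 m s⁻¹, h = 2000 m, u(zm) = 0.74 m s⁻¹), a small conical-footprint
circle at the tower holds essentially none of the flux weight while the
61.55 m hemispherical circle holds roughly half of it. Peak-centred circles
and an area-overlap variant against a cumulative source-area contour
(`source_area_coverage`) are provided as alternative readings. Default grid:
1400 m square domain, 0.5–1 m cells; halving the cell size moves the
reference overlap fractions by well under half a percentage point.

## 5. 3FLD retrieval

SIF at the O2-A band is retrieved with the three-band Fraunhofer Line
Discrimination estimator, with shoulder weights inversely proportional to
each shoulder's spectral distance from the in-band wavelength and normalised
to sum to one (the estimator is invariant to the weights' common scale).
Default bands: 758.7 / 761.1 / 770.1 nm — shoulders chosen on the κ ≈ 0
continuum either side of the synthetic absorption feature. The estimator is
exactly unbiased when reflectance and SIF are spectrally flat (or linear,
since the distance-inverse weights interpolate linearly) across the bands.
Retrieval always operates on top-of-canopy-corrected spectra; atmospheric
correction is wired *before* the estimator rather than folded into it.

## 6. Synthetic scene generator

The generator emulates the statistical structure of coupled
canopy-radiative-transfer + atmospheric simulations, not their physics:

* **Spectral window** 755.1–773.1 nm, 0.15 nm sampling, 0.3 nm FWHM
  (critical sampling, and both retrieval shoulders on-grid).
* **Downwelling irradiance**: 1000 mW m⁻² nm⁻¹ continuum with a Gaussian
  absorption well (transmittance 0.35 at line centre for the total solar
  path) convolved to the instrument line shape. These are typical clear-sky
  values near 760 nm.
* **Continuum reflectance** ρ₀(Cab, LAI, LIDF) ∈ ~0.27–0.42: increases
  saturating with LAI, decreases weakly with Cab, small leaf-angle offset —
  realistic near-infrared canopy levels whose only job is to spread the 80
  conditions.
* **Bowl anisotropy** L(θ) ∝ 1 + a sin²θ shared by reflected radiance and
  SIF (fluorescence is known to mirror the directional behaviour of
  reflectance). Amplitudes per leaf-angle class: planophile 0.10,
  plagiophile 0.18, spherical 0.25, extremophile 0.30, erectophile 0.35 —
  ordered by the physical expectation that erect leaves show the strongest
  far-red bowl. Azimuthal variation (hot spot, principal-plane asymmetry)
  is *not* emulated.
* **SIF amplitude** monotone in LAI and Cab, 0.87–2.0 mW m⁻² nm⁻¹ sr⁻¹
  across the grid (≈1–2% of the continuum radiance), with a mild −0.4%/nm
  far-red slope.
* **Determinism**: generation is exact and bit-identical given the seed;
  optional multiplicative Gaussian noise sits behind the seed and defaults
  to off.
* **Condition grid**: 4 Cab × 4 LAI × 5 LIDF = 80 scenes at SZA 30°,
  sensor height 20 m, VZA 0–89° step 1°, RAA 0–360° step 10°.

What passing tests on these scenes show: the *processing chain* (propagate →
correct → retrieve) is consistent and the error hierarchy of correction
choices is as the theory predicts. What they cannot show: absolute retrieval
accuracy on real canopies, whose directional fields, line shapes and noise
differ from the emulation.

## 7. End-to-end evaluations

`run_footprint_comparison`, `run_ertpl_evaluation` and
`run_retrieval_comparison` wire the above into the three study designs. On
the 80-scene grid with the default calibration the four 3FLD variants score
(RRMSE against the injected SIF): top-of-canopy ≈ 0%, uncorrected 373%
(every value negative — the attenuated in-band radiance mimics negative
fluorescence), corrected with path H 187%, corrected with path 2H 8.6% with
a small *positive* mean bias (+0.12) — the 2H path slightly over-corrects
because the scenes' own equivalent paths sit just below 2H.

## 8. Known limitations

* Beer–Lambert with a single effective κ replaces a band model; no aerosol
  or water-vapour dependence, no AOD sensitivity.
* The FFP encoding reproduces the published parameterisation, not a
  Lagrangian simulation; overlap numbers inherit its assumptions
  (stationarity, horizontal homogeneity).
* The generator's bowl is zenith-only and its reflectance maps are
  statistical stand-ins; per-scene magnitudes are meaningful only relatively.
* Hemispherical retrieval uses Lambertian-equivalent radiance E/π; strongly
  non-Lambertian targets would bias any irradiance-based retrieval alike.
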