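"""Synthetic directional canopy scenes with an O2-A absorption window.

The generator emulates the *statistical structure* of coupled canopy
radiative-transfer and atmospheric simulations - not their internal physics:

* a downwelling top-of-canopy irradiance spectrum with a Gaussian O2-A
  absorption well at 761.1 nm, convolved to the instrument line shape
  (0.3 nm FWHM, 0.15 nm sampling);
* top-of-canopy upwelling radiance on a (view zenith, relative azimuth) grid
  (1 deg x 10 deg) with the far-red "bowl" anisotropy of vegetation
  canopies - radiance rising with view zenith angle as 1 + a sin^2(theta);
* a directional SIF component sharing the same bowl shape (fluorescence
  emission is known to mirror the directional behaviour of reflectance);
* a condition grid of 80 scenes: chlorophyll 20/40/60/80 ug cm-2 x LAI
  1/2/4/6 x five leaf inclination distributions, at a 30 deg solar zenith
  angle and a 20 m sensor height.

Continuum reflectance and SIF amplitude are smooth monotone maps of (Cab,
LAI, LIDF) spanning realistic near-infrared canopy values; the maps only need
to spread the 80 conditions plausibly, since all downstream statistics are
relative. The generator is deterministic given its seed; noise is off by
default and optional.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .atmosphere import TransmittanceModel
from .fields import AngularGrid, DirectionalField

__all__ = [
    "LIDF_CLASSES",
    "CAB_LEVELS",
    "LAI_LEVELS",
    "SceneParams",
    "SpectralWindow",
    "Scene",
    "generate_scene",
    "propagate_to_sensor",
    "scene_grid",
]

CAB_LEVELS = (20.0, 40.0, 60.0, 80.0)
LAI_LEVELS = (1.0, 2.0, 4.0, 6.0)

#: leaf-inclination classes -> (continuum reflectance offset, bowl amplitude).
#: Planophile (horizontal leaves) canopies are brightest at nadir with a weak
#: bowl; erectophile (vertical leaves) canopies show the strongest rise of
#: radiance towards grazing view angles.
LIDF_CLASSES: dict[str, tuple[float, float]] = {
    "planophile": (+0.020, 0.10),
    "plagiophile": (+0.010, 0.18),
    "spherical": (0.000, 0.25),
    "extremophile": (-0.010, 0.30),
    "erectophile": (-0.020, 0.35),
}

#: clear-sky continuum solar irradiance near 760 nm, mW m-2 nm-1
CONTINUUM_IRRADIANCE = 1000.0
#: downwelling transmittance at the O2-A line centre (total solar path)
SUN_LINE_TRANSMITTANCE = 0.35
#: 1-sigma width (nm) of the effective absorption line profile
LINE_SIGMA_NM = 0.6


@dataclass(frozen=True)
class SceneParams:
    """Vegetation and geometry configuration of one synthetic scene."""

    cab: float = 40.0
    lai: float = 4.0
    lidf: str = "spherical"
    sza: float = 30.0
    sensor_height: float = 20.0
    anisotropy_amplitude: float | None = None
    sif_peak: float = 2.0

    def __post_init__(self) -> None:
        if self.cab not in CAB_LEVELS:
            raise ValueError(f"cab must be one of {CAB_LEVELS}")
        if self.lai not in LAI_LEVELS:
            raise ValueError(f"lai must be one of {LAI_LEVELS}")
        if self.lidf not in LIDF_CLASSES:
            raise ValueError(f"lidf must be one of {sorted(LIDF_CLASSES)}")
        if not 0.0 <= self.sza < 90.0:
            raise ValueError("sza must lie in [0, 90)")
        if self.sensor_height <= 0:
            raise ValueError("sensor_height must be positive")
        if self.anisotropy_amplitude is not None and self.anisotropy_amplitude < 0:
            raise ValueError("anisotropy_amplitude must be non-negative")
        if self.sif_peak < 0:
            raise ValueError("sif_peak must be non-negative")

    @property
    def bowl_amplitude(self) -> float:
        if self.anisotropy_amplitude is not None:
            return self.anisotropy_amplitude
        return LIDF_CLASSES[self.lidf][1]


@dataclass(frozen=True)
class SpectralWindow:
    """Sampled wavelength window around the O2-A band.

    sampling must equal fwhm / 2 (critical sampling of the instrument line
    shape) and the window must contain the three retrieval bands.
    """

    lo: float = 755.1
    hi: float = 773.1
    fwhm: float = 0.3
    sampling: float = 0.15

    def __post_init__(self) -> None:
        if abs(self.sampling - self.fwhm / 2.0) > 1e-9:
            raise ValueError("sampling must equal fwhm / 2")
        if self.hi <= self.lo:
            raise ValueError("window bounds inverted")
        if not (self.lo <= 758.7 and self.hi >= 770.1):
            raise ValueError("window must contain the three retrieval bands")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.sampling))
        return self.lo + self.sampling * np.arange(n + 1)


@dataclass
class Scene:
    """One generated scene: spectra, directional fields and scalars."""

    params: SceneParams
    wavelengths: np.ndarray
    downwelling: np.ndarray          # I at TOC, mW m-2 nm-1
    radiance: DirectionalField       # total upwelling L0 at TOC (reflected + SIF)
    sif: DirectionalField            # SIF component of L0
    continuum_reflectance: float
    sif_amplitude: float             # nadir SIF radiance at the in-band wavelength


def _continuum_reflectance(params: SceneParams) -> float:
    offset = LIDF_CLASSES[params.lidf][0]
    lai_term = 0.14 * (1.0 - np.exp(-0.45 * params.lai))
    cab_term = -0.02 * params.cab / 80.0
    return float(0.28 + lai_term + cab_term + offset)


def _sif_amplitude(params: SceneParams) -> float:
    # monotone in LAI and Cab, normalised so the densest canopy reaches sif_peak
    lai_term = 0.30 + 0.45 * (1.0 - np.exp(-0.5 * params.lai))
    cab_term = 0.55 + 0.45 * params.cab / 80.0
    dense = (0.30 + 0.45 * (1.0 - np.exp(-0.5 * max(LAI_LEVELS)))) * 1.0
    return float(params.sif_peak * lai_term * cab_term / dense)


def _downwelling_spectrum(window: SpectralWindow) -> np.ndarray:
    wl = window.wavelengths
    shape = np.exp(-0.5 * ((wl - 761.1) / LINE_SIGMA_NM) ** 2)
    high_res = CONTINUUM_IRRADIANCE * SUN_LINE_TRANSMITTANCE**shape
    sigma_samples = window.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / window.sampling
    return gaussian_filter1d(high_res, sigma_samples, mode="nearest")


def generate_scene(
    params: SceneParams,
    window: SpectralWindow | None = None,
    seed: int = 0,
    noise: float = 0.0,
) -> Scene:
    """Build the downwelling spectrum and TOC directional fields of one scene.

    `noise` is a relative (multiplicative Gaussian) perturbation applied to the
    radiance fields behind the seed; the default 0 keeps the scene exact.
    """
    window = window or SpectralWindow()
    wl = window.wavelengths
    grid = AngularGrid.regular(zenith_step=1.0, azimuth_step=10.0)

    downwelling = _downwelling_spectrum(window)
    rho0 = _continuum_reflectance(params)
    sif0 = _sif_amplitude(params)
    a = params.bowl_amplitude

    bowl = 1.0 + a * np.sin(np.radians(grid.zenith_centers)) ** 2  # (nz,)
    rho_spectral = rho0 * (1.0 + 0.0008 * (wl - 761.1))            # mild NIR slope
    sif_spectral = sif0 * (1.0 - 0.004 * (wl - 761.1))             # far-red SIF wing

    reflected = bowl[:, None] * (rho_spectral * downwelling)[None, :] / np.pi
    sif_vals = bowl[:, None] * sif_spectral[None, :]
    # azimuth-uniform fields (the bowl is a zenith effect)
    reflected = np.repeat(reflected[:, None, :], grid.n_azimuth, axis=1)
    sif_vals = np.repeat(sif_vals[:, None, :], grid.n_azimuth, axis=1)

    if noise > 0:
        rng = np.random.default_rng(seed)
        reflected = reflected * (1.0 + noise * rng.standard_normal(reflected.shape))
        sif_vals = sif_vals * (1.0 + noise * rng.standard_normal(sif_vals.shape))
        reflected = np.clip(reflected, 0.0, None)
        sif_vals = np.clip(sif_vals, 0.0, None)

    total = reflected + sif_vals
    return Scene(
        params=params,
        wavelengths=wl,
        downwelling=downwelling,
        radiance=DirectionalField(total, grid, wl),
        sif=DirectionalField(sif_vals, grid, wl),
        continuum_reflectance=rho0,
        sif_amplitude=sif0,
    )


def propagate_to_sensor(
    toc_field: DirectionalField,
    model: TransmittanceModel,
    sensor_height: float,
    wavelength: float | None = None,
) -> DirectionalField:
    """Attenuate each direction by T(H sec(theta), lambda) to sensor height."""
    if sensor_height <= 0:
        raise ValueError("sensor_height must be positive")
    sec = 1.0 / np.cos(np.radians(toc_field.grid.zenith_centers))
    paths = sensor_height * sec
    if toc_field.values.ndim == 3:
        kappa = np.atleast_1d(model.kappa_at(toc_field.wavelengths))
        T = np.exp(-np.outer(paths, kappa))  # (nz, nw)
        values = toc_field.values * T[:, None, :]
    else:
        T = model.transmittance(paths, wavelength)
        values = toc_field.values * T[:, None]
    return DirectionalField(values, toc_field.grid, toc_field.wavelengths)


def scene_grid(
    sensor_height: float = 20.0,
    sif_peak: float = 2.0,
) -> list[SceneParams]:
    """The 80-condition grid: 4 Cab x 4 LAI x 5 LIDF, fixed SZA and height."""
    base = SceneParams(sensor_height=sensor_height, sif_peak=sif_peak)
    return [
        replace(base, cab=cab, lai=lai, lidf=lidf)
        for cab, lai, lidf in product(CAB_LEVELS, LAI_LEVELS, LIDF_CLASSES)
    ]
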