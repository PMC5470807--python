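"""Path transmittance and atmospheric correction for tower-scale observations.

At the O2-A absorption band the upwelling transmittance between the canopy and
a tower sensor depends essentially on the slant path length p = H sec(theta).
The module models it as monochromatic Beer-Lambert extinction,

    T(p, lambda) = exp(-kappa(lambda) * p),

with kappa the effective per-metre extinction at instrument resolution. Over
tower-scale paths (tens of metres) this is nearly linear in p, which is what
makes a single *equivalent* path length meaningful for hemispherical data (see
:mod:`hemisif.ertpl`). The default O2-A extinction is calibrated so that an
equivalent transmittance of 0.924 corresponds to an equivalent path of 37.7 m,
a representative value for a 20 m instrument height.

Surface-atmosphere coupling (spherical albedo, path radiance) is carried as an
explicit :class:`SurfaceCoupling` term so the full at-sensor relation

    L_H = L_0 T / (1 - rho S) + L_path

and its inverse are available, but both coupling terms default to zero: at
heights of tens of metres the scattering contribution of the intervening layer
is negligible and attenuation dominates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "O2A_WAVELENGTH_NM",
    "DEFAULT_KAPPA_O2A",
    "TransmittanceModel",
    "LinearPathFit",
    "SurfaceCoupling",
    "fit_linear_T",
    "propagate_radiance",
    "correct_radiance",
    "correct_hemispherical_irradiance",
]

O2A_WAVELENGTH_NM = 761.1
#: Per-metre extinction at the O2-A band centre: -ln(0.924) / 37.7 m.
DEFAULT_KAPPA_O2A = -math.log(0.924) / 37.7


@dataclass(frozen=True)
class TransmittanceModel:
    """Beer-Lambert path transmittance, constant or spectrally resolved.

    Either ``kappa`` is a scalar (wavelength-independent extinction, 1/m), or
    both ``wavelengths`` (nm, ascending) and ``kappa`` are matching 1-D arrays
    and extinction is linearly interpolated between samples.
    """

    kappa: float | np.ndarray
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.wavelengths is None:
            k = float(self.kappa)
            if k < 0 or not np.isfinite(k):
                raise ValueError("kappa must be finite and non-negative")
            object.__setattr__(self, "kappa", k)
        else:
            wl = np.asarray(self.wavelengths, dtype=float)
            k = np.asarray(self.kappa, dtype=float)
            if wl.ndim != 1 or wl.shape != k.shape:
                raise ValueError("wavelengths and kappa must be matching 1-D arrays")
            if np.any(np.diff(wl) <= 0):
                raise ValueError("wavelengths must be strictly increasing")
            if np.any(k < 0) or np.any(~np.isfinite(k)):
                raise ValueError("kappa must be finite and non-negative")
            object.__setattr__(self, "wavelengths", wl)
            object.__setattr__(self, "kappa", k)

    # -- constructors -------------------------------------------------------

    @classmethod
    def constant(cls, kappa: float) -> "TransmittanceModel":
        return cls(kappa=kappa)

    @classmethod
    def from_calibration(
        cls, transmittance: float, path: float, wavelength: float = O2A_WAVELENGTH_NM
    ) -> "TransmittanceModel":
        """Constant-extinction model anchored to one (transmittance, path) pair."""
        if not 0.0 < transmittance <= 1.0:
            raise ValueError("calibration transmittance must lie in (0, 1]")
        if path <= 0:
            raise ValueError("calibration path must be positive")
        del wavelength  # anchor wavelength recorded by the caller if needed
        return cls(kappa=-math.log(transmittance) / path)

    @classmethod
    def gaussian_line(
        cls,
        kappa_peak: float = DEFAULT_KAPPA_O2A,
        center: float = O2A_WAVELENGTH_NM,
        sigma: float = 0.6,
        wavelengths: np.ndarray | None = None,
    ) -> "TransmittanceModel":
        """Gaussian absorption-line extinction profile around `center`.

        The profile is the effective band-averaged extinction at instrument
        resolution; `sigma` (nm) sets the line width (default FWHM ~1.4 nm,
        so shoulders a few nm away sit on a kappa ~ 0 continuum).
        """
        if wavelengths is None:
            wavelengths = np.arange(center - 8.0, center + 12.0 + 1e-9, 0.05)
        wl = np.asarray(wavelengths, dtype=float)
        k = kappa_peak * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
        return cls(kappa=k, wavelengths=wl)

    @classmethod
    def o2a_default(cls) -> "TransmittanceModel":
        """Default spectral model: Gaussian O2-A line at the calibrated extinction."""
        return cls.gaussian_line()

    # -- evaluation ---------------------------------------------------------

    def kappa_at(self, wavelength: float | np.ndarray | None = None):
        """Extinction (1/m) at the given wavelength(s); scalar models ignore it."""
        if self.wavelengths is None:
            if wavelength is None or np.isscalar(wavelength):
                return self.kappa
            return np.full(np.shape(wavelength), self.kappa)
        if wavelength is None:
            raise ValueError("spectral model requires a wavelength")
        return np.interp(wavelength, self.wavelengths, self.kappa)

    def transmittance(self, path, wavelength: float | np.ndarray | None = None):
        """T = exp(-kappa(lambda) * path); multiplicative in path."""
        p = np.asarray(path, dtype=float)
        if np.any(p < 0):
            raise ValueError("path length must be non-negative")
        out = np.exp(-p * self.kappa_at(wavelength))
        return float(out) if np.isscalar(path) and np.ndim(out) == 0 else out


@dataclass(frozen=True)
class LinearPathFit:
    """Ordinary least-squares line T = intercept + slope * path.

    ``degenerate`` flags a constant-transmittance input (kappa ~ 0), reported
    as a perfect flat fit so absorption-free pipelines run unchanged.
    """

    slope: float
    intercept: float
    r_squared: float
    path_range: tuple[float, float]
    degenerate: bool = False

    def predict(self, path):
        return self.intercept + self.slope * np.asarray(path, dtype=float)

    def invert(self, transmittance: float) -> float:
        """Path length at which the fitted line reaches `transmittance`."""
        if self.degenerate or self.slope == 0.0:
            raise ValueError("cannot invert a flat transmittance-path relation")
        path = (float(transmittance) - self.intercept) / self.slope
        lo, hi = self.path_range
        span = hi - lo
        if path < lo - 0.05 * span or path > hi + 0.05 * span:
            warnings.warn(
                f"inverted path {path:.2f} m extrapolates beyond the fitted "
                f"range [{lo:.2f}, {hi:.2f}] m",
                stacklevel=2,
            )
        return path


def fit_linear_T(
    model: TransmittanceModel,
    wavelength: float | None,
    paths,
) -> LinearPathFit:
    """Fit T(path) with a straight line over the given paths.

    Over tower-scale paths at the O2-A band the Beer-Lambert curve is close to
    linear (R^2 > 0.99 for 20-65 m at the default extinction), which underpins
    the equivalent-path construction.
    """
    p = np.asarray(paths, dtype=float)
    if p.ndim != 1 or np.unique(p).size < 3:
        raise ValueError("need at least 3 distinct path lengths")
    if np.ptp(p) <= 0:
        raise ValueError("paths must not be all equal")
    t = model.transmittance(p, wavelength)
    rng = (float(p.min()), float(p.max()))
    if np.ptp(t) < 1e-14:
        return LinearPathFit(0.0, float(np.mean(t)), 1.0, rng, degenerate=True)
    res = stats.linregress(p, t)
    return LinearPathFit(float(res.slope), float(res.intercept), float(res.rvalue**2), rng)


@dataclass(frozen=True)
class SurfaceCoupling:
    """Surface reflectance / spherical albedo / path radiance of the layer."""

    rho: float = 0.0
    spherical_albedo: float = 0.0
    path_radiance: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0 and 0.0 <= self.spherical_albedo <= 1.0):
            raise ValueError("rho and spherical_albedo must lie in [0, 1]")
        if self.path_radiance < 0:
            raise ValueError("path_radiance must be non-negative")
        if self.rho * self.spherical_albedo >= 1.0:
            raise ValueError("rho * spherical_albedo must be < 1 (series convergence)")


def propagate_radiance(L0, T_up, coupling: SurfaceCoupling | None = None):
    """Top-of-canopy radiance to at-sensor radiance: L0 T / (1 - rho S) + L_path."""
    c = coupling or SurfaceCoupling()
    return np.asarray(L0, dtype=float) * np.asarray(T_up, dtype=float) / (
        1.0 - c.rho * c.spherical_albedo
    ) + c.path_radiance


def correct_radiance(LH, T_up, coupling: SurfaceCoupling | None = None):
    """Invert the at-sensor relation: L0 = (L_H - L_path) (1 - rho S) / T_up.

    With the default (zero) coupling this is plain division by the upwelling
    transmittance. A negative corrected radiance triggers an over-correction
    warning rather than an error.
    """
    T = np.asarray(T_up, dtype=float)
    if np.any(T <= 0) or np.any(T > 1.0 + 1e-12):
        raise ValueError("T_up must lie in (0, 1]")
    c = coupling or SurfaceCoupling()
    L0 = (np.asarray(LH, dtype=float) - c.path_radiance) * (1.0 - c.rho * c.spherical_albedo) / T
    if np.any(L0 < 0):
        warnings.warn("corrected radiance is negative (over-correction)", stacklevel=2)
    return L0


def correct_hemispherical_irradiance(
    Ecos,
    sensor_height: float,
    model: TransmittanceModel,
    wavelength: float | np.ndarray | None = None,
    ertpl_ratio: float = 2.0,
):
    """Correct at-sensor hemispherical irradiance to top of canopy.

    Divides by the transmittance of the equivalent path ``ertpl_ratio * H``;
    the closed-form equivalent path for an isotropic surface and transmittance
    linear in path is exactly 2H, hence the default ratio.
    """
    if ertpl_ratio <= 0:
        raise ValueError("ertpl_ratio must be positive")
    if sensor_height <= 0:
        raise ValueError("sensor_height must be positive")
    T = model.transmittance(ertpl_ratio * sensor_height, wavelength)
    return np.asarray(Ecos, dtype=float) / T
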