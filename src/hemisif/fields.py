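"""Angular grids and directional radiance fields.

A hemispherical (cosine-corrected) observation integrates radiance over view
zenith angle theta in [0, 90) deg and relative azimuth phi in [0, 360) deg with
the cosine-weighted solid-angle measure cos(theta) sin(theta) dtheta dphi.
These containers hold radiance (or SIF radiance) sampled at the centres of a
regular (theta, phi) cell grid, optionally with a trailing wavelength axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AngularGrid", "DirectionalField"]


def _as_edges(values, lo: float, hi: float, name: str) -> np.ndarray:
    edges = np.asarray(values, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError(f"{name} must be a 1-D array of at least two edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError(f"{name} must be strictly increasing")
    if edges[0] < lo - 1e-12 or edges[-1] > hi + 1e-12:
        raise ValueError(f"{name} must lie within [{lo}, {hi}] degrees")
    return edges


@dataclass(frozen=True)
class AngularGrid:
    """Regular or irregular cell grid over the upper hemisphere.

    Parameters
    ----------
    zenith_edges : array of degrees, ascending, within [0, 90]
    azimuth_edges : array of degrees, ascending, within [0, 360]

    Cell centres carry the field samples; quadrature weights are the exact
    cell integrals of cos(theta) sin(theta) dtheta dphi, so an isotropic unit
    field integrates to pi (the Lambertian irradiance/radiance factor).
    """

    zenith_edges: np.ndarray
    azimuth_edges: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "zenith_edges", _as_edges(self.zenith_edges, 0.0, 90.0, "zenith_edges")
        )
        object.__setattr__(
            self, "azimuth_edges", _as_edges(self.azimuth_edges, 0.0, 360.0, "azimuth_edges")
        )

    @classmethod
    def regular(cls, zenith_step: float = 1.0, azimuth_step: float = 10.0) -> "AngularGrid":
        """Uniform grid over the full hemisphere (default 1 deg x 10 deg)."""
        if zenith_step <= 0 or azimuth_step <= 0:
            raise ValueError("grid steps must be positive")
        nz = int(round(90.0 / zenith_step))
        na = int(round(360.0 / azimuth_step))
        if abs(nz * zenith_step - 90.0) > 1e-9 or abs(na * azimuth_step - 360.0) > 1e-9:
            raise ValueError("steps must divide 90 and 360 degrees evenly")
        return cls(
            np.linspace(0.0, 90.0, nz + 1),
            np.linspace(0.0, 360.0, na + 1),
        )

    @property
    def n_zenith(self) -> int:
        return self.zenith_edges.size - 1

    @property
    def n_azimuth(self) -> int:
        return self.azimuth_edges.size - 1

    @property
    def zenith_centers(self) -> np.ndarray:
        return 0.5 * (self.zenith_edges[:-1] + self.zenith_edges[1:])

    @property
    def azimuth_centers(self) -> np.ndarray:
        return 0.5 * (self.azimuth_edges[:-1] + self.azimuth_edges[1:])

    @property
    def azimuth_widths_rad(self) -> np.ndarray:
        return np.radians(np.diff(self.azimuth_edges))

    @property
    def ring_fractions(self) -> np.ndarray:
        """Exact per-ring share of hemispherical irradiance, sin^2(hi) - sin^2(lo)."""
        s2 = np.sin(np.radians(self.zenith_edges)) ** 2
        return np.diff(s2)

    @property
    def quadrature_weights(self) -> np.ndarray:
        """(n_zenith, n_azimuth) cell weights; sum equals pi for a full grid."""
        return np.outer(self.ring_fractions / 2.0, self.azimuth_widths_rad)


@dataclass
class DirectionalField:
    """Radiance samples on an :class:`AngularGrid`.

    values has shape (n_zenith, n_azimuth) or (n_zenith, n_azimuth, n_wavelength);
    in the latter case `wavelengths` (nm) must be given. Values are radiances in
    mW m-2 nm-1 sr-1 and must be non-negative.
    """

    values: np.ndarray
    grid: AngularGrid
    wavelengths: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("values must be 2-D (theta, phi) or 3-D (theta, phi, wavelength)")
        if self.values.shape[:2] != (self.grid.n_zenith, self.grid.n_azimuth):
            raise ValueError(
                f"values shape {self.values.shape[:2]} does not match grid "
                f"({self.grid.n_zenith}, {self.grid.n_azimuth})"
            )
        if self.values.ndim == 3:
            if self.wavelengths is None:
                raise ValueError("3-D field requires wavelengths")
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths.shape != (self.values.shape[2],):
                raise ValueError("wavelengths length must match the trailing axis")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("radiance values must be finite and non-negative")

    @classmethod
    def isotropic(
        cls,
        value: float,
        grid: AngularGrid | None = None,
        wavelengths: np.ndarray | None = None,
    ) -> "DirectionalField":
        grid = grid if grid is not None else AngularGrid.regular()
        shape: tuple[int, ...] = (grid.n_zenith, grid.n_azimuth)
        if wavelengths is not None:
            shape = shape + (np.asarray(wavelengths).size,)
        return cls(np.full(shape, float(value)), grid, wavelengths)

    def at_wavelength(self, wavelength: float, tol: float = 1e-6) -> "DirectionalField":
        """Extract the 2-D field at one sampled wavelength."""
        if self.values.ndim == 2:
            raise ValueError("field has no wavelength axis")
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[idx] - wavelength) > max(tol, 1e-6):
            raise ValueError(f"wavelength {wavelength} nm not sampled by this field")
        return DirectionalField(self.values[:, :, idx], self.grid)
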