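"""Three-band Fraunhofer Line Discrimination (3FLD) retrieval of SIF at O2-A.

Inside a telluric absorption well the downwelling irradiance I collapses while
the fluorescence emission does not, so comparing the in-band upwelling
radiance L_in with what the shoulder reflectance predicts isolates SIF:

    SIF_in = [(I_l w_l + I_r w_r) L_in - I_in (L_l w_l + L_r w_r)]
             / [(I_l w_l + I_r w_r) - I_in]

with shoulder weights w inversely proportional to the spectral distance of
each shoulder from the in-band wavelength (normalised to sum to one; the
estimator is invariant to the weights' common scale). The estimator is exact -
zero bias - whenever reflectance and SIF are spectrally flat across the three
bands, which is the 3FLD assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThreeBandSet",
    "RetrievalInput",
    "band_weights",
    "threefld",
    "rrmse",
    "sample_bands",
]


@dataclass(frozen=True)
class ThreeBandSet:
    """Left-shoulder, in-band and right-shoulder wavelengths (nm).

    Defaults put the in-band sample at the O2-A centre (761.1 nm) and the
    shoulders on the absorption-free continuum either side of the feature.
    """

    lambda_left: float = 758.7
    lambda_in: float = 761.1
    lambda_right: float = 770.1

    def __post_init__(self) -> None:
        if not self.lambda_left < self.lambda_in < self.lambda_right:
            raise ValueError("bands must satisfy lambda_left < lambda_in < lambda_right")

    @property
    def weights(self) -> tuple[float, float]:
        return band_weights(self)


def band_weights(bands: ThreeBandSet) -> tuple[float, float]:
    """Distance-inverse shoulder weights, normalised to w_left + w_right = 1."""
    span = bands.lambda_right - bands.lambda_left
    w_left = (bands.lambda_right - bands.lambda_in) / span
    w_right = (bands.lambda_in - bands.lambda_left) / span
    return float(w_left), float(w_right)


@dataclass(frozen=True)
class RetrievalInput:
    """Downwelling irradiance I and upwelling radiance L at the three bands.

    I in mW m-2 nm-1 at the top of canopy; L in mW m-2 nm-1 sr-1 at the top
    of canopy (for hemispherical data the Lambertian-equivalent radiance E/pi).
    """

    I_left: float
    I_in: float
    I_right: float
    L_left: float
    L_in: float
    L_right: float

    def __post_init__(self) -> None:
        for name in ("I_left", "I_in", "I_right", "L_left", "L_in", "L_right"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def threefld(
    inputs: RetrievalInput,
    weights: ThreeBandSet | tuple[float, float] | None = None,
) -> float:
    """Evaluate the 3FLD estimator; `weights` defaults to the standard band set."""
    if weights is None:
        weights = ThreeBandSet()
    if isinstance(weights, ThreeBandSet):
        w_left, w_right = weights.weights
    else:
        w_left, w_right = weights
    I_shoulder = inputs.I_left * w_left + inputs.I_right * w_right
    L_shoulder = inputs.L_left * w_left + inputs.L_right * w_right
    denom = I_shoulder - inputs.I_in
    if abs(denom) < 1e-12 * max(I_shoulder, 1.0):
        raise ValueError(
            "weighted shoulder irradiance equals in-band irradiance: "
            "no absorption feature, retrieval undefined"
        )
    return float((I_shoulder * inputs.L_in - inputs.I_in * L_shoulder) / denom)


def rrmse(estimates, references) -> float:
    """Relative root-mean-square error in percent: 100 sqrt(mean((e-r)^2)) / mean(r)."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape or est.size == 0:
        raise ValueError("estimates and references must be equal-length and non-empty")
    mean_ref = ref.mean()
    if mean_ref <= 0:
        raise ValueError("mean reference must be positive")
    return float(100.0 * np.sqrt(np.mean((est - ref) ** 2)) / mean_ref)


def sample_bands(
    wavelengths: np.ndarray,
    spectrum: np.ndarray,
    bands: ThreeBandSet | None = None,
    tol: float = 0.5,
) -> tuple[float, float, float]:
    """Pick the spectrum samples nearest each band wavelength.

    Raises if a band falls more than `tol` nm from the closest sample.
    """
    bands = bands or ThreeBandSet()
    wl = np.asarray(wavelengths, dtype=float)
    sp = np.asarray(spectrum, dtype=float)
    out = []
    for lam in (bands.lambda_left, bands.lambda_in, bands.lambda_right):
        idx = int(np.argmin(np.abs(wl - lam)))
        if abs(wl[idx] - lam) > tol:
            raise ValueError(f"no sample within {tol} nm of {lam} nm")
        out.append(float(sp[idx]))
    return out[0], out[1], out[2]
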