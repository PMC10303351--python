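"""Wavelength grids, reflectance spectra and a simple camera forward model.

Everything downstream works on a common visible-band wavelength grid
(380-780 nm by default).  A :class:`CameraModel` renders a reflectance
spectrum to an RGB triple by weighting it with per-channel spectral
sensitivities under an illuminant — the forward model that calibration
fixtures (color checker, phantoms) share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling in nanometres, 380-780 nm by default."""

    start: float = 380.0
    stop: float = 780.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.step <= 0 or self.stop <= self.start:
            raise ValueError("grid requires stop > start and step > 0")

    @property
    def values(self) -> np.ndarray:
        return np.arange(self.start, self.stop + 0.5 * self.step, self.step)

    def __len__(self) -> int:
        return self.values.size

    def band_indices(self, lo: float, hi: float) -> np.ndarray:
        """Indices of grid points with lo <= lambda <= hi."""
        lam = self.values
        return np.nonzero((lam >= lo) & (lam <= hi))[0]


DEFAULT_GRID = WavelengthGrid()

#: Red band used for artery/vein contrast statements (nm).
RED_BAND = (620.0, 780.0)
#: Mid (green-yellow) band where disease-linked absorption changes appear (nm).
MID_BAND = (495.0, 570.0)


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """A unitless reflectance fraction per wavelength, each value in [0, 1]."""

    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.grid),):
            raise ValueError("spectrum length must equal grid length")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum contains non-finite values")
        if vals.min() < 0.0 or vals.max() > 1.0:
            raise ValueError("reflectance must lie in [0, 1]")

    def band_mean(self, lo: float, hi: float) -> float:
        return float(self.values[self.grid.band_indices(lo, hi)].mean())


def _gaussian(lam: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / sd) ** 2)


@dataclass(frozen=True)
class CameraModel:
    """Three-channel spectral camera under a fixed illuminant.

    ``sensitivities`` is a (3, B) array of nonnegative per-channel weighting
    curves (R, G, B order), ``illuminant`` a (B,) spectral power
    distribution and ``gain`` a per-channel scalar.  Rendering a flat 100 %
    reflector at gain 1 yields (1, 1, 1) by construction.
    """

    grid: WavelengthGrid = DEFAULT_GRID
    sensitivities: np.ndarray = None  # type: ignore[assignment]
    illuminant: np.ndarray = None  # type: ignore[assignment]
    gain: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        lam = self.grid.values
        if self.sensitivities is None:
            # Gaussian R/G/B sensitivity peaks at 600/540/460 nm, sd 40 nm.
            sens = np.stack(
                [
                    _gaussian(lam, 600.0, 40.0),
                    _gaussian(lam, 540.0, 40.0),
                    _gaussian(lam, 460.0, 40.0),
                ]
            )
            object.__setattr__(self, "sensitivities", sens)
        else:
            object.__setattr__(
                self, "sensitivities", np.asarray(self.sensitivities, dtype=float)
            )
        if self.illuminant is None:
            object.__setattr__(self, "illuminant", np.ones_like(lam))
        else:
            object.__setattr__(
                self, "illuminant", np.asarray(self.illuminant, dtype=float)
            )
        object.__setattr__(self, "gain", np.asarray(self.gain, dtype=float))
        if self.sensitivities.shape != (3, len(self.grid)):
            raise ValueError("sensitivities must have shape (3, len(grid))")
        if np.any(self.sensitivities < 0):
            raise ValueError("sensitivities must be nonnegative")
        weights = self.sensitivities @ self.illuminant
        if np.any(weights <= 0):
            raise ValueError("each channel must integrate to a positive value")


DEFAULT_CAMERA = CameraModel()


def camera_response(
    spectrum: ReflectanceSpectrum | np.ndarray, cam: CameraModel = DEFAULT_CAMERA
) -> np.ndarray:
    """Render reflectance spectra to RGB through the camera model.

    RGB_c = gain_c * (sum_l L(l) R(l) S_c(l)) / (sum_l L(l) S_c(l)),
    clamped to [0, 1].  Accepts a single spectrum or an (N, B) stack;
    returns shape (3,) or (N, 3) accordingly.
    """
    if isinstance(spectrum, ReflectanceSpectrum):
        if spectrum.grid != cam.grid:
            raise ValueError("spectrum and camera are on different grids")
        refl = spectrum.values
    else:
        refl = np.asarray(spectrum, dtype=float)
        if refl.shape[-1] != len(cam.grid):
            raise ValueError("spectrum length does not match the camera grid")
    weighted = cam.sensitivities * cam.illuminant  # (3, B)
    denom = weighted.sum(axis=1)  # (3,)
    rgb = (refl @ weighted.T) / denom * cam.gain
    return np.clip(rgb, 0.0, 1.0)
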