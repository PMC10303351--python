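"""RGB-to-spectrum reconstruction via color-checker calibration.

A 6-eigenvector principal-component basis is fitted to the 24 calibration
spectra; a ridge-regularized linear regression then maps a polynomial
expansion of camera RGB to the 6 basis coefficients.  Applying that
transformation matrix per pixel simulates a full visible-band reflectance
spectrum from each RGB triple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import DEFAULT_GRID, ReflectanceSpectrum, WavelengthGrid
from .synthetic import ColorCheckerSet


@dataclass(frozen=True)
class SpectralBasis:
    """Mean spectrum plus k orthonormal eigenvector spectra (variance order)."""

    grid: WavelengthGrid
    mean_spectrum: np.ndarray  # (B,)
    eigenvectors: np.ndarray  # (k, B), rows orthonormal
    eigenvalues: np.ndarray  # (k,), descending

    @property
    def k(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass(frozen=True)
class RGBFeatureExpansion:
    """A fixed, ordered list of monomials of (R, G, B), constant term first."""

    terms: tuple[str, ...]


#: Default 11-term second-order polynomial expansion of RGB.
DEFAULT_EXPANSION = RGBFeatureExpansion(
    terms=("1", "R", "G", "B", "R2", "G2", "B2", "RG", "GB", "RB", "RGB")
)


@dataclass(frozen=True)
class TransformationMatrix:
    """Linear map from expanded RGB features to basis coefficients."""

    M: np.ndarray  # (k, n_features)
    expansion: RGBFeatureExpansion
    ridge: float = 0.0


@dataclass(frozen=True)
class SpectralCube:
    """Per-pixel simulated spectra at listed (row, col) coordinates."""

    coordinates: np.ndarray  # (N, 2) int
    spectra: np.ndarray  # (N, B), clipped to [0, 1]
    grid: WavelengthGrid

    def __len__(self) -> int:
        return self.spectra.shape[0]


def fit_spectral_basis(
    spectra: np.ndarray, k: int = 6, grid: WavelengthGrid = DEFAULT_GRID
) -> SpectralBasis:
    """PCA basis of a spectral collection: top-k eigenvectors of the sample
    covariance (divisor n), sign-fixed so each vector's largest-|entry|
    loading is positive.

    Raises if fewer than k+1 spectra are supplied or the centered data have
    rank below k — a padded basis would silently break downstream
    regression, so it is an error instead.
    """
    x = np.asarray(spectra, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected an (n, B) stack of spectra")
    n, b = x.shape
    if b != len(grid):
        raise ValueError("spectra length does not match the grid")
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} spectra to fit a {k}-vector basis")
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(s > max(s[0], 1.0) * 1e-10)) if s.size else 0
    if rank < k:
        raise ValueError(f"calibration spectra have rank {rank} < k={k}")
    eigvals = (s[:k] ** 2) / n
    eigvecs = vt[:k].copy()
    for i in range(k):
        j = np.argmax(np.abs(eigvecs[i]))
        if eigvecs[i, j] < 0:
            eigvecs[i] = -eigvecs[i]
    return SpectralBasis(grid, mean, eigvecs, eigvals)


def expand_rgb(
    rgb: np.ndarray, expansion: RGBFeatureExpansion = DEFAULT_EXPANSION
) -> np.ndarray:
    """Evaluate the monomial feature list on one RGB triple or an (N, 3) stack."""
    rgb = np.asarray(rgb, dtype=float)
    single = rgb.ndim == 1
    rgb = np.atleast_2d(rgb)
    r, g, b = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    values = {
        "1": np.ones_like(r),
        "R": r,
        "G": g,
        "B": b,
        "R2": r * r,
        "G2": g * g,
        "B2": b * b,
        "RG": r * g,
        "GB": g * b,
        "RB": r * b,
        "RGB": r * g * b,
    }
    feats = np.stack([values[t] for t in expansion.terms], axis=1)
    return feats[0] if single else feats


def fit_transformation(
    checker: ColorCheckerSet | tuple[np.ndarray, np.ndarray],
    basis: SpectralBasis,
    expansion: RGBFeatureExpansion = DEFAULT_EXPANSION,
    ridge: float = 1e-6,
) -> TransformationMatrix:
    """Regress calibration-patch basis coefficients on expanded RGB.

    Solves (X^T X + ridge I) M^T = X^T C where X is the (n_patches,
    n_features) design and C the (n_patches, k) coefficient matrix of the
    patch spectra in the basis.  ``checker`` may be a ColorCheckerSet or a
    raw ``(rgb, spectra)`` pair.
    """
    if isinstance(checker, ColorCheckerSet):
        rgb, spectra = checker.rgb, checker.spectra
    else:
        rgb, spectra = checker
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    feats = expand_rgb(rgb, expansion)
    coeffs = (np.asarray(spectra, dtype=float) - basis.mean_spectrum) @ basis.eigenvectors.T
    gram = feats.T @ feats + ridge * np.eye(feats.shape[1])
    if ridge == 0 and np.linalg.matrix_rank(gram) < feats.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix at ridge=0")
    m_t = np.linalg.solve(gram, feats.T @ coeffs)  # (n_features, k)
    return TransformationMatrix(m_t.T, expansion, ridge)


def _simulate_spectra(
    rgb: np.ndarray, m: TransformationMatrix, basis: SpectralBasis
) -> np.ndarray:
    feats = expand_rgb(np.atleast_2d(rgb), m.expansion)
    coeffs = feats @ m.M.T
    spectra = basis.mean_spectrum + coeffs @ basis.eigenvectors
    return np.clip(spectra, 0.0, 1.0)


def simulate_pixel_spectrum(
    rgb: np.ndarray, m: TransformationMatrix, basis: SpectralBasis
) -> ReflectanceSpectrum:
    """Simulate one pixel's reflectance spectrum from its RGB triple."""
    if basis.k != m.M.shape[0]:
        raise ValueError("transformation and basis disagree on component count")
    return ReflectanceSpectrum(basis.grid, _simulate_spectra(rgb, m, basis)[0])


def reconstruct_cube(
    img: np.ndarray,
    mask: np.ndarray,
    m: TransformationMatrix,
    basis: SpectralBasis,
) -> SpectralCube:
    """Simulate a spectrum for every masked pixel of an RGB image."""
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if img.shape[:2] != mask.shape:
        raise ValueError("mask shape does not match the image")
    if not mask.any():
        raise ValueError("empty mask")
    coords = np.argwhere(mask)
    spectra = _simulate_spectra(img[mask], m, basis)
    return SpectralCube(coords, spectra, basis.grid)


def mean_class_spectrum(
    cube: SpectralCube, labels: np.ndarray, cls: int
) -> ReflectanceSpectrum:
    """Arithmetic mean spectrum over the cube pixels carrying label ``cls``."""
    labels = np.asarray(labels)
    pix = labels[cube.coordinates[:, 0], cube.coordinates[:, 1]]
    sel = pix == cls
    if not sel.any():
        raise ValueError(f"class {cls} absent from the cube")
    return ReflectanceSpectrum(cube.grid, cube.spectra[sel].mean(axis=0))
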