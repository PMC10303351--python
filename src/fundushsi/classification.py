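"""Artery/vein separation on principal-component score plots.

Per severity stage, vessel-pixel spectra are projected onto their first two
principal components, scores are min-max normalized to [0, 1], and a scalar
threshold on the first (x-axis) component splits arteries from veins.
Which side of the threshold is arterial is learned from a labeled training
subset, since PCA signs are arbitrary.  Arteries render red, veins blue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reconstruction import SpectralCube
from .synthetic import ARTERY, BACKGROUND, VEIN, SeverityLevel


@dataclass(frozen=True)
class ScoreModel:
    """Two-component score projection with normalization bounds and threshold."""

    mean_spectrum: np.ndarray  # (B,)
    loadings: np.ndarray  # (2, B), orthonormal rows
    eigenvalues: np.ndarray  # (2,)
    minmax: np.ndarray  # (2, 2): per-component (min, max) of training scores
    threshold: float  # on normalized component 1, in [0, 1]
    artery_high: bool  # True if s1 >= threshold means artery
    stage: SeverityLevel | None = None


@dataclass(frozen=True)
class NormalizedScores:
    """Per-pixel (s1, s2) in [0, 1]^2 with their image coordinates."""

    scores: np.ndarray  # (N, 2)
    coordinates: np.ndarray  # (N, 2)


def _pca2(spectra: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = spectra.mean(axis=0)
    xc = spectra - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    if s.size < 2 or s[1] <= max(s[0], 1.0) * 1e-12:
        raise ValueError("degenerate spectra: fewer than 2 informative components")
    load = vt[:2].copy()
    for i in range(2):
        j = np.argmax(np.abs(load[i]))
        if load[i, j] < 0:
            load[i] = -load[i]
    eigvals = (s[:2] ** 2) / spectra.shape[0]
    return mean, load, eigvals


def minmax_normalize(scores: np.ndarray, minmax: np.ndarray) -> np.ndarray:
    """Affine map to [0, 1] per component; out-of-range values are clamped."""
    minmax = np.asarray(minmax, dtype=float)
    lo, hi = minmax[:, 0], minmax[:, 1]
    if np.any(hi <= lo):
        raise ValueError("min must be strictly below max per component")
    return np.clip((scores - lo) / (hi - lo), 0.0, 1.0)


def fit_score_model(
    cube: SpectralCube,
    labels: np.ndarray,
    stage: SeverityLevel | None = None,
    threshold_method: str = "midpoint",
) -> ScoreModel:
    """Fit the per-stage score model on a labeled vessel-pixel cube.

    ``labels`` is a per-pixel label map (or a length-N label vector aligned
    with the cube) that must contain both classes.  The threshold on
    normalized component 1 is the midpoint of the class-conditional means
    (default) or an F1-maximizing scan in 0.01 steps.
    """
    if len(cube) < 3:
        raise ValueError("need at least 3 vessel pixels")
    labels = np.asarray(labels)
    if labels.ndim == 2:
        lab = labels[cube.coordinates[:, 0], cube.coordinates[:, 1]]
    else:
        lab = labels
    is_a, is_v = lab == ARTERY, lab == VEIN
    if not (is_a.any() and is_v.any()):
        raise ValueError("labeled subset must contain both arteries and veins")
    mean, load, eigvals = _pca2(cube.spectra)
    raw = (cube.spectra - mean) @ load.T  # (N, 2)
    minmax = np.stack([raw.min(axis=0), raw.max(axis=0)], axis=1)
    if np.any(minmax[:, 1] <= minmax[:, 0]):
        raise ValueError("degenerate scores: zero variance component")
    norm = minmax_normalize(raw, minmax)
    mu_a = float(norm[is_a, 0].mean())
    mu_v = float(norm[is_v, 0].mean())
    artery_high = mu_a >= mu_v
    if threshold_method == "midpoint":
        threshold = 0.5 * (mu_a + mu_v)
    elif threshold_method == "f1-scan":
        threshold = _f1_scan_threshold(norm[:, 0], is_a, artery_high)
    else:
        raise ValueError(f"unknown threshold method: {threshold_method!r}")
    return ScoreModel(
        mean_spectrum=mean,
        loadings=load,
        eigenvalues=eigvals,
        minmax=minmax,
        threshold=float(threshold),
        artery_high=artery_high,
        stage=stage,
    )


def _class_f1(pred_pos: np.ndarray, is_pos: np.ndarray) -> float:
    tp = np.sum(pred_pos & is_pos)
    fp = np.sum(pred_pos & ~is_pos)
    fn = np.sum(~pred_pos & is_pos)
    if tp + fp == 0 or tp + fn == 0:
        return 0.0
    sens = tp / (tp + fn)
    prec = tp / (tp + fp)
    return 0.0 if sens + prec == 0 else 2 * sens * prec / (sens + prec)


def _f1_scan_threshold(s1: np.ndarray, is_artery: np.ndarray, artery_high: bool) -> float:
    """Sweep thresholds in 0.01 steps maximizing the training macro-F1."""
    best_t, best_f1 = 0.5, -1.0
    for t in np.arange(0.0, 1.0 + 1e-9, 0.01):
        pred_a = s1 >= t if artery_high else s1 < t
        macro = 0.5 * (_class_f1(pred_a, is_artery) + _class_f1(~pred_a, ~is_artery))
        if macro > best_f1:
            best_f1, best_t = macro, t
    return best_t


def project_scores(cube: SpectralCube, model: ScoreModel) -> NormalizedScores:
    """Project cube spectra into the model's normalized score plane."""
    raw = (cube.spectra - model.mean_spectrum) @ model.loadings.T
    return NormalizedScores(minmax_normalize(raw, model.minmax), cube.coordinates)


def classify(scores: NormalizedScores, model: ScoreModel) -> np.ndarray:
    """Per-pixel artery/vein labels from the component-1 threshold rule."""
    high = scores.scores[:, 0] >= model.threshold
    labels = np.where(
        high == model.artery_high, ARTERY, VEIN
    ).astype(np.uint8)
    return labels


def labels_to_map(
    labels: np.ndarray, coordinates: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Scatter per-pixel labels back into an H x W label map."""
    out = np.full(shape, BACKGROUND, dtype=np.uint8)
    out[coordinates[:, 0], coordinates[:, 1]] = labels
    return out


def render_overlay(img: np.ndarray, label_map: np.ndarray) -> np.ndarray:
    """Paint arteries pure red and veins pure blue over the image."""
    img = np.asarray(img, dtype=float)
    label_map = np.asarray(label_map)
    if img.shape[:2] != label_map.shape:
        raise ValueError("image and label map shapes differ")
    out = img.copy()
    out[label_map == ARTERY] = (1.0, 0.0, 0.0)
    out[label_map == VEIN] = (0.0, 0.0, 1.0)
    return out
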