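"""End-to-end orchestration: simulate -> segment -> calibrate -> reconstruct
-> classify -> evaluate, with an image-level 70/30 train/test split.

The split is at whole-image granularity (pixels of one image never appear
in both sets), score models are fitted per severity stage on training-image
vessel pixels, and test-image pixels are normalized with the training
min-max bounds.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classification import classify, fit_score_model, labels_to_map, project_scores, render_overlay
from .evaluation import ConfusionCounts, confusion_counts, metrics_table, stage_trend
from .io import save_image_png, save_labels_png, save_mask_png, save_model_json
from .optics import DEFAULT_CAMERA
from .reconstruction import fit_spectral_basis, fit_transformation, reconstruct_cube
from .segmentation import GaborParams, dice_coefficient, segment_vessels
from .synthetic import (
    ARTERY,
    STAGES,
    VEIN,
    PhantomGeometry,
    make_color_checker,
    make_phantom_fundus,
)

logger = logging.getLogger("fundushsi")


@dataclass
class RunConfig:
    """All tunables of an end-to-end synthetic run, YAML round-trippable."""

    seed: int = 0
    n_images_per_stage: int = 10
    test_fraction: float = 0.30
    image_size: int = 256
    noise_sd: float = 0.01
    # segmentation
    run_segmentation: bool = True
    f0: float = 1.0 / 6.0
    sigma_x: float = 1.75
    sigma_y: float = 1.75
    theta_step_deg: float = 1.0
    kernel_halfwidth: int = 8
    epsilon: float = 0.5
    min_pixels: int = 30
    # calibration
    ridge: float = 1e-6
    # classification
    threshold_method: str = "f1-scan"
    # stage contrast scales, normal..PDR
    contrast_scales: tuple[float, ...] = (1.0, 0.6, 0.45, 0.25)
    out_dir: str | None = None
    save_artifacts: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test fraction must lie in (0, 1)")

    def gabor_params(self) -> GaborParams:
        return GaborParams(
            f0=self.f0,
            sigma_x=self.sigma_x,
            sigma_y=self.sigma_y,
            theta_step=np.deg2rad(self.theta_step_deg),
            kernel_halfwidth=self.kernel_halfwidth,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrast_scales"] = list(self.contrast_scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "contrast_scales" in d:
            d["contrast_scales"] = tuple(d["contrast_scales"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    config: dict
    metrics: list[dict]
    trend: dict
    dice: dict[str, list[float]]
    files: list[str]
    version: str
    started: str
    finished: str


def split_train_test(items, fraction: float = 0.30, seed: int = 0):
    """Seeded, disjoint, exhaustive image-level split; test size = round(f*n)."""
    items = list(items)
    if len(items) < 2:
        raise ValueError("need at least 2 items to split")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_test = int(round(fraction * len(items)))
    test_idx = set(order[:n_test].tolist())
    train = [it for i, it in enumerate(items) if i not in test_idx]
    test = [it for i, it in enumerate(items) if i in test_idx]
    return train, test


def _stage_levels(cfg: RunConfig):
    from .synthetic import SeverityLevel

    names = [s.name for s in STAGES]
    return [SeverityLevel(n, c) for n, c in zip(names, cfg.contrast_scales)]


def run_pipeline(cfg: RunConfig, cam=DEFAULT_CAMERA) -> RunManifest:
    """Execute the full synthetic study and return a manifest.

    Per stage: generate ``n_images_per_stage`` phantoms, optionally segment
    them (Dice vs ground truth), reconstruct vessel-pixel spectra over the
    ground-truth mask, fit the stage score model on the training images'
    labeled pixels, classify the test images, and aggregate confusion
    counts into the per-stage metrics table.
    """
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    t0 = time.time()
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    geometry = PhantomGeometry(size=cfg.image_size)
    gp = cfg.gabor_params()

    checker = make_color_checker(cam, seed=cfg.seed)
    basis = fit_spectral_basis(checker.spectra, k=6, grid=cam.grid)
    m = fit_transformation(checker, basis, ridge=cfg.ridge)
    if out_dir:
        save_model_json(out_dir / "model.json", m, basis)
        files.append("model.json")
    logger.info("calibration fitted (%d patches, ridge=%g)", 24, cfg.ridge)

    results: dict[str, dict[int, ConfusionCounts]] = {}
    dice: dict[str, list[float]] = {}
    for stage_idx, stage in enumerate(_stage_levels(cfg)):
        t_stage = time.time()
        scenes = [
            make_phantom_fundus(
                stage=stage,
                geometry=geometry,
                cam=cam,
                noise_sd=cfg.noise_sd,
                seed=cfg.seed + 1000 * stage_idx + i,
            )
            for i in range(cfg.n_images_per_stage)
        ]
        train, test = split_train_test(
            scenes, fraction=cfg.test_fraction, seed=cfg.seed + stage_idx
        )
        if cfg.run_segmentation:
            dice[stage.name] = [
                dice_coefficient(
                    segment_vessels(
                        sc.image, gp, epsilon=cfg.epsilon,
                        min_pixels=cfg.min_pixels, fov=sc.fov_mask,
                    ),
                    sc.vessel_mask,
                )
                for sc in scenes
            ]

        train_cubes = [
            reconstruct_cube(sc.image, sc.vessel_mask, m, basis) for sc in train
        ]
        from .reconstruction import SpectralCube

        all_coords = np.concatenate([c.coordinates for c in train_cubes])
        all_spectra = np.concatenate([c.spectra for c in train_cubes])
        all_labels = np.concatenate(
            [
                sc.av_labels[c.coordinates[:, 0], c.coordinates[:, 1]]
                for sc, c in zip(train, train_cubes)
            ]
        )
        merged = SpectralCube(all_coords, all_spectra, basis.grid)
        model = fit_score_model(
            merged, all_labels, stage=stage, threshold_method=cfg.threshold_method
        )

        agg = {ARTERY: ConfusionCounts(0, 0, 0, 0), VEIN: ConfusionCounts(0, 0, 0, 0)}
        for j, sc in enumerate(test):
            cube = reconstruct_cube(sc.image, sc.vessel_mask, m, basis)
            scores = project_scores(cube, model)
            pred = labels_to_map(
                classify(scores, model), cube.coordinates, sc.av_labels.shape
            )
            for cls in (ARTERY, VEIN):
                agg[cls] = agg[cls] + confusion_counts(pred, sc.av_labels, cls)
            if out_dir and cfg.save_artifacts:
                stem = f"{stage.name}_test{j}"
                save_image_png(out_dir / f"{stem}_image.png", sc.image)
                save_labels_png(out_dir / f"{stem}_pred.png", pred)
                save_image_png(
                    out_dir / f"{stem}_overlay.png", render_overlay(sc.image, pred)
                )
                files += [f"{stem}_image.png", f"{stem}_pred.png", f"{stem}_overlay.png"]
        results[stage.name] = agg
        logger.info(
            "stage %s done in %.1fs (threshold %.3f, artery_high=%s)",
            stage.name, time.time() - t_stage, model.threshold, model.artery_high,
        )

    table = metrics_table(results)
    trend = stage_trend(table) if len(results) == 4 else {}
    metrics_records = table.to_dict(orient="records")
    if out_dir:
        (out_dir / "metrics.json").write_text(json.dumps(metrics_records, indent=2))
        table.to_csv(out_dir / "metrics.csv", index=False)
        files += ["metrics.json", "metrics.csv"]

    manifest = RunManifest(
        config=cfg.to_dict(),
        metrics=metrics_records,
        trend=trend,
        dice=dice,
        files=files,
        version=__version__,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    if out_dir:
        (out_dir / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(manifest), indent=2)
        )
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return manifest
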