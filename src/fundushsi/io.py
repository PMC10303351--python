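"""File I/O: images, masks, label maps, spectra tables, model JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .optics import WavelengthGrid
from .reconstruction import (
    RGBFeatureExpansion,
    SpectralBasis,
    SpectralCube,
    TransformationMatrix,
)
from .synthetic import ARTERY, BACKGROUND, VEIN, ColorCheckerSet, PhantomScene

LABEL_CODES = {BACKGROUND: 0, ARTERY: 128, VEIN: 255}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}


def save_image_png(path, img: np.ndarray) -> None:
    """8-bit RGB PNG from a float image in [0, 1]."""
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(path)


def load_image(path) -> np.ndarray:
    """RGB image as float in [0, 1] (PNG or TIFF; float TIFF via tifffile)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
        if arr.dtype.kind == "f":
            return np.asarray(arr, dtype=float)
        return np.asarray(arr, dtype=float) / 255.0
    arr = np.asarray(Image.open(path).convert("RGB"))
    return arr.astype(float) / 255.0


def save_image_tiff(path, img: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(img, dtype=np.float32))


def save_mask_png(path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)).save(
        path
    )


def load_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def save_labels_png(path, labels: np.ndarray) -> None:
    """0/128/255 coding for background/artery/vein."""
    coded = np.zeros(labels.shape, dtype=np.uint8)
    for lab, code in LABEL_CODES.items():
        coded[labels == lab] = code
    Image.fromarray(coded).save(path)


def load_labels_png(path) -> np.ndarray:
    coded = np.asarray(Image.open(path).convert("L"))
    out = np.zeros(coded.shape, dtype=np.uint8)
    # nearest-code decoding tolerates lossy viewers
    for code, lab in CODE_LABELS.items():
        out[np.abs(coded.astype(int) - code) <= 63] = lab
    return out


def save_checker_csv(spectra_path, rgb_path, checker: ColorCheckerSet) -> None:
    lam = checker.grid.values
    df = pd.DataFrame({"wavelength_nm": lam})
    for pid, spec in zip(checker.patch_ids, checker.spectra):
        df[pid] = spec
    df.to_csv(spectra_path, index=False)
    pd.DataFrame(checker.rgb, columns=["R", "G", "B"], index=checker.patch_ids).to_csv(
        rgb_path, index_label="patch"
    )


def load_checker_csv(spectra_path, rgb_path) -> ColorCheckerSet:
    df = pd.read_csv(spectra_path)
    lam = df["wavelength_nm"].to_numpy()
    step = float(lam[1] - lam[0])
    grid = WavelengthGrid(float(lam[0]), float(lam[-1]), step)
    ids = tuple(c for c in df.columns if c != "wavelength_nm")
    spectra = df[list(ids)].to_numpy().T
    rgb_df = pd.read_csv(rgb_path, index_col=0)
    rgb = rgb_df.loc[list(ids), ["R", "G", "B"]].to_numpy()
    return ColorCheckerSet(grid, spectra, rgb, ids)


def save_model_json(path, m: TransformationMatrix, basis: SpectralBasis) -> None:
    payload = {
        "grid": {
            "start": basis.grid.start,
            "stop": basis.grid.stop,
            "step": basis.grid.step,
        },
        "mean_spectrum": basis.mean_spectrum.tolist(),
        "eigenvectors": basis.eigenvectors.tolist(),
        "eigenvalues": basis.eigenvalues.tolist(),
        "expansion": list(m.expansion.terms),
        "M": m.M.tolist(),
        "ridge": m.ridge,
    }
    Path(path).write_text(json.dumps(payload))


def load_model_json(path) -> tuple[TransformationMatrix, SpectralBasis]:
    payload = json.loads(Path(path).read_text())
    g = payload["grid"]
    grid = WavelengthGrid(g["start"], g["stop"], g["step"])
    basis = SpectralBasis(
        grid,
        np.asarray(payload["mean_spectrum"]),
        np.asarray(payload["eigenvectors"]),
        np.asarray(payload["eigenvalues"]),
    )
    m = TransformationMatrix(
        np.asarray(payload["M"]),
        RGBFeatureExpansion(tuple(payload["expansion"])),
        payload["ridge"],
    )
    return m, basis


def save_cube_csv(path, cube: SpectralCube) -> None:
    lam = cube.grid.values
    cols = {"row": cube.coordinates[:, 0], "col": cube.coordinates[:, 1]}
    df = pd.DataFrame(cols)
    spec_df = pd.DataFrame(
        cube.spectra, columns=[f"r{int(round(w))}" for w in lam]
    )
    pd.concat([df, spec_df], axis=1).to_csv(path, index=False)


def save_scene(out_dir, scene: PhantomScene, name: str = "scene") -> dict:
    """Persist a phantom scene: image, masks, true spectra, JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {
        "image": f"{name}_image.png",
        "vessel_mask": f"{name}_vessel_mask.png",
        "av_labels": f"{name}_av_labels.png",
        "fov_mask": f"{name}_fov_mask.png",
        "spectra": f"{name}_true_spectra.csv",
        "meta": f"{name}_meta.json",
    }
    save_image_png(out_dir / files["image"], scene.image)
    save_mask_png(out_dir / files["vessel_mask"], scene.vessel_mask)
    save_labels_png(out_dir / files["av_labels"], scene.av_labels)
    save_mask_png(out_dir / files["fov_mask"], scene.fov_mask)
    pd.DataFrame(
        {
            "wavelength_nm": scene.artery_spectrum.grid.values,
            "artery": scene.artery_spectrum.values,
            "vein": scene.vein_spectrum.values,
        }
    ).to_csv(out_dir / files["spectra"], index=False)
    meta = {
        "seed": scene.seed,
        "stage": scene.stage.name,
        "contrast_scale": scene.stage.contrast_scale,
        "noise_sd": scene.noise_sd,
        "size": scene.geometry.size,
        "files": files,
    }
    (out_dir / files["meta"]).write_text(json.dumps(meta, indent=2))
    return meta
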