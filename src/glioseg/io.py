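"""Reading and writing images, label maps, models and reports.

Phantoms go to per-channel 8-bit PNGs (or a channel-stacked NIfTI) plus
a label image and a JSON manifest recording the seed and configuration;
probability maps are written as float NIfTI volumes; models serialize to
a single ``.npz`` archive with a JSON config manifest inside.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .network import NetConfig, SegModel
from .phantom import CHANNEL_NAMES, Phantom, TumorConfig

__all__ = [
    "load_image",
    "save_image",
    "save_phantom",
    "load_phantom",
    "save_probmap",
    "load_probmap",
    "save_model",
    "load_model",
]


def load_image(path: str | Path) -> np.ndarray:
    """Read a 2-D plane or channel stack from PNG or NIfTI."""
    path = Path(path)
    if path.suffix in {".nii", ".gz"}:
        data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        return np.transpose(data, (2, 0, 1)) if data.ndim == 3 else data
    return np.asarray(Image.open(path).convert("L"), dtype=float)


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a plane (PNG, 8-bit) or stack (NIfTI float)."""
    path = Path(path)
    if path.suffix in {".nii", ".gz"}:
        arr = np.asarray(image, dtype=np.float32)
        if arr.ndim == 3:  # channel-first to channel-last for NIfTI
            arr = np.transpose(arr, (1, 2, 0))
        nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))
    else:
        arr = np.clip(np.asarray(image), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(path)


def save_phantom(out_dir: str | Path, phantom: Phantom, stem: str = "phantom",
                 fmt: str = "png") -> Path:
    """Write channels + labels + manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "png":
        for c, name in enumerate(CHANNEL_NAMES):
            save_image(out / f"{stem}_{name}.png", phantom.channels[c])
        save_image(out / f"{stem}_labels.png", phantom.labels)
    elif fmt == "nii":
        save_image(out / f"{stem}_channels.nii", phantom.channels)
        save_image(out / f"{stem}_labels.nii",
                   phantom.labels[None].astype(np.float32))
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    manifest = {
        "stem": stem,
        "format": fmt,
        "seed": int(phantom.seed),
        "shape": list(phantom.shape),
        "channels": list(CHANNEL_NAMES),
        "config": dataclasses.asdict(phantom.config),
    }
    mpath = out / f"{stem}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def load_phantom(manifest_path: str | Path) -> Phantom:
    """Rebuild a phantom from a manifest written by :func:`save_phantom`."""
    mpath = Path(manifest_path)
    meta = json.loads(mpath.read_text())
    out, stem = mpath.parent, meta["stem"]
    if meta["format"] == "png":
        channels = np.stack([
            load_image(out / f"{stem}_{name}.png") for name in CHANNEL_NAMES
        ]).astype(np.uint8)
        labels = load_image(out / f"{stem}_labels.png").astype(np.uint8)
    else:
        channels = np.rint(load_image(out / f"{stem}_channels.nii")) \
            .astype(np.uint8)
        labels = np.rint(np.asarray(
            nib.load(str(out / f"{stem}_labels.nii")).dataobj
        )).astype(np.uint8).squeeze()
    return Phantom(channels=channels, labels=labels, seed=meta["seed"],
                   config=TumorConfig(**meta["config"]))


def save_probmap(path: str | Path, probmap: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(probmap, dtype=np.float32),
                             affine=np.eye(4)), str(path))


def load_probmap(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_model(path: str | Path, model: SegModel) -> None:
    """Serialize a trained segmenter to one portable .npz archive."""
    arrays = {
        "W": model.W,
        "b": model.b,
        "beta_out": model.beta_out,
        "classes": model.classes,
        "conv1": model.filters["conv1"],
        "conv2": model.filters["conv2"],
        "train_mse": np.array(model.train_mse),
    }
    if model.feature_mask is not None:
        arrays["feature_mask"] = model.feature_mask
    if model.logit_offsets is not None:
        arrays["logit_offsets"] = model.logit_offsets
    if model.gram is not None:
        arrays["gram"] = model.gram
        arrays["cross"] = model.cross
    arrays["config_json"] = np.frombuffer(
        json.dumps(dataclasses.asdict(model.config)).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_model(path: str | Path) -> SegModel:
    with np.load(str(path)) as z:
        cfg = NetConfig(**json.loads(bytes(z["config_json"]).decode()))
        return SegModel(
            W=z["W"], b=z["b"], beta_out=z["beta_out"], classes=z["classes"],
            config=cfg, filters={"conv1": z["conv1"], "conv2": z["conv2"]},
            feature_mask=z["feature_mask"] if "feature_mask" in z else None,
            logit_offsets=z["logit_offsets"] if "logit_offsets" in z else None,
            train_mse=float(z["train_mse"]),
            gram=z["gram"] if "gram" in z else None,
            cross=z["cross"] if "cross" in z else None,
        )
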