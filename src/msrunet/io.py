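"""Readers and writers for cases (PNG / NIfTI / NPZ), masks and checkpoints.

A *case* is an image, an optional integer label mask, and a pixel spacing.
Images are normalized to [0, 1].  For PNG and NIfTI, masks live in a
companion file ``<stem>_mask.<ext>``; NPZ files carry ``image`` and
(optionally) ``label`` arrays directly.  NIfTI volumes are returned as a
stack of 2D slices along axis 0.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = ["read_case", "write_mask", "save_checkpoint", "load_checkpoint"]


def _normalize(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    if hi > lo:
        image = (image - lo) / (hi - lo)
    else:
        image = np.zeros_like(image)
    return image


def _mask_companion(path: Path) -> Path | None:
    stem = path.name
    for ext in (".nii.gz", ".nii", ".png"):
        if stem.endswith(ext):
            cand = path.with_name(stem[: -len(ext)] + "_mask" + ext)
            return cand if cand.exists() else None
    return None


def read_case(path) -> tuple[np.ndarray, np.ndarray | None, tuple[float, float]]:
    """Load ``(image, mask, spacing)`` from a PNG, NIfTI or NPZ file.

    The image is float in [0, 1]; the mask (if present) is integer labels of
    the same shape; spacing is (row, col) in mm, defaulting to (1, 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    name = path.name
    if name.endswith(".npz"):
        data = np.load(path)
        if "image" not in data:
            raise ValueError(f"{path}: NPZ case needs an 'image' key")
        image = _normalize(data["image"])
        mask = data["label"].astype(np.int64) if "label" in data else None
        spacing = tuple(data["spacing"]) if "spacing" in data else (1.0, 1.0)
    elif name.endswith(".png"):
        arr = iio.imread(path)
        if arr.ndim == 3:  # RGB(A) -> luminance
            arr = arr[..., :3].mean(axis=-1)
        image = _normalize(arr)
        mpath = _mask_companion(path)
        mask = None
        if mpath is not None:
            mask = np.asarray(iio.imread(mpath)).astype(np.int64)
    elif name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        arr = np.asarray(img.get_fdata())
        image = _normalize(arr)
        zooms = img.header.get_zooms()
        spacing = tuple(float(z) for z in (zooms[1:3] if arr.ndim == 3 else zooms[:2]))
        mpath = _mask_companion(path)
        mask = None
        if mpath is not None:
            mask = np.asarray(nib.load(str(mpath)).get_fdata()).astype(np.int64)
    else:
        raise ValueError(
            f"{path}: unknown case format; expected .png, .nii(.gz) or .npz"
        )
    if name.endswith(".png"):
        spacing = (1.0, 1.0)
    if mask is not None and mask.shape != image.shape:
        raise ValueError(
            f"{path}: image shape {image.shape} does not match mask shape {mask.shape}"
        )
    return image, mask, tuple(float(s) for s in spacing)


def write_mask(path, mask: np.ndarray) -> None:
    """Write an integer label mask mirroring the extension of ``path``
    (PNG uses an identity grayscale palette: label value = pixel value)."""
    path = Path(path)
    mask = np.asarray(mask)
    if path.name.endswith(".png"):
        iio.imwrite(path, mask.astype(np.uint8))
    elif path.name.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(mask.astype(np.int16), affine=np.eye(4)), str(path))
    elif path.name.endswith(".npz"):
        np.savez(path, label=mask.astype(np.int64))
    else:
        raise ValueError(f"{path}: unknown mask format")


def save_checkpoint(path, model, config: dict) -> None:
    """Single-file checkpoint: parameter arrays + embedded JSON config."""
    state = model.state_dict()
    arrays = {f"param::{k}": v for k, v in state.items()}
    arrays["config_json"] = np.frombuffer(
        json.dumps(config).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[dict, dict]:
    """Return ``(state_dict, config)`` from a checkpoint file."""
    data = np.load(path)
    config = json.loads(bytes(data["config_json"]).decode())
    state = {
        k[len("param::") :]: data[k] for k in data.files if k.startswith("param::")
    }
    return state, config
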