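"""Readers and writers for grayscale images, binary masks and probability maps.

Supported raster formats: PNG (8/16-bit grayscale), TIFF (8/16-bit integer or
float32 grayscale) and NIfTI-1 (single slice, or a volume with an explicit
slice index along the axial axis).  Intensities are always mapped to [0, 1]
on read; masks are strict {0, 255} (PNG/TIFF) or {0, 1} (NIfTI) — anything
in between is an error, never silently thresholded.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
from PIL import Image


class ImageIOError(ValueError):
    pass


_PNG_EXT = {".png"}
_TIFF_EXT = {".tif", ".tiff"}


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def read_image(path: str | Path, slice_index: int | None = None) -> np.ndarray:
    """Read a grayscale image as float64 in [0, 1].

    NIfTI volumes require ``slice_index`` (0-based, axial axis = last axis);
    single-slice NIfTI files need none.  RGB inputs are rejected, not
    converted.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    if _is_nifti(path):
        data = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
        if data.ndim == 3:
            if data.shape[2] == 1:
                data = data[:, :, 0]
            elif slice_index is None:
                raise ImageIOError(f"volume {path} has {data.shape[2]} slices; slice_index required")
            else:
                if not (0 <= slice_index < data.shape[2]):
                    raise ImageIOError(f"slice_index {slice_index} out of range for {path}")
                data = data[:, :, slice_index]
        if data.ndim != 2:
            raise ImageIOError(f"{path}: expected 2-D or 3-D NIfTI, got {data.ndim}-D")
        lo, hi = float(data.min()), float(data.max())
        return (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    if path.suffix.lower() in _TIFF_EXT:
        arr = tifffile.imread(str(path))
        if arr.ndim != 2:
            raise ImageIOError(f"{path}: grayscale required, got shape {arr.shape}")
        if np.issubdtype(arr.dtype, np.floating):
            return arr.astype(float)
        return arr.astype(float) / np.iinfo(arr.dtype).max
    if path.suffix.lower() in _PNG_EXT:
        img = Image.open(path)
        if img.mode in ("RGB", "RGBA", "P"):
            raise ImageIOError(f"{path}: grayscale required, got mode {img.mode}")
        arr = np.asarray(img)
        if arr.ndim != 2:
            raise ImageIOError(f"{path}: grayscale required, got shape {arr.shape}")
        maxval = 65535 if arr.dtype == np.uint16 else 255
        return arr.astype(float) / maxval
    raise ImageIOError(f"unsupported image format: {path}")


def write_image(image: np.ndarray, path: str | Path) -> Path:
    """Write a [0, 1] image: 16-bit PNG, float32 TIFF, or float32 NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ImageIOError(f"expected 2-D image, got shape {image.shape}")
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(image.astype(np.float32), np.eye(4)), str(path))
    elif path.suffix.lower() in _TIFF_EXT:
        tifffile.imwrite(str(path), image.astype(np.float32))
    elif path.suffix.lower() in _PNG_EXT:
        arr = np.round(np.clip(image, 0, 1) * 65535).astype(np.uint16)
        Image.fromarray(arr).save(path)
    else:
        raise ImageIOError(f"unsupported image format: {path}")
    return path


def read_mask(path: str | Path, slice_index: int | None = None) -> np.ndarray:
    """Read a binary mask as uint8 {0, 1}.

    PNG/TIFF masks must be exactly {0, 255}; NIfTI masks exactly {0, 1}.
    Intermediate values raise — no silent thresholding.
    """
    path = Path(path)
    if _is_nifti(path):
        data = np.asanyarray(nib.load(str(path)).dataobj)
        if data.ndim == 3:
            data = data[:, :, 0 if slice_index is None else slice_index]
        vals = np.unique(data)
        if not np.isin(vals, [0, 1]).all():
            raise ImageIOError(f"{path}: mask values must be {{0,1}}, found {vals[:8]}")
        return data.astype(np.uint8)
    if path.suffix.lower() in (_PNG_EXT | _TIFF_EXT):
        if path.suffix.lower() in _TIFF_EXT:
            arr = tifffile.imread(str(path))
        else:
            img = Image.open(path)
            if img.mode not in ("L", "I;16", "I", "1"):
                raise ImageIOError(f"{path}: grayscale mask required, got mode {img.mode}")
            arr = np.asarray(img)
        vals = np.unique(arr)
        if not np.isin(vals, [0, 255]).all():
            raise ImageIOError(f"{path}: mask values must be {{0,255}}, found {vals[:8]}")
        return (arr == 255).astype(np.uint8)
    raise ImageIOError(f"unsupported mask format: {path}")


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a {0, 1} mask: 8-bit 0/255 PNG/TIFF, or uint8 NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.isin(vals, [0, 1]).all():
        raise ImageIOError(f"mask values must be {{0,1}}, found {vals[:8]}")
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), str(path))
    elif path.suffix.lower() in (_PNG_EXT | _TIFF_EXT):
        arr = (mask.astype(np.uint8) * 255).astype(np.uint8)
        if path.suffix.lower() in _TIFF_EXT:
            tifffile.imwrite(str(path), arr)
        else:
            Image.fromarray(arr, mode="L").save(path)
    else:
        raise ImageIOError(f"unsupported mask format: {path}")
    return path


def write_probability_map(prob_map: np.ndarray, path: str | Path) -> Path:
    """Persist a (K, H, W) probability map as float32 NIfTI (channels last)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.moveaxis(np.asarray(prob_map, dtype=np.float32), 0, -1)
    nib.save(nib.Nifti1Image(arr, np.eye(4)), str(path))
    return path


def read_probability_map(path: str | Path) -> np.ndarray:
    arr = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    return np.moveaxis(arr, -1, 0)


def file_checksum(path: str | Path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
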