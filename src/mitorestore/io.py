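"""TIFF image I/O with float widening and optional 16-bit quantization."""

from __future__ import annotations

import json

import numpy as np
import tifffile

__all__ = ["read_image", "write_image", "read_pixel_size"]


def read_image(path) -> np.ndarray:
    """Read a grayscale TIFF as float64; multi-page files become (P, H, W).

    Integer data are widened to float with values preserved exactly.
    RGB/multichannel pages are rejected.
    """
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError(
            f"{path}: multichannel image with {arr.shape[-1]} samples per pixel; "
            "only single-channel grayscale TIFF is supported"
        )
    if arr.ndim not in (2, 3):
        raise ValueError(f"{path}: unsupported TIFF layout with shape {arr.shape}")
    return np.asarray(arr, dtype=np.float64)


def read_pixel_size(path) -> float | None:
    """Pixel size in nm from TIFF resolution tags, if present."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is None:
            return None
        num, den = res.value
        if num == 0:
            return None
        per_unit = num / den  # pixels per unit
        unit_val = int(unit.value) if unit is not None else 0
        unit_nm = {2: 2.54e7, 3: 1e7}.get(unit_val)  # inch, cm
        if unit_nm is None:
            return None
        return unit_nm / per_unit


def write_image(arrays: np.ndarray, path, dtype: str = "float32") -> None:
    """Write one image or a stack as (multi-page) TIFF.

    ``dtype='uint16'`` quantizes linearly over [min, max]; the mapping is
    recorded in the TIFF description for inversion.
    """
    arr = np.asarray(arrays)
    if arr.size == 0:
        raise ValueError("refusing to write an empty image stack")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains NaN or Inf")
    if dtype == "float32":
        tifffile.imwrite(path, arr.astype(np.float32))
    elif dtype == "uint16":
        lo, hi = float(arr.min()), float(arr.max())
        scale = (hi - lo) or 1.0
        q = np.round((arr - lo) / scale * 65535).astype(np.uint16)
        desc = json.dumps({"quantization": {"min": lo, "max": hi}})
        tifffile.imwrite(path, q, description=desc)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
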