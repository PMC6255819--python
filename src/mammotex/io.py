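"""Raster and table I/O.

Images travel through the pipeline as float64 arrays in [0, 1].  On disk
they are single-channel 8- or 16-bit PNG or PGM; 16-bit is preferred for
synthesis outputs so quantization does not mask Gram differences.
Quantization is linear with round-half-up and is validated, never silently
clipped.  Tables are UTF-8 CSV with a header row.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import InputError

__all__ = ["read_image", "write_image", "read_table", "write_table", "sha256_file"]

log = logging.getLogger("mammotex")


def read_image(path) -> np.ndarray:
    """Read an 8- or 16-bit raster as a [0, 1] float image.

    Multi-channel inputs are converted by averaging the channels
    (luminance average) with a logged warning.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        log.warning("multi-channel image %s converted by channel average", path)
        arr = arr.mean(axis=2)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype in (np.uint16, np.int32):  # PIL mode I;16 may load as I (int32)
        return arr.astype(float) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(float)
    raise InputError(f"unsupported raster dtype {arr.dtype} in {path}")


def write_image(image, path, depth: int = 16) -> Path:
    """Write a [0, 1] image as an 8- or 16-bit grayscale PNG/PGM.

    Values outside [0, 1] are a validation error — silent clipping could
    hide synthesis bugs.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InputError("write_image expects a 2-D grayscale image")
    if not np.isfinite(img).all() or img.min() < 0.0 or img.max() > 1.0:
        raise InputError("image values must be finite and within [0, 1]")
    if depth not in (8, 16):
        raise InputError("depth must be 8 or 16")
    path = Path(path)
    scale = 255 if depth == 8 else 65535
    q = np.floor(img * scale + 0.5).astype(np.uint8 if depth == 8 else np.uint16)
    if depth == 8:
        Image.fromarray(q, mode="L").save(path)
    else:
        if path.suffix.lower() == ".pgm":
            _write_pgm16(q, path)
        else:
            Image.fromarray(q.astype("<u2")).save(path)
    return path


def _write_pgm16(q: np.ndarray, path: Path):
    with open(path, "wb") as fh:
        fh.write(f"P5\n{q.shape[1]} {q.shape[0]}\n65535\n".encode())
        fh.write(q.astype(">u2").tobytes())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
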