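"""File I/O: raster images, plain-text float matrices, YAML parameter files."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .retina import LuminanceImage, RetinaParams


def read_image(path: str | Path) -> LuminanceImage:
    """Read an 8- or 16-bit PNG/JPEG as a LuminanceImage.

    The luminance ceiling is set from the sample depth (255 or 65535); an
    alpha channel, if present, is dropped.
    """
    raw = iio.imread(path)
    arr = np.asarray(raw)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.ndim == 3 and arr.shape[2] not in (1, 3):
        raise ValueError(f"unsupported channel count {arr.shape[2]} in {path}")
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        vmax = 255.0
    elif arr.dtype == np.uint16:
        vmax = 65535.0
    else:
        arr = arr.astype(np.float64)
        vmax = max(float(arr.max()), 1.0)
    return LuminanceImage(arr.astype(np.float64), vmax)


def write_image(path: str | Path, values: np.ndarray, vmax: float = 1.0) -> None:
    """Write a raster as 8-bit PNG, scaling ``[0, vmax]`` to ``[0, 255]``."""
    scaled = np.clip(np.asarray(values, dtype=np.float64) / vmax, 0.0, 1.0)
    iio.imwrite(Path(path), (scaled * 255.0 + 0.5).astype(np.uint8))


def write_matrix(path: str | Path, values: np.ndarray) -> None:
    """Lossless plain-text float matrix (one row per line)."""
    np.savetxt(path, np.asarray(values, dtype=np.float64))


def read_matrix(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path))


def read_density(path: str | Path) -> np.ndarray:
    """Read a density/saliency raster from a text matrix or a PNG."""
    if str(path).lower().endswith((".png", ".jpg", ".jpeg")):
        return read_image(path).luminance()
    return read_matrix(path)


def load_retina_params(path: str | Path | None) -> RetinaParams:
    """Load RetinaParams from YAML; keys mirror the field names exactly."""
    if path is None:
        return RetinaParams()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RetinaParams(**data)
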