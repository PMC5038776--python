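"""Reading and writing the image formats the tool accepts (PNG/TIFF)."""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_grayscale",
    "write_grayscale",
    "write_float_tiff",
    "read_fused",
    "write_pulse_frames",
]

# ITU-R BT.601 luminance weights, the standard grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])

_SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff"}


def _check_path(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"image file not found: {p}")
    if p.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(
            f"unsupported format {p.suffix!r} for {p}: expected PNG or TIFF"
        )
    return p


def read_grayscale(path, to_gray: bool = False, allow_16bit: bool = False) -> np.ndarray:
    """Read a PNG/TIFF as an 8-bit grayscale array.

    RGB(A) input is rejected unless ``to_gray`` converts it with BT.601
    luminance weights; 16-bit input is rejected unless ``allow_16bit``
    rescales it to 8 bits.
    """
    p = _check_path(path)
    arr = iio.imread(p)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ValueError(f"unsupported channel count {arr.shape[2]} in {p}")
        if not to_gray:
            raise ValueError(
                f"{p} is multi-channel; pass to_gray=True (--to-gray) to convert"
            )
        arr = arr[:, :, :3].astype(np.float64) @ _LUMA
        arr = np.rint(arr)
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image in {p}, got shape {arr.shape}")

    if arr.dtype == np.uint16:
        if not allow_16bit:
            raise ValueError(
                f"{p} is 16-bit; pass allow_16bit=True (--allow-16bit) to rescale"
            )
        arr = arr.astype(np.float64) * (255.0 / 65535.0)
        arr = np.rint(arr)
    return np.clip(arr, 0, 255).astype(np.uint8)


def write_grayscale(path, image: np.ndarray) -> None:
    """Write an 8-bit grayscale array as PNG/TIFF."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    iio.imwrite(Path(path), arr.astype(np.uint8))


def write_float_tiff(path, values: np.ndarray) -> None:
    """Write unquantized floating-point values as a 32-bit TIFF."""
    iio.imwrite(Path(path), np.asarray(values, dtype=np.float32))


def read_fused(path, allow_16bit: bool = False) -> tuple[np.ndarray, str]:
    """Read a fused image, preserving float TIFF values when present.

    Returns ``(array, source)`` where source is ``"float"`` for floating-point
    TIFF input (unquantized values, used as-is) or ``"uint8"`` otherwise.
    """
    p = _check_path(path)
    arr = iio.imread(p)
    if arr.ndim == 2 and np.issubdtype(arr.dtype, np.floating):
        return arr.astype(np.float64), "float"
    return read_grayscale(p, allow_16bit=allow_16bit).astype(np.float64), "uint8"


def write_pulse_frames(directory, pulses: np.ndarray, prefix: str = "pulse") -> list[str]:
    """Export a binary pulse series as numbered PNG frames (debug aid)."""
    directory = Path(directory)
    os.makedirs(directory, exist_ok=True)
    paths = []
    for n, frame in enumerate(np.asarray(pulses), start=1):
        out = directory / f"{prefix}_{n:03d}.png"
        iio.imwrite(out, (frame.astype(np.uint8) * 255))
        paths.append(str(out))
    return paths
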