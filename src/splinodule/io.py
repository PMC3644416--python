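"""Image and stack readers/writers.

Supported formats are single-channel 8- or 16-bit PNG and TIFF.  Images are
kept in their stored integer range (0-255 or 0-65535) as ``float64`` arrays
internally; writing quantizes (round + clip) to the requested bit depth, so a
write/read round trip of integer-valued data is lossless.  DICOM is
deliberately unsupported: PNG/TIFF keep the package dependency-light and fully
testable from generated data.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError

__all__ = ["read_image", "read_stack", "write_image"]

_EXTENSIONS = (".png", ".tif", ".tiff")


def read_image(path) -> np.ndarray:
    """Read a single-channel 8/16-bit PNG or TIFF as a float 2D array."""
    path = Path(path)
    if path.suffix.lower() not in _EXTENSIONS:
        raise FormatError(
            f"unsupported extension {path.suffix!r}; expected one of {_EXTENSIONS}"
        )
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(
            f"{path} has shape {arr.shape}; expected a single-channel 2D image "
            "(convert RGB(A) inputs to grayscale first)"
        )
    if arr.dtype not in (np.uint8, np.uint16):
        raise FormatError(
            f"{path} has dtype {arr.dtype}; expected 8-bit or 16-bit unsigned"
        )
    return arr.astype(np.float64)


def write_image(image, path, bit_depth: int = 8) -> None:
    """Write a 2D array as 8- or 16-bit PNG/TIFF, rounding and clipping."""
    path = Path(path)
    if path.suffix.lower() not in _EXTENSIONS:
        raise FormatError(
            f"unsupported extension {path.suffix!r}; expected one of {_EXTENSIONS}"
        )
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise FormatError(f"expected a 2D image, got shape {image.shape}")
    if bit_depth == 8:
        out = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        out = np.clip(np.rint(image), 0, 65535).astype(np.uint16)
    else:
        raise FormatError(f"bit_depth must be 8 or 16, got {bit_depth}")
    iio.imwrite(path, out)


def read_stack(directory) -> np.ndarray:
    """Read an ordered slice stack from a directory of same-shape images.

    Slice order is the lexicographic order of the file names; the returned
    array has shape ``(n_slices, H, W)``.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FormatError(f"{directory} is not a directory")
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _EXTENSIONS
    )
    if not paths:
        raise FormatError(f"no PNG/TIFF slices found in {directory}")
    slices = [read_image(p) for p in paths]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise FormatError(f"slice shapes differ in {directory}: {sorted(shapes)}")
    return np.stack(slices)
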