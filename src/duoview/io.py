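"""Multi-page TIFF readers/writers for stacks and label volumes."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError, IOFailure, ValidationError
from .stack import LabelVolume, VolumeStack


def read_volume(
    path: str | Path,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    view_id: str = "view1",
) -> VolumeStack:
    """Read a multi-page TIFF into a :class:`VolumeStack`.

    Pages map to z-planes; pixel data is promoted to float64.  2D files are
    treated as single-plane stacks.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except FileNotFoundError as exc:
        raise IOFailure(f"no such file: {path}") from exc
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"not a readable TIFF: {path} ({exc})") from exc
    except OSError as exc:
        raise IOFailure(f"cannot read {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3 or data.size == 0:
        raise FormatError(
            f"{path}: expected a 3D (pages, y, x) TIFF, got shape {data.shape}"
        )
    return VolumeStack(data=data.astype(np.float64), spacing=spacing, view_id=view_id)


def write_volume(stack: VolumeStack, path: str | Path, dtype=np.float32) -> Path:
    """Write a stack as a multi-page TIFF (one page per z-plane)."""
    path = Path(path)
    if not np.all(np.isfinite(stack.data)):
        raise ValidationError("stack contains non-finite values; refusing to write")
    try:
        tifffile.imwrite(path, stack.data.astype(dtype), photometric="minisblack")
    except OSError as exc:
        raise IOFailure(f"cannot write {path}: {exc}") from exc
    return path


def read_labels(
    path: str | Path, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> LabelVolume:
    """Read an integer multi-page TIFF as a label volume."""
    stack = read_volume(path, spacing)
    return LabelVolume(labels=stack.data, spacing=spacing)


def write_labels(volume: LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    try:
        tifffile.imwrite(path, volume.labels.astype(np.int32), photometric="minisblack")
    except OSError as exc:
        raise IOFailure(f"cannot write {path}: {exc}") from exc
    return path
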