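"""In-memory containers for image stacks and label volumes.

All volumetric data in this package is indexed ``(z, y, x)`` with ``z`` the
detection axis and plane 0 the first acquired page.  Physical voxel spacing is
carried alongside the array in micrometres per axis, in the same ``(z, y, x)``
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

#: Recognised origins of a stack.
VIEW_IDS = ("view1", "view2", "fused")


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValidationError(f"spacing must have 3 components, got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValidationError(f"spacing components must be positive, got {spacing}")
    return spacing


@dataclass
class VolumeStack:
    """A 3D intensity stack with physical voxel spacing.

    Parameters
    ----------
    data:
        3D array indexed ``(z, y, x)``.  Promoted to floating point on
        construction so downstream arithmetic is exact.
    spacing:
        Voxel size in µm per axis, ``(z, y, x)`` order.
    view_id:
        Which detection arm (or fusion product) the stack comes from.
    time_index, channel:
        Optional acquisition coordinates for 4D/5D experiments.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    view_id: str = "view1"
    time_index: int | None = None
    channel: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(
                f"stack data must be 3D (z, y, x), got ndim={self.data.ndim}"
            )
        if any(s < 1 for s in self.data.shape):
            raise ValidationError(f"all dimensions must be >= 1, got {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("stack intensities must be finite")
        self.spacing = _check_spacing(self.spacing)
        if self.view_id not in VIEW_IDS:
            raise ValidationError(
                f"view_id must be one of {VIEW_IDS}, got {self.view_id!r}"
            )
        if self.time_index is not None and self.time_index < 0:
            raise ValidationError("time_index must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    def with_data(self, data: np.ndarray, **changes) -> "VolumeStack":
        """Copy of this stack with new voxel data (same geometry)."""
        return replace(self, data=data, **changes)


@dataclass
class LabelVolume:
    """A 3D integer label image; 0 is background and never a region."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError(
                f"label volume must be 3D, got ndim={self.labels.ndim}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValidationError("labels must be integer-valued")
            self.labels = self.labels.astype(np.int64)
        if self.labels.min() < 0:
            raise ValidationError("labels must be non-negative")
        self.spacing = _check_spacing(self.spacing)

    @property
    def ids(self) -> np.ndarray:
        """Sorted nonzero label ids present in the volume."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))
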