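"""Rigid 3D registration and resampling between the two detection views.

A :class:`RigidTransform` maps a physical point ``p`` (µm) of the fixed frame
to the point ``R (p - c) + c + t`` of the moving frame: resampling the moving
stack through the transform expresses it on the fixed grid.  Angles are Euler
angles in degrees about the z, y and x axes (matrix ``Rz @ Ry @ Rx`` in
physical xyz coordinates); translations and the rotation center are µm triples
in the package's (z, y, x) order.

Registration itself maximises Mattes mutual information under a 3-level
multi-resolution schedule with exhaustive (non-stochastic) metric sampling, so
the result is deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .config import RunConfig
from .errors import ConvergenceError, ValidationError
from .stack import VolumeStack

_PERM = (2, 1, 0)  # (z, y, x) <-> (x, y, z)


def _to_xyz(v):
    return np.asarray(v, dtype=float)[::-1]


@dataclass
class RigidTransform:
    """6-DOF rigid-body transform (rotation + translation) in physical µm."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)  # about z, y, x
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (z, y, x) µm
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (z, y, x) µm

    def __post_init__(self) -> None:
        for name in ("rotation_deg", "translation", "center"):
            v = tuple(float(x) for x in getattr(self, name))
            if len(v) != 3 or not all(np.isfinite(v)):
                raise ValidationError(f"{name} must be a finite triple")
            setattr(self, name, v)

    # -- matrix plumbing ---------------------------------------------------
    def rotation_matrix_xyz(self) -> np.ndarray:
        """3x3 rotation matrix acting on (x, y, z) physical coordinates."""
        return Rotation.from_euler("ZYX", self.rotation_deg, degrees=True).as_matrix()

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix acting on (z, y, x) physical coordinates."""
        r_xyz = self.rotation_matrix_xyz()
        r = r_xyz[np.ix_(_PERM, _PERM)]
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = c + t - r @ c
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        r = np.asarray(m)[:3, :3]
        r_xyz = r[np.ix_(_PERM, _PERM)]
        angles = Rotation.from_matrix(r_xyz).as_euler("ZYX", degrees=True)
        c = np.asarray(center, dtype=float)
        offset = np.asarray(m)[:3, 3]
        t = offset - c + r @ c
        return cls(tuple(angles), tuple(t), tuple(c))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 3) physical (z, y, x) points through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        m = self.as_matrix()
        return pts @ m[:3, :3].T + m[:3, 3]

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform.from_matrix(
            self.as_matrix() @ other.as_matrix(), center=self.center
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(
            np.linalg.inv(self.as_matrix()), center=self.center
        )

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.as_matrix(), np.eye(4), atol=1e-9)


def flip_opposing_view(stack: VolumeStack, flip_axes) -> VolumeStack:
    """Reverse the listed axes of a stack (the opposing view's mirror).

    ``flip_axes`` is a subset of {"z", "x"}; an empty set is the identity.
    """
    axes = tuple(flip_axes)
    if not set(axes) <= {"z", "x"}:
        raise ValidationError(f"flip_axes must be a subset of {{'z', 'x'}}, got {axes}")
    data = stack.data
    for ax in axes:
        data = np.flip(data, axis={"z": 0, "x": 2}[ax])
    return stack.with_data(np.ascontiguousarray(data))


def resample(
    stack: VolumeStack,
    transform: RigidTransform,
    background: float = 0.0,
) -> VolumeStack:
    """Trilinearly resample a stack through a rigid transform.

    Output voxel ``v`` takes the input intensity at the transformed physical
    position; out-of-bounds samples are filled with ``background``.
    """
    m = transform.as_matrix()
    if not np.all(np.isfinite(m)):
        raise ValidationError("transform is not finite")
    s = np.asarray(stack.spacing)
    mat = m[:3, :3] * (s[None, :] / s[:, None])  # S^-1 R S
    offset = m[:3, 3] / s
    if transform.is_identity:
        return stack.with_data(stack.data.copy())
    out = ndimage.affine_transform(
        stack.data, mat, offset=offset, order=1, mode="constant", cval=background
    )
    return stack.with_data(out)


def _as_sitk(stack: VolumeStack) -> sitk.Image:
    img = sitk.GetImageFromArray(stack.data.astype(np.float32))
    img.SetSpacing(tuple(float(s) for s in stack.spacing[::-1]))
    return img


def register_rigid(
    moving: VolumeStack,
    fixed: VolumeStack,
    config: RunConfig | None = None,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Maximises Mattes mutual information (32 bins, exhaustive sampling) with a
    regular-step gradient descent over a shrink 4/2/1 pyramid.  Returns the
    transform such that ``resample(moving, transform)`` overlays ``fixed``.
    """
    config = config or RunConfig()
    if moving.spacing != fixed.spacing:
        raise ValidationError(
            f"voxel spacing differs: moving {moving.spacing} vs fixed {fixed.spacing}"
        )
    if np.ptp(moving.data) == 0 or np.ptp(fixed.data) == 0:
        raise ConvergenceError("cannot register constant images (no structure)")

    f_img, m_img = _as_sitk(fixed), _as_sitk(moving)

    tx = sitk.Euler3DTransform()
    tx.SetComputeZYX(True)
    center_idx = [(sz - 1) / 2.0 for sz in f_img.GetSize()]
    center_xyz = f_img.TransformContinuousIndexToPhysicalPoint(center_idx)
    tx.SetCenter(center_xyz)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=config.registration_min_step,
        numberOfIterations=config.registration_iterations,
        relaxationFactor=0.5,
        gradientMagnitudeTolerance=1e-8,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2, 1, 0])
    reg.SetInitialTransform(tx, inPlace=True)
    try:
        reg.Execute(f_img, m_img)
    except RuntimeError as exc:
        raise ConvergenceError(f"registration failed: {exc}") from exc
    metric = reg.GetMetricValue()
    if not np.isfinite(metric):
        raise ConvergenceError(f"registration diverged (final metric {metric})")

    ax, ay, az = tx.GetAngleX(), tx.GetAngleY(), tx.GetAngleZ()  # radians
    t_xyz = np.asarray(tx.GetTranslation())
    c_xyz = np.asarray(tx.GetCenter())
    return RigidTransform(
        rotation_deg=tuple(np.degrees([az, ay, ax])),
        translation=tuple(t_xyz[::-1]),
        center=tuple(c_xyz[::-1]),
    )
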