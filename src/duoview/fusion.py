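"""Fuse two opposing detection views into one stack.

Each view degrades with imaging depth in its own direction, so at every depth
one view is sharper.  The switching plane is the depth where the opposing
view's focus score overtakes the near view's; the two stacks are blended with
a sigmoid centered there, and a constant camera background is subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .quality import QualityProfile
from .registration import RigidTransform
from .stack import VolumeStack


@dataclass
class FusionPlan:
    """Everything needed to reproduce one fusion: geometry and blending."""

    z_switch: int
    slope: float = 3.0
    background: float = 0.0
    transform: RigidTransform = field(default_factory=RigidTransform)
    flip_axes: tuple[str, ...] = ("z",)

    def __post_init__(self) -> None:
        if self.z_switch < 0:
            raise ValidationError("z_switch must be >= 0")
        if not self.slope > 0:
            raise ValidationError("slope must be > 0")
        if self.background < 0:
            raise ValidationError("background must be >= 0")
        self.flip_axes = tuple(self.flip_axes)
        if not set(self.flip_axes) <= {"z", "x"}:
            raise ValidationError("flip_axes must be a subset of {'z', 'x'}")


def find_switch_plane(p1: QualityProfile, p2: QualityProfile) -> int:
    """First plane where the opposing view's quality overtakes the near view.

    The dominant near-side view is decided by the comparison at plane 0; the
    returned index is the smallest z where that dominance flips (ties break
    toward the smaller index).  Without any crossover the better single view
    wins outright: plane 0 when view 2 dominates everywhere, the last plane
    when view 1 does.
    """
    if len(p1) != len(p2):
        raise ValidationError(
            f"profile lengths differ: {len(p1)} vs {len(p2)}"
        )
    if len(p1) < 2:
        raise ValidationError("profiles must cover at least 2 planes")
    diff = p1.scores - p2.scores
    dominant = np.sign(diff[0])
    if dominant == 0:
        return 0
    crossed = np.flatnonzero(diff * dominant <= 0)
    if crossed.size:
        return int(crossed[0])
    # no crossover: degenerate to the everywhere-better view
    return len(p1) - 1 if dominant > 0 else 0


def sigmoid_weights(
    n_planes: int, z_switch: float, slope: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-plane blending weights ``(w1, w2)`` with ``w1 + w2 = 1``.

    ``w2(z) = 1 / (1 + exp(-(z - z_switch) / slope))`` rises from 0 to 1
    through 0.5 at the switching plane; view 1 carries the shallow planes.
    """
    if not slope > 0:
        raise ValidationError("slope must be > 0")
    if n_planes < 1:
        raise ValidationError("n_planes must be >= 1")
    z = np.arange(n_planes, dtype=float)
    # clip the exponent to avoid overflow; weights saturate anyway
    arg = np.clip(-(z - z_switch) / slope, -700, 700)
    w2 = 1.0 / (1.0 + np.exp(arg))
    return 1.0 - w2, w2


def fuse_stacks(
    view1: VolumeStack, view2: VolumeStack, plan: FusionPlan
) -> VolumeStack:
    """Sigmoid-blend two aligned views and subtract the camera background.

    ``view2`` must already be flipped and resampled into ``view1``'s frame.
    Negative intensities after background subtraction are clipped to zero.
    """
    if view1.shape != view2.shape:
        raise ValidationError(
            f"shape mismatch: view1 {view1.shape} vs view2 {view2.shape}"
        )
    if plan.z_switch >= view1.n_planes:
        raise ValidationError(
            f"z_switch {plan.z_switch} outside stack of {view1.n_planes} planes"
        )
    w1, w2 = sigmoid_weights(view1.n_planes, plan.z_switch, plan.slope)
    fused = (
        w1[:, None, None] * view1.data
        + w2[:, None, None] * view2.data
        - plan.background
    )
    np.clip(fused, 0.0, None, out=fused)
    return view1.with_data(fused, view_id="fused")
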