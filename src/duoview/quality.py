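"""Per-plane focus scoring: Shannon entropy of the normalized DCT (DCTS).

Each z-plane of a stack is scored independently.  A sharp plane spreads
spectral power over many DCT coefficients and scores high; blurring
concentrates power at low frequencies and lowers the score.  The score is
invariant to multiplying the image by a positive constant, so depth-dependent
attenuation does not move the view crossover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as _fft

from .errors import ValidationError
from .stack import VolumeStack


@dataclass
class QualityProfile:
    """One focus score per z-plane of a single view."""

    scores: np.ndarray
    view_id: str = "view1"
    smoothing_window: int = 1

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValidationError("scores must be a 1D sequence")
        if not np.all(np.isfinite(self.scores)) or np.any(self.scores < 0):
            raise ValidationError("scores must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.scores)


def _support_mask(shape: tuple[int, int], support_fraction: float) -> np.ndarray:
    h, w = shape
    radius = support_fraction * np.hypot(h, w)
    ii, jj = np.ogrid[0:h, 0:w]
    return (ii * ii + jj * jj) <= radius * radius


def dcts_plane(
    plane: np.ndarray,
    support_fraction: float = 1.0,
    *,
    subtract_mean: bool = True,
    norm: str = "power",
) -> float:
    """Shannon entropy of the normalized 2D DCT of one plane.

    The plane is (optionally) mean-subtracted, transformed with a type-II
    orthonormal DCT, restricted to the quarter-disk of radius
    ``support_fraction * sqrt(H^2 + W^2)`` in coefficient index space, and the
    retained coefficients are normalised to a distribution
    ``p_k = c_k^2 / sum_j c_j^2`` (``norm="power"``) or
    ``p_k = |c_k| / sum_j |c_j|`` (``norm="l2"`` uses magnitudes over their
    sum).  Returns ``H = -sum p_k ln p_k``; an all-zero plane scores 0.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValidationError(f"plane must be 2D, got ndim={plane.ndim}")
    if plane.shape[0] < 4 or plane.shape[1] < 4:
        raise ValidationError(f"plane must be at least 4x4, got {plane.shape}")
    if not np.all(np.isfinite(plane)):
        raise ValidationError("plane contains non-finite pixels")
    if not 0 < support_fraction <= 1:
        raise ValidationError("support_fraction must be in (0, 1]")
    if norm not in ("power", "l2"):
        raise ValidationError("norm must be 'power' or 'l2'")

    if subtract_mean:
        plane = plane - plane.mean()
    coeffs = _fft.dctn(plane, type=2, norm="ortho")
    if support_fraction < 1.0:
        coeffs = coeffs[_support_mask(coeffs.shape, support_fraction)]
    if norm == "power":
        weight = np.square(coeffs).ravel()
    else:
        weight = np.abs(coeffs).ravel()
    total = weight.sum()
    if total <= 0:
        return 0.0
    p = weight / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def smooth_profile(scores: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks to fit at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValidationError("smoothing window must be odd and >= 1")
    scores = np.asarray(scores, dtype=float)
    if window == 1:
        return scores.copy()
    half = window // 2
    out = np.empty_like(scores)
    n = len(scores)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = scores[lo:hi].mean()
    return out


def quality_profile(
    stack: VolumeStack,
    support_fraction: float = 1.0,
    smoothing_window: int = 1,
    *,
    norm: str = "power",
) -> QualityProfile:
    """Score every z-plane of a stack and smooth the resulting profile."""
    if smoothing_window > stack.n_planes:
        raise ValidationError(
            f"smoothing_window {smoothing_window} exceeds plane count {stack.n_planes}"
        )
    scores = np.empty(stack.n_planes)
    for z in range(stack.n_planes):
        try:
            scores[z] = dcts_plane(stack.data[z], support_fraction, norm=norm)
        except ValidationError as exc:
            raise ValidationError(f"plane {z}: {exc}") from exc
    return QualityProfile(
        scores=smooth_profile(scores, smoothing_window),
        view_id=stack.view_id,
        smoothing_window=smoothing_window,
    )
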