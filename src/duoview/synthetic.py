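"""Seeded synthetic generators for every input the toolkit consumes.

These phantoms carry their own ground truth (crossover plane, applied
misalignment, bead positions, motion parameters) so every downstream
operation can be validated without real microscope data.  They emulate the
statistical structure the algorithms rely on — depth-dependent blur and
attenuation, camera offsets, shot noise, Brownian/ballistic motion — not a
physically rigorous light-sheet image-formation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GenerationError, ValidationError
from .registration import RigidTransform, resample
from .stack import LabelVolume, VolumeStack
from .tracks import TrackSet


@dataclass
class DegradationModel:
    """Depth-dependent image degradation of one detection view.

    Blur grows linearly with distance from the view's near surface,
    ``sigma(z) = blur_sigma0 + blur_slope * z`` voxels; intensity decays as
    ``exp(-attenuation_rate * depth_um)``; optional Poisson noise at a given
    peak SNR; a constant camera background is added last.
    """

    blur_sigma0: float = 0.5
    blur_slope: float = 0.06
    attenuation_rate: float = 0.005  # per µm
    peak_snr: float | None = None
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.blur_sigma0 < 0 or self.blur_slope < 0:
            raise ValidationError("blur widths must be >= 0")
        if self.attenuation_rate < 0:
            raise ValidationError("attenuation_rate must be >= 0")
        if self.peak_snr is not None and self.peak_snr <= 0:
            raise ValidationError("peak_snr must be positive or None")
        if self.background < 0:
            raise ValidationError("background must be >= 0")

    def blur_sigma_at(self, depth_planes: float) -> float:
        return self.blur_sigma0 + self.blur_slope * depth_planes


@dataclass
class MotionModel:
    """Parameters of a simulated cell-motion ensemble."""

    kind: str = "brownian"  # or "ballistic"
    v: float = 2.0  # µm/h, ballistic speed
    D: float = 1.0  # µm²/h, diffusion coefficient
    dt: float = 0.1  # hours per frame
    n_steps: int = 20
    n_tracks: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ballistic", "brownian"):
            raise ValidationError("kind must be 'ballistic' or 'brownian'")
        if self.kind == "ballistic" and not self.v > 0:
            raise ValidationError("ballistic speed v must be > 0")
        if self.kind == "brownian" and not self.D > 0:
            raise ValidationError("diffusion coefficient D must be > 0")
        if not self.dt > 0 or self.n_steps < 1 or self.n_tracks < 1:
            raise ValidationError("dt, n_steps, n_tracks must be positive")


def bead_phantom(
    shape: tuple[int, int, int],
    n_beads: int,
    psf_sigma: tuple[float, float],
    spacing: tuple[float, float, float],
    seed: int = 0,
    *,
    min_separation_um: float | None = None,
    max_retries: int = 200,
) -> tuple[VolumeStack, np.ndarray]:
    """Random field of unit-peak Gaussian beads with known positions.

    ``psf_sigma`` is (lateral, axial) in µm; beads are placed at uniform
    subvoxel positions keeping a ``5 sigma`` margin from every border.
    Returns the stack and the (n, 3) ground-truth positions in µm (z, y, x).
    """
    sigma_lat, sigma_ax = (float(s) for s in psf_sigma)
    if sigma_lat <= 0 or sigma_ax <= 0:
        raise ValidationError("psf_sigma components must be positive")
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in spacing)
    rng = np.random.default_rng(seed)

    extent = np.array(shape) * np.array(spacing)
    margin = 5.0 * np.array([sigma_ax, sigma_lat, sigma_lat])
    lo, hi = margin, extent - margin
    if np.any(hi <= lo):
        raise GenerationError(
            f"stack {shape} too small for beads with 5-sigma margin {margin}"
        )
    if min_separation_um is None:
        min_separation_um = 4.0 * max(sigma_lat, sigma_ax)

    positions: list[np.ndarray] = []
    tries = 0
    while len(positions) < n_beads:
        cand = rng.uniform(lo, hi)
        if all(np.linalg.norm(cand - p) >= min_separation_um for p in positions):
            positions.append(cand)
        else:
            tries += 1
            if tries > max_retries * max(n_beads, 1):
                raise GenerationError(
                    f"could not place {n_beads} beads with separation "
                    f"{min_separation_um} µm after {tries} retries"
                )
    pos = np.array(positions) if positions else np.empty((0, 3))

    data = np.zeros(shape)
    sig = np.array([sigma_ax, sigma_lat, sigma_lat])
    for p in pos:
        # render only inside a ±5 sigma window around the bead
        lo_v = np.maximum(np.floor((p - 5 * sig) / spacing).astype(int), 0)
        hi_v = np.minimum(np.ceil((p + 5 * sig) / spacing).astype(int) + 1, shape)
        grids = np.meshgrid(
            *[np.arange(a, b) * s for a, b, s in zip(lo_v, hi_v, spacing)],
            indexing="ij",
        )
        expo = sum(
            ((g - c) / s) ** 2 for g, c, s in zip(grids, p, sig)
        )
        data[tuple(slice(a, b) for a, b in zip(lo_v, hi_v))] += np.exp(-expo / 2.0)
    return VolumeStack(data=data, spacing=spacing), pos


def textured_phantom(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    *,
    n_blobs: int = 40,
    noise_level: float = 0.2,
) -> VolumeStack:
    """Ground-truth stack with sharp structure in every plane.

    Smoothed random blobs plus white texture, normalised to peak 1; every
    plane carries high-frequency content so focus scores respond to blur.
    """
    rng = np.random.default_rng(seed)
    data = np.zeros(shape)
    zz, yy, xx = np.indices(shape)
    for _ in range(n_blobs):
        c = rng.uniform([0, 0, 0], shape)
        r = rng.uniform(2, max(3, min(shape[1], shape[2]) / 6))
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        data += rng.uniform(0.3, 1.0) * (d2 < r * r)
    data = ndimage.gaussian_filter(data, 1.0)
    data += noise_level * rng.random(shape)
    data /= data.max()
    return VolumeStack(data=data, spacing=spacing)


def _degrade_common_frame(
    truth: np.ndarray,
    model: DegradationModel,
    spacing_z_um: float,
    rng: np.random.Generator,
    toward_low_z: bool,
) -> np.ndarray:
    nz = truth.shape[0]
    out = np.empty_like(truth)
    for z in range(nz):
        depth = (nz - 1 - z) if toward_low_z else z
        sigma = model.blur_sigma_at(depth)
        plane = (
            ndimage.gaussian_filter(truth[z], sigma) if sigma > 0 else truth[z].copy()
        )
        plane *= np.exp(-model.attenuation_rate * depth * spacing_z_um)
        out[z] = plane
    if model.peak_snr is not None:
        peak = out.max()
        if peak > 0:
            scale = model.peak_snr**2 / peak
            out = rng.poisson(out * scale).astype(float) / scale
    out += model.background
    return out


def dual_view_pair(
    truth: VolumeStack,
    model: DegradationModel,
    misalignment: RigidTransform | None = None,
    seed: int = 0,
    *,
    crossover_plane: float | None = None,
    model2: DegradationModel | None = None,
    flip_view2: bool = False,
) -> tuple[VolumeStack, VolumeStack, float]:
    """Two depth-degraded views of one truth stack with known crossover.

    View 1 blurs increasingly toward high z, view 2 toward low z (both
    expressed in the common frame).  ``crossover_plane`` shifts view 2's blur
    offset so the two blur widths are equal at that plane (default: stack
    midplane).  View 2 is additionally displaced by ``misalignment`` and, when
    ``flip_view2`` is set, z-flipped into its as-acquired orientation.
    Returns (view1, view2, ground-truth crossover plane).
    """
    rng = np.random.default_rng(seed)
    nz = truth.n_planes
    if model2 is None:
        if crossover_plane is None:
            crossover_plane = (nz - 1) / 2.0
        # equalise blur widths at the requested crossover plane
        offset = model.blur_slope * (2.0 * crossover_plane - (nz - 1))
        sigma0_2 = model.blur_sigma0 + offset
        if sigma0_2 < 0:
            raise ValidationError(
                f"crossover_plane {crossover_plane} needs negative blur offset"
            )
        model2 = DegradationModel(
            blur_sigma0=sigma0_2,
            blur_slope=model.blur_slope,
            attenuation_rate=model.attenuation_rate,
            peak_snr=model.peak_snr,
            background=model.background,
        )
    else:
        if model.blur_slope > 0 or model2.blur_slope > 0:
            denom = model.blur_slope + model2.blur_slope
            crossover_plane = (
                (model2.blur_sigma0 - model.blur_sigma0)
                + model2.blur_slope * (nz - 1)
            ) / denom if denom > 0 else (nz - 1) / 2.0
        else:
            crossover_plane = (nz - 1) / 2.0

    view1 = truth.with_data(
        _degrade_common_frame(truth.data, model, truth.spacing[0], rng, False),
        view_id="view1",
    )
    v2_data = _degrade_common_frame(
        truth.data, model2, truth.spacing[0], rng, True
    )
    view2 = truth.with_data(v2_data, view_id="view2")
    if misalignment is not None and not misalignment.is_identity:
        view2 = resample(view2, misalignment, background=model2.background)
        view2 = view2.with_data(view2.data, view_id="view2")
    if flip_view2:
        view2 = view2.with_data(np.ascontiguousarray(view2.data[::-1]))
    return view1, view2, float(crossover_plane)


def simulate_tracks(model: MotionModel) -> TrackSet:
    """Simulate an ensemble of ballistic or Brownian 3D tracks.

    Ballistic: ``r(t) = r(0) + v t`` along a random unit direction per track.
    Brownian: independent Gaussian increments per axis with variance
    ``2 D dt``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(model.seed)
    n, steps = model.n_tracks, model.n_steps
    start = rng.uniform(0, 100, size=(n, 3))
    t = np.arange(steps + 1)[None, :, None] * model.dt
    if model.kind == "ballistic":
        direction = rng.normal(size=(n, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        pos = start[:, None, :] + model.v * t * direction[:, None, :]
    else:
        increments = rng.normal(
            scale=np.sqrt(2.0 * model.D * model.dt), size=(n, steps, 3)
        )
        pos = start[:, None, :] + np.concatenate(
            [np.zeros((n, 1, 3)), np.cumsum(increments, axis=1)], axis=1
        )
    frames = np.tile(np.arange(steps + 1), n)
    table = pd.DataFrame(
        {
            "track_id": np.repeat(np.arange(n), steps + 1),
            "frame": frames,
            "x": pos[:, :, 0].ravel(),
            "y": pos[:, :, 1].ravel(),
            "z": pos[:, :, 2].ravel(),
        }
    )
    return TrackSet(table=table, dt=model.dt)


def ellipsoid_labels(
    shape: tuple[int, int, int],
    centers,
    semi_axes,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LabelVolume:
    """Voxelize non-overlapping ellipsoids as distinct labels.

    ``centers`` and ``semi_axes`` are per-ellipsoid (z, y, x) triples in
    voxels; a voxel belongs to an ellipsoid when its center satisfies the
    implicit equation.  Overlap raises :class:`GenerationError`.
    """
    centers = [np.asarray(c, dtype=float) for c in centers]
    semi_axes = [np.asarray(a, dtype=float) for a in semi_axes]
    if len(centers) != len(semi_axes):
        raise ValidationError("centers and semi_axes must have equal length")
    labels = np.zeros(tuple(int(s) for s in shape), dtype=np.int64)
    grid = np.indices(labels.shape, dtype=float)
    for i, (c, ax) in enumerate(zip(centers, semi_axes), start=1):
        if np.any(ax <= 0):
            raise ValidationError(f"ellipsoid {i} has nonpositive semi-axis {ax}")
        d2 = sum(((grid[k] - c[k]) / ax[k]) ** 2 for k in range(3))
        mask = d2 <= 1.0
        if not mask.any():
            raise GenerationError(f"ellipsoid {i} covers no voxel in {shape}")
        if np.any(labels[mask] != 0):
            raise GenerationError(f"ellipsoid {i} overlaps an earlier one")
        labels[mask] = i
    return LabelVolume(labels=labels, spacing=spacing)
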