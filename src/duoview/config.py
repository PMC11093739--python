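"""Run configuration: every paper-unspecified knob lives here.

The config file is flat ``key: value`` YAML.  Unknown keys are rejected so a
typo never silently falls back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import FormatError, IOFailure, ValidationError

_REGISTER_MODES = ("once", "per_timepoint", "none")
_DCTS_NORMS = ("power", "l2")


@dataclass
class RunConfig:
    """Parameters of the fusion / characterization pipeline.

    Attributes
    ----------
    sigmoid_slope:
        Steepness of the view-blending sigmoid, in planes.  The blend spans
        roughly ``10 * slope`` planes around the switching plane.
    dcts_support_fraction:
        Fraction of the DCT index-space radius retained when scoring focus;
        1.0 keeps every coefficient.
    dcts_norm:
        ``power`` normalises squared coefficients to a probability
        distribution; ``l2`` uses coefficient magnitudes over the L2 norm.
    quality_crop_fraction:
        Fraction of each in-plane border excluded when scoring focus in the
        pipeline.  Resampling fills out-of-bounds voxels with a constant,
        and the resulting sharp rim would otherwise inflate the scores of
        blurred planes.
    smoothing_window:
        Odd moving-average window (planes) applied to quality profiles.
    background_view1, background_view2:
        Constant camera offsets (counts) subtracted at fusion.
    estimate_background:
        When true, backgrounds are estimated as the 1st percentile of each
        stack instead of the constants above.
    flip_axes:
        Axes of view 2 reversed before registration; subset of {"z", "x"}.
    register:
        ``once`` registers the first time point and reuses the transform,
        ``per_timepoint`` re-registers every time point, ``none`` assumes the
        views are already aligned.
    registration_min_step / registration_iterations:
        Optimiser stopping controls for rigid registration.
    stitch_overlap_threshold:
        Minimum IoU linking 2D masks across planes into one 3D label.
    volume_min/max, axis_min/max:
        Closed bounds for false-segmentation filtering (µm³ / µm).  They ship
        unset and must be provided explicitly; no silent defaults.
    seed:
        Seed for any stochastic stage (synthetic generation).
    """

    sigmoid_slope: float = 3.0
    dcts_support_fraction: float = 1.0
    quality_crop_fraction: float = 0.1
    dcts_norm: str = "power"
    smoothing_window: int = 5
    background_view1: float = 0.0
    background_view2: float = 0.0
    estimate_background: bool = False
    flip_axes: tuple[str, ...] = ("z",)
    register: str = "once"
    registration_min_step: float = 1e-4
    registration_iterations: int = 200
    stitch_overlap_threshold: float = 0.25
    volume_min: float | None = None
    volume_max: float | None = None
    axis_min: float | None = None
    axis_max: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.sigmoid_slope > 0:
            raise ValidationError("sigmoid_slope must be > 0")
        if not 0 < self.dcts_support_fraction <= 1:
            raise ValidationError("dcts_support_fraction must be in (0, 1]")
        if self.dcts_norm not in _DCTS_NORMS:
            raise ValidationError(f"dcts_norm must be one of {_DCTS_NORMS}")
        if not 0 <= self.quality_crop_fraction <= 0.45:
            raise ValidationError("quality_crop_fraction must be in [0, 0.45]")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValidationError("smoothing_window must be odd and >= 1")
        if self.background_view1 < 0 or self.background_view2 < 0:
            raise ValidationError("background offsets must be >= 0")
        self.flip_axes = tuple(self.flip_axes)
        if not set(self.flip_axes) <= {"z", "x"}:
            raise ValidationError("flip_axes must be a subset of {'z', 'x'}")
        if self.register not in _REGISTER_MODES:
            raise ValidationError(f"register must be one of {_REGISTER_MODES}")
        if not 0 < self.stitch_overlap_threshold <= 1:
            raise ValidationError("stitch_overlap_threshold must be in (0, 1]")
        for lo, hi, name in (
            (self.volume_min, self.volume_max, "volume"),
            (self.axis_min, self.axis_max, "axis"),
        ):
            if lo is not None and hi is not None and lo > hi:
                raise ValidationError(f"{name} bounds inverted: {lo} > {hi}")


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Read a flat key: value YAML file into a :class:`RunConfig`.

    Unknown keys raise :class:`FormatError` naming the offender.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOFailure(f"cannot read config file {path}: {exc}") from exc
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise FormatError(f"config {path} must be a flat key: value mapping")
    unknown = set(raw) - _FIELDS
    if unknown:
        raise FormatError(f"unknown config keys in {path}: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    data = dataclasses.asdict(config)
    data["flip_axes"] = list(config.flip_axes)
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path
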