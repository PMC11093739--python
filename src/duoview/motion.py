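"""Single-cell track statistics: MSD, per-step speeds and path lengths.

Tracks are time-indexed 3D positions in µm with a fixed frame interval ``dt``
in hours.  The mean-square displacement is the ensemble, origin-anchored
definition

    msd3d(t) = (1/N) * sum_i |r_i(t) - r_i(0)|^2

averaged over the N tracks observed at lag t — no sliding-window time
averaging.  Lags are measured from each track's own first frame, so tracks
starting at different acquisition frames still contribute from their own
origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tracks import TrackSet


@dataclass
class MSDCurve:
    """Ensemble MSD per lag with the number of contributing tracks."""

    lags: np.ndarray  # hours
    msd: np.ndarray  # µm^2
    n_tracks: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_tracks = np.asarray(self.n_tracks, dtype=int)
        if not (len(self.lags) == len(self.msd) == len(self.n_tracks)):
            raise ValidationError("lags, msd and n_tracks must align")
        if np.any(np.diff(self.lags) <= 0):
            raise ValidationError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValidationError("msd must be non-negative")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_h": self.lags, "msd_um2": self.msd,
                             "n_tracks": self.n_tracks})


def msd3d(tracks: TrackSet) -> MSDCurve:
    """Origin-anchored ensemble MSD of a track set.

    Each track contributes ``|r(t) - r(0)|^2`` at every lag it covers; the
    per-lag track count ``N`` is reported so partial coverage at long lags is
    visible.  ``msd(0)`` is exactly 0.
    """
    if tracks.n_tracks == 0:
        raise ValidationError("empty TrackSet")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for _, pos, frames in tracks.iter_tracks():
        disp2 = np.sum((pos - pos[0]) ** 2, axis=1)
        for k, d2 in zip(frames - frames[0], disp2):
            sums[k] = sums.get(k, 0.0) + float(d2)
            counts[k] = counts.get(k, 0) + 1
    lags = np.array(sorted(sums), dtype=int)
    msd = np.array([sums[k] / counts[k] for k in lags])
    n = np.array([counts[k] for k in lags])
    return MSDCurve(lags=lags * tracks.dt, msd=msd, n_tracks=n)


def step_speeds(tracks: TrackSet) -> pd.DataFrame:
    """Per-step speed table: one row per consecutive position pair.

    Speed is the Euclidean displacement divided by the elapsed time
    ``(frame gap) * dt`` in µm/h.  Single-point tracks contribute no rows.
    Columns: track_id, frame (of the step's start), speed_um_per_h.
    """
    if not tracks.dt > 0:
        raise ValidationError("dt must be > 0")
    rows = []
    for tid, pos, frames in tracks.iter_tracks():
        if len(frames) < 2:
            continue
        disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        elapsed = np.diff(frames) * tracks.dt
        for f, d, e in zip(frames[:-1], disp, elapsed):
            rows.append((tid, int(f), float(d / e)))
    return pd.DataFrame(rows, columns=["track_id", "frame", "speed_um_per_h"])


def track_mean_speeds(tracks: TrackSet) -> pd.DataFrame:
    """Mean per-step speed of each track (µm/h); one row per track."""
    steps = step_speeds(tracks)
    if steps.empty:
        return pd.DataFrame(columns=["track_id", "mean_speed_um_per_h"])
    out = steps.groupby("track_id", as_index=False)["speed_um_per_h"].mean()
    return out.rename(columns={"speed_um_per_h": "mean_speed_um_per_h"})


def path_length(positions: np.ndarray) -> float:
    """Total path length of an ordered position sequence (µm).

    A single-point track has length 0.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.shape[0] < 1 or pos.shape[1] != 3:
        raise ValidationError("positions must be an (n, 3) array with n >= 1")
    if pos.shape[0] == 1:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1)))


def path_lengths(tracks: TrackSet) -> pd.DataFrame:
    """Path length per track; one row per track id."""
    rows = [(tid, path_length(pos)) for tid, pos, _ in tracks.iter_tracks()]
    return pd.DataFrame(rows, columns=["track_id", "path_length_um"])
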