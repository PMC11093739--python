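"""The TrackSet container and the track-table CSV reader.

The expected CSV layout is the per-spot export of manual curation tools
(Mastodon and kin): one row per spot with a track id, a frame index and x/y/z
positions in µm, optionally followed by per-channel mean-intensity columns.
Header names are matched loosely (case/space insensitive) because exports
vary: any column containing "track" is the track id, "frame"/"t"/"spot frame"
the frame, and columns containing "intensity" or starting with "mean" are
attached as intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import IOFailure, SchemaError, ValidationError

_FRAME_NAMES = {"frame", "t", "spot frame", "frames", "timepoint"}


@dataclass
class TrackSet:
    """Per-cell time-indexed 3D positions with a fixed frame interval.

    ``table`` holds one row per spot with columns ``track_id``, ``frame``,
    ``x``, ``y``, ``z`` (µm) and any intensity columns; rows are sorted by
    (track_id, frame).  ``dt`` is the frame interval in hours.
    """

    table: pd.DataFrame
    dt: float

    def __post_init__(self) -> None:
        required = {"track_id", "frame", "x", "y", "z"}
        missing = required - set(self.table.columns)
        if missing:
            raise SchemaError(f"track table missing columns: {sorted(missing)}")
        if not self.dt > 0:
            raise ValidationError("dt must be > 0 hours")
        self.table = self.table.sort_values(["track_id", "frame"]).reset_index(
            drop=True
        )
        dup = self.table.duplicated(subset=["track_id", "frame"])
        if dup.any():
            first = self.table.loc[dup.idxmax()]
            raise ValidationError(
                f"duplicate (track, frame) pair: ({first['track_id']}, "
                f"{first['frame']})"
            )
        try:
            coords = self.table[["x", "y", "z"]].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"positions must be numeric: {exc}") from exc
        if not np.all(np.isfinite(coords)):
            raise ValidationError("positions must be finite")

    @property
    def n_tracks(self) -> int:
        return int(self.table["track_id"].nunique())

    @property
    def intensity_columns(self) -> list[str]:
        base = {"track_id", "frame", "x", "y", "z"}
        return [c for c in self.table.columns if c not in base]

    def iter_tracks(self) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
        """Yield (track_id, positions (n, 3) µm, frames (n,)) per track."""
        for tid, grp in self.table.groupby("track_id", sort=True):
            yield tid, grp[["x", "y", "z"]].to_numpy(dtype=float), grp[
                "frame"
            ].to_numpy(dtype=int)

    def positions(self, track_id) -> np.ndarray:
        grp = self.table[self.table["track_id"] == track_id]
        if grp.empty:
            raise ValidationError(f"unknown track id {track_id}")
        return grp[["x", "y", "z"]].to_numpy(dtype=float)


def _resolve_column(columns: list[str], want: str) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    if want in lowered:
        return lowered[want]
    if want == "track_id":
        for lc, c in lowered.items():
            if "track" in lc:
                return c
    elif want == "frame":
        for lc, c in lowered.items():
            if lc in _FRAME_NAMES:
                return c
    return None


def read_track_table(path: str | Path, dt: float) -> TrackSet:
    """Read a spot-position CSV export into a :class:`TrackSet`.

    Intensity columns (headers containing "intensity" or starting with
    "mean") are carried through untouched — whatever counts the export holds.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise IOFailure(f"cannot read track table {path}: {exc}") from exc
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"unparseable track table {path}: {exc}") from exc

    rename = {}
    for want in ("track_id", "frame", "x", "y", "z"):
        col = _resolve_column(list(df.columns), want)
        if col is None:
            raise SchemaError(f"track table {path} lacks a '{want}' column")
        rename[col] = want
    intensity = [
        c
        for c in df.columns
        if c not in rename
        and ("intensity" in c.lower() or c.lower().startswith("mean"))
    ]
    df = df[list(rename) + intensity].rename(columns=rename)
    return TrackSet(table=df, dt=dt)


def write_track_table(tracks: TrackSet, path: str | Path) -> Path:
    path = Path(path)
    tracks.table.to_csv(path, index=False)
    return path
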