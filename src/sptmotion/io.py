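"""Trajectory containers and CSV input/output.

Tracks are tables of localized particle positions, one row per frame, in
micrometers. Internally time is measured in frames (the frame interval is
carried only as metadata); all motion parameters downstream are therefore
"per frame" quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "TrackSet",
    "TrackDataError",
    "TrackFormatError",
    "read_tracks_csv",
    "write_tracks_csv",
    "segment_track",
    "segment_tracks",
    "compute_msd",
    "MSDResult",
]


class TrackFormatError(ValueError):
    """Input table cannot be mapped to (track_id, frame, x[, y, z])."""


class TrackDataError(ValueError):
    """Input table violates track invariants (duplicate frames, gaps...)."""


#: Column aliases accepted on input, including TrackMate export names.
DEFAULT_COLUMN_ALIASES: dict[str, str] = {
    "track_id": "track_id",
    "trajectory": "track_id",
    "tid": "track_id",
    "track": "track_id",
    "frame": "frame",
    "t": "frame",
    "x": "x",
    "y": "y",
    "z": "z",
    # TrackMate spot table exports
    "TRACK_ID": "track_id",
    "FRAME": "frame",
    "POSITION_X": "x",
    "POSITION_Y": "y",
    "POSITION_Z": "z",
    "POSITION_T": "frame",
}


@dataclass(frozen=True)
class Track:
    """An observed trajectory: positions c_0..c_n of one particle.

    Parameters
    ----------
    track_id : str
        Unique identifier within a :class:`TrackSet`.
    positions : ndarray, shape (n+1, dim)
        Observed coordinates in μm; ``dim`` in {1, 2, 3}.
    frames : ndarray, shape (n+1,)
        Consecutive integer frame indices (no gaps).
    """

    track_id: str
    positions: np.ndarray
    frames: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim == 1:
            pos = pos[:, None]
        if pos.ndim != 2 or pos.shape[1] not in (1, 2, 3):
            raise TrackDataError(
                f"track {self.track_id!r}: positions must be (n+1, dim) with dim in 1..3"
            )
        if pos.shape[0] < 2:
            raise TrackDataError(f"track {self.track_id!r}: needs at least 2 points")
        if not np.all(np.isfinite(pos)):
            raise TrackDataError(f"track {self.track_id!r}: non-finite coordinates")
        frames = self.frames
        if frames is None:
            frames = np.arange(pos.shape[0])
        frames = np.asarray(frames, dtype=np.int64)
        if frames.shape != (pos.shape[0],):
            raise TrackDataError(f"track {self.track_id!r}: frames/positions mismatch")
        if not np.all(np.diff(frames) == 1):
            raise TrackDataError(
                f"track {self.track_id!r}: frames must be consecutive integers"
            )
        pos.setflags(write=False)
        frames.setflags(write=False)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "frames", frames)

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    @property
    def n_steps(self) -> int:
        """Number of displacements (length of the track minus one)."""
        return self.positions.shape[0] - 1

    def __len__(self) -> int:
        return self.positions.shape[0]

    def displacements(self) -> np.ndarray:
        return np.diff(self.positions, axis=0)


@dataclass
class TrackSet:
    """A collection of tracks with shared unit metadata."""

    tracks: list[Track]
    length_unit: str = "um"
    frame_interval_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tracks = list(self.tracks)
        if not self.tracks:
            # empty is tolerated (e.g. after filtering); operations that
            # require data check for themselves
            return
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            raise TrackDataError("duplicate track_ids in TrackSet")

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __len__(self) -> int:
        return len(self.tracks)

    def __getitem__(self, i: int) -> Track:
        return self.tracks[i]

    @property
    def dim(self) -> int:
        dims = {t.dim for t in self.tracks}
        if len(dims) != 1:
            raise TrackDataError("TrackSet has mixed dimensionality")
        return dims.pop()

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        axes = "xyz"
        for t in self.tracks:
            df = pd.DataFrame(t.positions, columns=list(axes[: t.dim]))
            df.insert(0, "frame", t.frames)
            df.insert(0, "track_id", t.track_id)
            rows.append(df)
        if not rows:
            return pd.DataFrame(columns=["track_id", "frame", "x", "y"])
        return pd.concat(rows, ignore_index=True)


def _map_columns(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    mapping: dict[str, str] = {}
    aliases = dict(DEFAULT_COLUMN_ALIASES)
    lower_aliases = {k.lower(): v for k, v in aliases.items()}
    if column_map:
        # user map: {csv_name: canonical}
        for src, dst in column_map.items():
            mapping[src] = dst
    for col in df.columns:
        if col in mapping:
            continue
        if col in aliases:
            mapping[col] = aliases[col]
        elif col.lower() in lower_aliases:
            mapping[col] = lower_aliases[col.lower()]
    out = df.rename(columns=mapping)
    required = {"track_id", "frame", "x"}
    missing = required - set(out.columns)
    if missing:
        raise TrackFormatError(f"cannot map required columns: {sorted(missing)}")
    return out


def read_tracks_csv(
    path,
    column_map: Mapping[str, str] | None = None,
    gap_policy: str = "error",
    min_length: int = 2,
) -> TrackSet:
    """Read a trajectory table into a :class:`TrackSet`.

    Accepts canonical columns ``track_id, frame, x[, y, z]`` as well as
    TrackMate spot-table names (``TRACK_ID, FRAME, POSITION_X, ...``).

    Parameters
    ----------
    gap_policy : {"error", "split"}
        The motion likelihoods assume a uniform frame interval, so missing
        frames are an error by default. With ``"split"`` a track with a gap
        becomes multiple tracks with suffixed ids; fragments shorter than
        ``min_length`` are dropped with a warning.
    """
    if gap_policy not in ("error", "split"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    # TrackMate CSVs carry up to three non-numeric header rows; drop them.
    df = _map_columns(df, column_map)
    axes = [a for a in ("x", "y", "z") if a in df.columns]
    for col in ["frame"] + axes:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=["frame"] + axes)
    if not np.all(np.isfinite(df[axes].to_numpy(dtype=float))):
        raise TrackDataError("non-finite coordinates in input")
    df = df.sort_values(["track_id", "frame"], kind="stable")

    tracks: list[Track] = []
    for tid, g in df.groupby("track_id", sort=False):
        frames = g["frame"].to_numpy(dtype=np.int64)
        pos = g[axes].to_numpy(dtype=float)
        dif = np.diff(frames)
        if np.any(dif == 0):
            bad = frames[1:][dif == 0][0]
            raise TrackDataError(f"track {tid!r}: duplicate frame {bad}")
        if np.any(dif > 1):
            if gap_policy == "error":
                bad = frames[1:][dif > 1][0]
                raise TrackDataError(
                    f"track {tid!r}: gap before frame {bad} (gap_policy='error')"
                )
            # split at gaps
            cuts = np.where(dif > 1)[0] + 1
            parts_f = np.split(frames, cuts)
            parts_p = np.split(pos, cuts, axis=0)
            for k, (pf, pp) in enumerate(zip(parts_f, parts_p)):
                if len(pf) < min_length:
                    warnings.warn(
                        f"track {tid!r}: dropping fragment of length {len(pf)} after split",
                        stacklevel=2,
                    )
                    continue
                tracks.append(Track(f"{tid}_{k}", pp, pf))
        else:
            if len(frames) < min_length:
                warnings.warn(f"track {tid!r}: too short, dropped", stacklevel=2)
                continue
            tracks.append(Track(str(tid), pos, frames))
    return TrackSet(tracks)


def write_tracks_csv(tracks: TrackSet, path) -> None:
    """Write a TrackSet in canonical column order at full float precision."""
    df = tracks.to_dataframe()
    df.to_csv(path, index=False, float_format="%.17g")


def segment_track(track: Track, segment_len: int) -> list[Track]:
    """Cut a track into consecutive non-overlapping pieces of fixed length.

    ``segment_len`` counts positions (a segment of L positions has L-1
    steps). The trailing remainder shorter than ``segment_len`` is dropped.
    """
    if segment_len < 2:
        raise ValueError("segment_len must be >= 2")
    n_seg = len(track) // segment_len
    out = []
    for k in range(n_seg):
        sl = slice(k * segment_len, (k + 1) * segment_len)
        out.append(
            Track(f"{track.track_id}_seg{k}", track.positions[sl], track.frames[sl])
        )
    return out


def segment_tracks(tracks: TrackSet, segment_len: int) -> TrackSet:
    segs: list[Track] = []
    for t in tracks:
        segs.extend(segment_track(t, segment_len))
    return TrackSet(segs, tracks.length_unit, tracks.frame_interval_s)


@dataclass(frozen=True)
class MSDResult:
    """Mean-squared displacement curve with a log-log power-law fit.

    ``msd(τ) ≈ gamma * τ**alpha``; ``alpha`` is the anomalous exponent
    (1 for Brownian motion). For a noiseless Brownian track in ``dim``
    dimensions with per-axis step sd ``d``, ``gamma ≈ dim * d**2``.
    ``alpha`` is NaN (``fit_ok=False``) for degenerate (e.g. static) tracks.
    """

    lags: np.ndarray
    msd: np.ndarray
    gamma: float
    alpha: float
    fit_ok: bool


def compute_msd(track: Track, max_lag: int) -> MSDResult:
    """Time-averaged MSD over lags 1..max_lag plus a power-law fit."""
    if max_lag >= len(track):
        raise ValueError("max_lag must be smaller than the track length")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    pos = track.positions
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    for i, lag in enumerate(lags):
        diffs = pos[lag:] - pos[:-lag]
        msd[i] = np.mean(np.sum(diffs**2, axis=1))
    if np.any(msd <= 0):
        return MSDResult(lags, msd, np.nan, np.nan, False)
    slope, intercept = np.polyfit(np.log(lags), np.log(msd), 1)
    return MSDResult(lags, msd, float(np.exp(intercept)), float(slope), True)
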