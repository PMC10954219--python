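"""Track containers: sub-pixel localizations linked over frames.

Coordinates are micrometres throughout (pixel-center convention: the center
of pixel (i, j) maps to ((i + 0.5) * pixel_size, (j + 0.5) * pixel_size)).
Tracks may contain single-frame gaps (blinks); frame indices are strictly
increasing with inter-localization differences of 1 or 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Localization:
    """One detected molecule in one frame."""

    frame: int
    x: float
    y: float
    intensity: float = np.nan
    snr: float = np.nan


@dataclass
class Track:
    """A time-ordered sequence of localizations of one molecule.

    ``frames`` are 0-based movie frame indices; ``x``/``y`` are micrometres.
    A difference of 2 between consecutive frames marks a bridged one-frame
    gap (blink).
    """

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray | None = None
    snr: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x, y must have equal length")
        d = np.diff(self.frames)
        if len(d) and d.min() < 1:
            raise ValueError(f"track {self.track_id}: frames not strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames_spanned(self) -> int:
        """First-to-last frame span in frames (gaps included)."""
        return int(self.frames[-1] - self.frames[0]) + 1

    @property
    def gap_flags(self) -> np.ndarray:
        """Boolean per localization: preceded by a bridged gap."""
        flags = np.zeros(len(self.frames), dtype=bool)
        if len(self.frames) > 1:
            flags[1:] = np.diff(self.frames) > 1
        return flags

    def duration(self, frame_interval: float) -> float:
        """Dwell time in seconds: first-to-last frame span times the interval."""
        return (self.n_frames_spanned - 1) * frame_interval

    def displacements(self, lag: int = 1) -> np.ndarray:
        """2D displacement magnitudes between localizations ``lag`` frames apart.

        Matching is by true frame difference, so bridged gaps contribute at
        their actual lag, never to lag 1.
        """
        if lag < 1:
            raise ValueError("lag must be >= 1")
        out = []
        pos = {int(f): i for i, f in enumerate(self.frames)}
        for i, f in enumerate(self.frames):
            j = pos.get(int(f) + lag)
            if j is not None:
                out.append(
                    np.hypot(self.x[j] - self.x[i], self.y[j] - self.y[i])
                )
        return np.asarray(out, dtype=float)

    def msd_at_lag(self, lag: int) -> float:
        """Time-averaged squared 2D displacement at a frame lag (NaN if none)."""
        d = self.displacements(lag)
        return float(np.mean(d**2)) if len(d) else np.nan


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Flatten a track list into a tidy DataFrame (one row per localization)."""
    rows = []
    for t in tracks:
        gaps = t.gap_flags
        for i in range(len(t)):
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": int(t.frames[i]),
                    "x_um": t.x[i],
                    "y_um": t.y[i],
                    "intensity": t.intensity[i] if t.intensity is not None else np.nan,
                    "snr": t.snr[i] if t.snr is not None else np.nan,
                    "gap_flag": bool(gaps[i]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["track_id", "frame", "x_um", "y_um", "intensity", "snr", "gap_flag"],
    )


def frame_to_tracks(df: pd.DataFrame) -> list[Track]:
    """Inverse of :func:`tracks_to_frame`. Validates frame monotonicity."""
    required = {"track_id", "frame", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        row = df.index[dup][0]
        raise ValueError(f"duplicated (track_id, frame) at row {row}")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        tracks.append(
            Track(
                track_id=int(tid),
                frames=g["frame"].to_numpy(),
                x=g["x_um"].to_numpy(),
                y=g["y_um"].to_numpy(),
                intensity=g["intensity"].to_numpy() if "intensity" in g else None,
                snr=g["snr"].to_numpy() if "snr" in g else None,
            )
        )
    return tracks
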