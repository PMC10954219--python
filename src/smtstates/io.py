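"""File interchange: track CSV, TIFF stacks, YAML run configuration.

Track CSV columns: track_id, frame, x_um, y_um[, intensity, snr, gap_flag].
A ``# units: um`` header line guards against pixel/micrometre mix-ups.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .tracks import Track, frame_to_tracks, tracks_to_frame

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_stack",
    "write_stack",
    "load_config",
    "save_config",
    "config_hash",
]

_UNITS_HEADER = "# units: um"


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    path = Path(path)
    df = tracks_to_frame(tracks)
    with open(path, "w") as fh:
        fh.write(_UNITS_HEADER + "\n")
        df.to_csv(fh, index=False)


def read_tracks(path: str | Path) -> list[Track]:
    """Read a track CSV, validating the units header, required columns,
    duplicates, and frame monotonicity."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.strip().startswith("#"):
            if "um" not in first:
                raise ValueError(
                    f"{path}: units header {first.strip()!r} does not declare um"
                )
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    try:
        return frame_to_tracks(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(stack))


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, for output provenance."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
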