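"""Ensemble MSD curves, exploration diameters, and the unbound fraction.

The ensemble MSD per diffusive state averages squared 2D displacements over
retained sub-tracks (time average within each sub-track, ensemble average
over sub-tracks; SEM over sub-track means). Exploration diameter follows
d = 2 sqrt(MSD(1.2 s)). The unbound fraction uses two jump thresholds
derived from a histone H2B reference: R_min, the 99th percentile of
consecutive-frame jumps, and R_max, the 99th percentile of displacements
across a six-frame window; a track with any jump beyond either threshold
counts as one unbound event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .states import Assignment, SubTrack
from .tracks import Track

logger = logging.getLogger(__name__)

__all__ = [
    "MSDCurve",
    "BoundThresholds",
    "ensemble_msd",
    "exploration_diameter",
    "jump_thresholds",
    "unbound_fraction",
]


@dataclass
class MSDCurve:
    """Ensemble MSD at frame lags 1..6 (um^2) with SEM and counts."""

    lag_times: np.ndarray  # seconds
    msd: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    state: int | None = None


@dataclass(frozen=True)
class BoundThresholds:
    """H2B-derived jump thresholds (um): consecutive-frame and six-frame."""

    r_min: float
    r_max: float

    def __post_init__(self) -> None:
        if self.r_max < self.r_min:
            raise ValueError("R_max must be >= R_min")


def _subtrack_sq_disp(sub: SubTrack, lag: int) -> float:
    """Time-averaged squared 2D displacement of one sub-track at a frame lag
    (NaN when the sub-track has no pair at that exact lag)."""
    pos = {int(f): i for i, f in enumerate(sub.frames)}
    vals = []
    for f, i in pos.items():
        j = pos.get(f + lag)
        if j is not None:
            vals.append((sub.x[j] - sub.x[i]) ** 2 + (sub.y[j] - sub.y[i]) ** 2)
    return float(np.mean(vals)) if vals else np.nan


def ensemble_msd(
    subtracks: list[SubTrack],
    assignment: Assignment | None = None,
    frame_interval: float = 0.2,
    max_lag: int = 6,
    per_state: bool = True,
) -> dict[int | None, MSDCurve]:
    """Ensemble MSD curves, optionally per assigned state.

    With an assignment, only retained (unambiguous) sub-tracks contribute
    and one curve per post-filter state label is returned (keyed by the
    label; -1 = "other" states). Without one, a single pooled curve is
    returned under key ``None``. Displacement pairs are matched by true
    frame difference, so gap-bridged displacements enter at their actual
    lag, never at lag 1.
    """
    if assignment is None:
        groups: dict[int | None, list[SubTrack]] = {None: list(subtracks)}
    else:
        labels = (
            assignment.post_filter_state
            if assignment.post_filter_state is not None
            else assignment.state
        )
        groups = {}
        for sub, lab, keep in zip(subtracks, labels, assignment.retained):
            if not keep:
                continue
            key = int(lab) if per_state else None
            groups.setdefault(key, []).append(sub)
    curves: dict[int | None, MSDCurve] = {}
    for key, subs in sorted(groups.items(), key=lambda kv: (kv[0] is None, kv[0])):
        if not subs:
            logger.info("ensemble_msd: no retained sub-tracks for state %s", key)
            continue
        msd, sem, n = [], [], []
        for lag in range(1, max_lag + 1):
            vals = np.array([_subtrack_sq_disp(s, lag) for s in subs])
            vals = vals[~np.isnan(vals)]
            n.append(len(vals))
            msd.append(vals.mean() if len(vals) else np.nan)
            sem.append(vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan)
        curves[key] = MSDCurve(
            lag_times=np.arange(1, max_lag + 1) * frame_interval,
            msd=np.array(msd),
            sem=np.array(sem),
            n=np.array(n),
            state=key,
        )
    return curves


def exploration_diameter(msd_at_1p2s: float) -> float:
    """Exploration diameter d = 2 sqrt(MSD(1.2 s)), in um."""
    if msd_at_1p2s < 0:
        raise ValueError("MSD must be >= 0")
    return 2.0 * float(np.sqrt(msd_at_1p2s))


def jump_thresholds(h2b_tracks: list[Track], window: int = 6) -> BoundThresholds:
    """Jump thresholds from a histone reference track set.

    R_min is the empirical 99th percentile of all consecutive-frame 2D jump
    distances; R_max the 99th percentile of end-to-end displacements across
    a six-frame window (five frame intervals, the minimum track length).
    """
    if not h2b_tracks:
        raise ValueError("reference track set is empty")
    jumps1 = np.concatenate([t.displacements(1) for t in h2b_tracks] or [[]])
    jumpsw = np.concatenate([t.displacements(window - 1) for t in h2b_tracks] or [[]])
    if len(jumps1) < 100:
        logger.warning(
            "jump_thresholds: only %d consecutive-frame jumps; percentile unstable",
            len(jumps1),
        )
    r_min = float(np.percentile(jumps1, 99)) if len(jumps1) else 0.0
    r_max = float(np.percentile(jumpsw, 99)) if len(jumpsw) else 0.0
    return BoundThresholds(r_min=r_min, r_max=max(r_max, r_min))


def unbound_fraction(
    tracks: list[Track], thr: BoundThresholds, window: int = 6
) -> float:
    """Fraction of tracked molecules classified as unbound.

    A track is one unbound event if any consecutive-frame jump exceeds
    R_min or any six-frame-window displacement exceeds R_max; the fraction
    is unbound tracks over total tracks.
    """
    if not tracks:
        return 0.0
    n_unbound = 0
    for t in tracks:
        d1 = t.displacements(1)
        dw = t.displacements(window - 1)
        if (len(d1) and d1.max() > thr.r_min) or (len(dw) and dw.max() > thr.r_max):
            n_unbound += 1
    return n_unbound / len(tracks)
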