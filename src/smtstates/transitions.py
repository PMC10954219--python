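"""State-switching statistics: transition matrices and permutation testing.

Per-track sequences of sub-track state labels over {state 1, state 2,
other} are reduced to a 3x3 count matrix T and row-normalized transition
matrix P_t. Significance is assessed against a null ensemble with the same
population fractions: sub-track labels are pooled over all sequences,
globally shuffled, redistributed into the original sequence lengths, and
P_t recomputed — repeated 1000 times. The significance of cell (i, j) is
the proportion of shuffles whose transition probability exceeds the
observed one (strict inequality), so persistent same-state switching shows
up as diagonal significances of 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .states import Assignment, SubTrack

__all__ = [
    "StateSequence",
    "TransitionResult",
    "state_sequences",
    "transition_matrix",
    "permutation_test",
]

OTHER = 2  # label index of the pooled "other" state


@dataclass(frozen=True)
class StateSequence:
    """Ordered sub-track labels of one track; labels in {0, 1, 2=other}."""

    track_id: int
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class TransitionResult:
    counts: np.ndarray  # (3, 3) transition counts T
    probabilities: np.ndarray  # row-normalized P_t (NaN rows where empty)
    significance: np.ndarray | None = None  # proportion of shuffles > observed
    n_perm: int = 0
    seed: int | None = None
    null_mean: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def state_sequences(
    subtracks: list[SubTrack],
    assignment: Assignment,
    min_length: int = 3,
) -> tuple[list[StateSequence], dict]:
    """Per-track ordered state labels with non-{1,2} states mapped to other.

    All argmax-assigned sub-tracks enter the sequences (the ambiguity filter
    applies to population fractions, not to switching). Tracks with fewer
    than ``min_length`` sub-tracks are dropped; the returned report gives
    the fraction of tracks retained and of sub-tracks covered.
    """
    labels = (
        assignment.post_filter_state
        if assignment.post_filter_state is not None
        else assignment.state
    )
    per_track: dict[int, list[tuple[int, int]]] = {}
    for sub, lab in zip(subtracks, labels):
        mapped = int(lab) if lab in (0, 1) else OTHER
        per_track.setdefault(sub.track_id, []).append((sub.ordinal, mapped))
    seqs = []
    n_subs_kept = 0
    for tid, pairs in sorted(per_track.items()):
        pairs.sort()
        if len(pairs) < min_length:
            continue
        seqs.append(StateSequence(track_id=tid, labels=np.array([p[1] for p in pairs])))
        n_subs_kept += len(pairs)
    report = {
        "n_tracks": len(per_track),
        "n_tracks_kept": len(seqs),
        "track_fraction": len(seqs) / len(per_track) if per_track else 0.0,
        "subtrack_fraction": n_subs_kept / len(subtracks) if subtracks else 0.0,
    }
    return seqs, report


def _flatten(seqs: list[StateSequence]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled label vector and a mask of valid adjacent pairs (within-track)."""
    labels = np.concatenate([s.labels for s in seqs])
    lengths = np.array([len(s) for s in seqs])
    ends = np.cumsum(lengths)[:-1]  # pair (i, i+1) across a boundary is invalid
    pair_valid = np.ones(len(labels) - 1, dtype=bool)
    pair_valid[ends - 1] = False
    return labels, pair_valid


def _count_matrix(labels: np.ndarray, pair_valid: np.ndarray) -> np.ndarray:
    code = 3 * labels[:-1] + labels[1:]
    return np.bincount(code[pair_valid], minlength=9).reshape(3, 3).astype(float)


def _normalize_rows(t: np.ndarray) -> np.ndarray:
    rowsum = t.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = t / rowsum
    return p


def transition_matrix(seqs: list[StateSequence]) -> TransitionResult:
    """Count adjacent sub-track transitions over all sequences and
    row-normalize. Rows with no outgoing transitions are NaN."""
    if not seqs:
        raise ValueError("no sequences supplied")
    labels, pair_valid = _flatten(seqs)
    t = _count_matrix(labels, pair_valid)
    return TransitionResult(counts=t, probabilities=_normalize_rows(t))


def permutation_test(
    seqs: list[StateSequence],
    n_perm: int = 1000,
    seed: int = 0,
) -> TransitionResult:
    """Global-shuffle permutation test of the transition matrix.

    Labels are pooled across all sequences, permuted, and redistributed
    into the original sequence lengths; this preserves population fractions
    while destroying temporal order. Significance of cell (i, j) is the
    proportion of permuted ensembles with a strictly larger P_t(i, j)
    (NaN cells compare as not-larger).
    """
    base = transition_matrix(seqs)
    labels, pair_valid = _flatten(seqs)
    rng = np.random.default_rng(seed)
    n = len(labels)
    exceed = np.zeros((3, 3))
    null_sum = np.zeros((3, 3))
    obs = base.probabilities
    for _ in range(n_perm):
        perm = labels[rng.permutation(n)]
        p = _normalize_rows(_count_matrix(perm, pair_valid))
        with np.errstate(invalid="ignore"):
            exceed += np.where(np.isnan(p) | np.isnan(obs), 0.0, (p > obs).astype(float))
        null_sum += np.nan_to_num(p)
    base.significance = exceed / n_perm
    base.null_mean = null_sum / n_perm
    base.n_perm = n_perm
    base.seed = seed
    return base
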