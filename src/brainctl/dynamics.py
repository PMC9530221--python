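"""Temporal statistics of brain-state sequences.

All metrics treat scans as temporally disjoint: runs and transitions never
bridge a scan boundary.  A run that starts a scan counts as an appearance
and contributes to dwell time (the state is "transitioned into" at t = 0);
this is applied uniformly to both conditions so paired contrasts stay
unbiased.  States never visited in a subject-condition propagate as NaN
("missing"), never as zeros — a dwell time of 0 s is not observed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StateSequence",
    "DynamicsSummary",
    "fractional_occupancy",
    "dwell_times",
    "appearance_rate",
    "transition_probabilities",
    "binarize_to_meta_states",
    "summarize",
]


@dataclass(frozen=True)
class StateSequence:
    """Integer state labels (1..k) for one subject-condition, possibly multi-scan."""

    scans: tuple  # tuple of 1-D integer arrays, one per scan
    tr_seconds: float
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self):
        if not self.scans:
            raise ValueError("at least one scan required")
        for s in self.scans:
            if len(s) == 0:
                raise ValueError("empty scan in state sequence")
            if np.asarray(s).min() < 1:
                raise ValueError("labels must be 1-based state indices")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_frames(self) -> int:
        return sum(len(s) for s in self.scans)


@dataclass
class DynamicsSummary:
    fractional_occupancy: np.ndarray
    dwell_time_seconds: np.ndarray
    appearance_rate_per_min: np.ndarray
    transition_probabilities: np.ndarray


def _runs(scan: np.ndarray):
    """(state, run_length) pairs for one scan."""
    scan = np.asarray(scan, dtype=int)
    change = np.flatnonzero(np.diff(scan) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(scan)]))
    return [(int(scan[s]), int(e - s)) for s, e in zip(starts, ends)]


def fractional_occupancy(seq: StateSequence, k: int) -> np.ndarray:
    """Fraction of all frames assigned to each state; absent states get 0."""
    counts = np.zeros(k)
    for scan in seq.scans:
        idx, c = np.unique(np.asarray(scan, dtype=int), return_counts=True)
        if idx.max() > k:
            raise ValueError("label exceeds k")
        counts[idx - 1] += c
    return counts / counts.sum()


def dwell_times(seq: StateSequence, k: int) -> np.ndarray:
    """Mean contiguous run length per state, in seconds (NaN if never visited)."""
    lengths = [[] for _ in range(k)]
    for scan in seq.scans:
        for state, length in _runs(scan):
            lengths[state - 1].append(length)
    out = np.full(k, np.nan)
    for j in range(k):
        if lengths[j]:
            out[j] = float(np.mean(lengths[j])) * seq.tr_seconds
    return out


def appearance_rate(seq: StateSequence, k: int) -> np.ndarray:
    """Run starts per state per minute of total scan time (0 if never visited)."""
    starts = np.zeros(k)
    for scan in seq.scans:
        for state, _ in _runs(scan):
            starts[state - 1] += 1
    minutes = seq.n_frames * seq.tr_seconds / 60.0
    return starts / minutes


def transition_probabilities(seq: StateSequence, k: int) -> np.ndarray:
    """Row-stochastic empirical matrix P[i, j] = Pr(next = j | current = i).

    Consecutive pairs are counted within scans only.  The diagonal is the
    persistence probability.  Rows with no outgoing observations are NaN.
    """
    counts = np.zeros((k, k))
    for scan in seq.scans:
        s = np.asarray(scan, dtype=int)
        for a, b in zip(s[:-1], s[1:]):
            counts[a - 1, b - 1] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = counts / totals
    P[totals.squeeze(-1) == 0] = np.nan
    return P


def binarize_to_meta_states(seq: StateSequence, meta_assignment: dict) -> np.ndarray:
    """Map each frame's sub-state to its meta-state, concatenated across scans.

    The assignment must cover every observed label; meta indices are re-coded
    to {0, 1} when exactly two meta-states exist.
    """
    out = []
    for scan in seq.scans:
        for label in np.asarray(scan, dtype=int):
            if label not in meta_assignment:
                raise KeyError(f"state label {label} has no meta-state assignment")
            out.append(meta_assignment[label])
    arr = np.asarray(out, dtype=int)
    metas = np.unique(arr)
    if len(metas) <= 2:
        recode = {m: i for i, m in enumerate(metas)}
        arr = np.asarray([recode[m] for m in arr], dtype=int)
    return arr


def summarize(seq: StateSequence, k: int) -> DynamicsSummary:
    """All four temporal metrics for one subject-condition."""
    return DynamicsSummary(
        fractional_occupancy=fractional_occupancy(seq, k),
        dwell_time_seconds=dwell_times(seq, k),
        appearance_rate_per_min=appearance_rate(seq, k),
        transition_probabilities=transition_probabilities(seq, k),
    )
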