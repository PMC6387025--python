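"""Per-time-step label aggregation: majority voting and duration smoothing.

With overlapping test windows (gamma > 0), each time step is covered by
several windows; its label is the mode of the covering windows' predicted
labels (hard votes).  The voted sequence is then smoothed: any maximal run of
label Ek that is flanked on both sides by one and the same label Ej (j != k)
and lasts shorter than Ek's minimum repetition duration T_min_k is replaced
by Ej; a sub-T_min exercise run flanked by null on both sides likewise
becomes null.  The rule is applied shortest-run-first until a fixpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .types import CLASSES, NULL_LABEL, ExerciseConfig, ValidationError

log = logging.getLogger(__name__)


@dataclass
class LabelSequence:
    """Per-time-step class indices at a stated time resolution."""

    labels: np.ndarray  # int indices into `classes`
    classes: tuple[str, ...] = CLASSES
    resolution_s: float = 0.01
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size == 0:
            raise ValidationError("empty label sequence")
        if self.labels.min() < 0 or self.labels.max() >= len(self.classes):
            raise ValidationError("label index outside the configured class set")

    def codes(self) -> list[str]:
        return [self.classes[i] for i in self.labels]


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (value, start, length)."""
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate(([0], change, [labels.size]))
    return [
        (int(labels[a]), int(a), int(b - a))
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def majority_vote(
    window_labels: list[tuple[int, int]],
    W: int,
    seq_len: int,
    classes: tuple[str, ...] = CLASSES,
    resolution_s: float = 0.01,
    t0: float = 0.0,
) -> LabelSequence:
    """Combine overlapping window votes into one label per time step.

    ``window_labels`` holds (start_index, class_index) pairs; each window
    casts one vote for every step it covers.  Per step the most frequent
    label wins, ties going to the lowest class index.  Steps covered by no
    window inherit the label of the nearest covered step (earlier step on
    ties).
    """
    if not window_labels:
        raise ValidationError("majority_vote needs at least one window")
    votes = np.zeros((seq_len, len(classes)), dtype=np.int32)
    for start, label in window_labels:
        if start < 0 or start + W > seq_len:
            raise ValidationError(
                f"window [{start}, {start + W}) outside sequence of {seq_len}"
            )
        votes[start : start + W, int(label)] += 1
    covered = votes.sum(axis=1) > 0
    labels = votes.argmax(axis=1)  # argmax ties -> lowest class index
    if not covered.all():
        idx_cov = np.flatnonzero(covered)
        if idx_cov.size == 0:
            raise ValidationError("no step covered by any window")
        idx_all = np.arange(seq_len)
        pos = np.searchsorted(idx_cov, idx_all)
        left = np.clip(pos - 1, 0, idx_cov.size - 1)
        right = np.clip(pos, 0, idx_cov.size - 1)
        d_left = np.abs(idx_all - idx_cov[left])
        d_right = np.abs(idx_cov[right] - idx_all)
        nearest = np.where(d_left <= d_right, idx_cov[left], idx_cov[right])
        labels = labels[nearest]
    return LabelSequence(
        labels=labels, classes=classes, resolution_s=resolution_s, t0=t0
    )


def smooth_labels(seq: LabelSequence, cfg: ExerciseConfig) -> LabelSequence:
    """Remove implausibly short exercise runs (shorter than their T_min).

    Shortest runs are processed first, recomputing runs after every
    replacement, until no applicable run remains; runs touching a sequence
    boundary (only one flank) are never altered.  Null runs themselves are
    never replaced.  Raises if an observed exercise label has no configured
    T_min.
    """
    labels = seq.labels.copy()
    classes = seq.classes
    null_idx = classes.index(NULL_LABEL) if NULL_LABEL in classes else -1
    for i in np.unique(labels):
        if i != null_idx and classes[i] not in cfg.t_min:
            raise ValidationError(f"no t_min configured for label {classes[i]}")
    while True:
        runs = _runs(labels)
        candidates = []
        for r, (value, start, length) in enumerate(runs):
            if r == 0 or r == len(runs) - 1:
                continue  # boundary run: only one flank
            if value == null_idx:
                continue
            left_val = runs[r - 1][0]
            right_val = runs[r + 1][0]
            if left_val != right_val or left_val == value:
                continue
            duration = length * seq.resolution_s
            if duration < cfg.t_min[classes[value]] - 1e-12:
                candidates.append((length, start, left_val))
        if not candidates:
            break
        length, start, repl = min(candidates, key=lambda c: (c[0], c[1]))
        labels[start : start + length] = repl
    return LabelSequence(
        labels=labels, classes=classes, resolution_s=seq.resolution_s, t0=seq.t0
    )


def segment_sets(seq: LabelSequence) -> list[tuple[str, float, float]]:
    """Maximal non-null runs as (label, start_s, end_s), ordered by start."""
    null_idx = seq.classes.index(NULL_LABEL) if NULL_LABEL in seq.classes else -1
    out = []
    for value, start, length in _runs(seq.labels):
        if value == null_idx:
            continue
        out.append(
            (
                seq.classes[value],
                seq.t0 + start * seq.resolution_s,
                seq.t0 + (start + length) * seq.resolution_s,
            )
        )
    return out


def write_segments(segments: list[tuple[str, float, float]], path) -> None:
    """Export segments as a tab-separated file: label, start_s, end_s."""
    with open(path, "w") as fh:
        fh.write("label\tstart_s\tend_s\n")
        for label, a, b in segments:
            fh.write(f"{label}\t{a:.3f}\t{b:.3f}\n")
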