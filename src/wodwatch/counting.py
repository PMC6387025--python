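"""Repetition counting from a binary repetition-start sequence.

The per-exercise detector emits one bit per counting-window position (1 = the
window fully contains a repetition start).  A perfect detector would produce
one compact 1-run per repetition, so the count is the number of 1-runs.  Real
output is noisy, and is cleaned with a mode-based rule: let M1 be the most
frequent 1-run length and M0 the most frequent 0-run length; 1-runs of length
>= M1/2 are confirmed repetition starts, shorter runs are removal candidates,
and a candidate survives only if no confirmed run starts within M0/2
positions of it on either side.  The count is the number of remaining 1-runs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
import logging
from typing import Optional, Sequence

import numpy as np

from .types import ChannelMatrix, ExerciseConfig, ValidationError
from .windowing import WindowingConfig, counting_bits_for_positions, window_starts

log = logging.getLogger(__name__)


@dataclass
class BinarySequence:
    """Ordered 0/1 detections, one per counting-window position."""

    bits: np.ndarray
    stride: int = 1  # samples between consecutive window positions

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.size == 0:
            raise ValidationError("empty binary sequence")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValidationError("bits must be 0 or 1")


@dataclass
class RunSummary:
    """Run-length encoding plus the 1-run and 0-run length modes."""

    runs: list[tuple[int, int, int]]  # (value, start_position, length)
    M1: Optional[int]
    M0: Optional[int]

    def runs_of(self, value: int) -> list[tuple[int, int, int]]:
        return [r for r in self.runs if r[0] == value]


def _mode(lengths: list[int]) -> Optional[int]:
    """Most frequent value; ties resolved to the larger length."""
    if not lengths:
        return None
    counts = Counter(lengths)
    best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    return best[0]


def run_lengths(seq: BinarySequence) -> RunSummary:
    """Exact run-length encoding with 1-run / 0-run length modes."""
    bits = seq.bits
    change = np.flatnonzero(np.diff(bits)) + 1
    bounds = np.concatenate(([0], change, [bits.size]))
    runs = [
        (int(bits[a]), int(a), int(b - a)) for a, b in zip(bounds[:-1], bounds[1:])
    ]
    M1 = _mode([r[2] for r in runs if r[0] == 1])
    M0 = _mode([r[2] for r in runs if r[0] == 0])
    return RunSummary(runs=runs, M1=M1, M0=M0)


def smooth_binary(seq: BinarySequence) -> BinarySequence:
    """Remove spurious short 1-runs using the M1/M0 mode rule.

    1-runs of length >= M1/2 are confirmed; shorter ones are candidates and
    are zeroed iff a confirmed run starts within M0/2 positions (start-to-
    start distance, inclusive) before or after the candidate's start.  If no
    run reaches the confirmed threshold the longest 1-run (leftmost on ties)
    is treated as confirmed, with a warning.  Candidates never confirm each
    other; a single pass is made over the candidate set.
    """
    summary = run_lengths(seq)
    ones = summary.runs_of(1)
    if not ones:
        log.warning("smooth_binary: sequence contains no 1-runs")
        return BinarySequence(bits=seq.bits.copy(), stride=seq.stride)
    M1, M0 = summary.M1, summary.M0
    confirmed = [r for r in ones if r[2] >= M1 / 2]
    candidates = [r for r in ones if r[2] < M1 / 2]
    if not confirmed:
        keep = max(ones, key=lambda r: (r[2], -r[1]))
        log.warning(
            "smooth_binary: no 1-run reaches M1/2=%.1f; keeping the longest "
            "run at position %d as confirmed",
            M1 / 2,
            keep[1],
        )
        confirmed = [keep]
        candidates = [r for r in ones if r is not keep]
    bits = seq.bits.copy()
    if candidates and M0 is None:
        # cannot happen for a valid run decomposition (>=2 one-runs imply a
        # zero-run between them) but guard anyway
        return BinarySequence(bits=bits, stride=seq.stride)
    starts = np.array([r[1] for r in confirmed])
    for value, start, length in candidates:
        if np.any(np.abs(starts - start) <= M0 / 2):
            bits[start : start + length] = 0
    return BinarySequence(bits=bits, stride=seq.stride)


def count_repetitions(seq: BinarySequence, smooth: bool = True) -> int:
    """Number of maximal 1-runs after mode-based smoothing."""
    if not seq.bits.any():
        return 0
    if smooth:
        seq = smooth_binary(seq)
    return len(run_lengths(seq).runs_of(1))


def bits_from_starts(
    start_samples: Sequence[int],
    w: int,
    stride: int,
    n_samples: int,
) -> BinarySequence:
    """Ground-truth detector output: the bit sequence a perfect model yields.

    For every window position p (multiples of ``stride``), the bit is 1 iff
    some start segment [v, v + floor(w/2)) lies entirely within [p, p + w).
    """
    positions = window_starts(n_samples, w, stride)
    if positions.size == 0:
        raise ValidationError(f"sequence of {n_samples} samples shorter than {w}")
    half = w // 2
    segments = [(int(v), int(v) + half) for v in start_samples]
    bits = counting_bits_for_positions(positions, w, segments)
    return BinarySequence(bits=bits, stride=stride)


def count_segment(
    matrix: ChannelMatrix,
    label: str,
    models: dict,
    cfg: ExerciseConfig,
    wcfg: Optional[WindowingConfig] = None,
    threshold: float = 0.5,
) -> int:
    """Count repetitions in one recognized exercise segment.

    Windows of the exercise's counting length slide at the configured test
    stride; the per-exercise model's start probability is thresholded into a
    bit sequence which is then smoothed and counted.
    """
    if label not in models:
        raise ValidationError(f"no trained counting model for exercise {label}")
    if wcfg is None:
        wcfg = WindowingConfig(rate=cfg.rate)
    w = cfg.window_samples(label)
    stride = wcfg.counting_stride(w)
    if matrix.n_samples < w:
        log.warning(
            "segment of %d samples shorter than counting window %d for %s",
            matrix.n_samples,
            w,
            label,
        )
        return 0
    from .windowing import window_view  # local import to avoid cycle at load

    X = window_view(matrix.data, w, stride)
    probs = models[label].predict_proba(np.ascontiguousarray(X, dtype=np.float32))
    bits = (probs[:, 1] >= threshold).astype(np.int8)
    if not bits.any():
        return 0
    return count_repetitions(BinarySequence(bits=bits, stride=stride))
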