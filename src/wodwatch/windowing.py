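"""Window extraction and labeling for recognition and counting.

Recognition uses a single window length ``W = T * rate`` (default T = 4 s) for
all exercises; consecutive test windows overlap by a factor gamma (default
0.95), giving a stride of ``round(W * (1 - gamma))`` samples.  Counting uses a
per-exercise window length equal to the shortest observed repetition duration
``T_min`` of that exercise, which guarantees a window never fully contains two
repetition starts; a window is labeled 1 iff it fully contains the "start
segment" — the first ``T_min / 2`` samples after a repetition cue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import logging

import numpy as np

from .types import (
    NULL_LABEL,
    ChannelMatrix,
    ExerciseConfig,
    ExerciseSet,
    Session,
    ValidationError,
    _round_half_up,
)

log = logging.getLogger(__name__)


@dataclass
class WindowingConfig:
    """Windowing parameters shared by the recognition pipeline."""

    T_seconds: float = 4.0
    gamma: float = 0.95
    #: test-time counting stride = max(1, round(w_i / counting_stride_divisor))
    counting_stride_divisor: int = 20
    rate: float = 100.0

    def __post_init__(self) -> None:
        if not (0 <= self.gamma < 1):
            raise ValidationError(f"gamma must be in [0, 1), got {self.gamma}")
        if not self.T_seconds > 0:
            raise ValidationError("T_seconds must be positive")

    @property
    def window_samples(self) -> int:
        return _round_half_up(self.T_seconds * self.rate)

    @property
    def stride_samples(self) -> int:
        return compute_stride(self.window_samples, self.gamma)

    def counting_stride(self, w: int) -> int:
        return max(1, _round_half_up(w / self.counting_stride_divisor))


@dataclass
class Window:
    """One extracted window: a contiguous (W, 3*S) slice of a channel matrix."""

    data: np.ndarray
    start_index: int
    label: Optional[object] = None  # exercise code (recognition) or bit (counting)


def compute_stride(W: int, gamma: float) -> int:
    """Sample stride between consecutive windows with overlap factor gamma."""
    if not (0 <= gamma < 1):
        raise ValidationError(f"gamma must be in [0, 1), got {gamma}")
    if W < 1:
        raise ValidationError("window length must be >= 1 sample")
    return max(1, _round_half_up(W * (1.0 - gamma)))


def window_starts(n_samples: int, W: int, stride: int) -> np.ndarray:
    """Start indices 0, stride, 2*stride, ... of full windows in a sequence."""
    if n_samples < W:
        return np.empty(0, dtype=int)
    count = (n_samples - W) // stride + 1
    return np.arange(count) * stride


def window_view(data: np.ndarray, W: int, stride: int) -> np.ndarray:
    """Zero-copy view of shape (n_windows, W, n_channels)."""
    starts = window_starts(data.shape[0], W, stride)
    if starts.size == 0:
        return np.empty((0, W, data.shape[1]), dtype=data.dtype)
    view = np.lib.stride_tricks.sliding_window_view(data, W, axis=0)
    # sliding_window_view puts the window axis last: (n, C, W) -> (n, W, C)
    return view[starts].transpose(0, 2, 1)


def extract_windows(matrix: ChannelMatrix, W: int, stride: int) -> list[Window]:
    """Extract all full windows of length W at the given stride, in order."""
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    if matrix.n_samples < W:
        log.warning(
            "sequence of %d samples shorter than window %d: no windows",
            matrix.n_samples,
            W,
        )
        return []
    starts = window_starts(matrix.n_samples, W, stride)
    return [Window(data=matrix.data[s : s + W], start_index=int(s)) for s in starts]


def label_recognition_window(
    window: Window, session: Session, matrix: ChannelMatrix
) -> str:
    """Exercise label of the set covering the majority of the window's samples.

    A window is labeled with a set's exercise code iff that set covers at
    least half of the window's samples (ties between two sets split exactly in
    half go to the earlier set); otherwise it is labeled null.
    """
    W = window.data.shape[0]
    t_start = matrix.t0 + window.start_index / matrix.rate
    t_end = t_start + W / matrix.rate
    best_label, best_cov = NULL_LABEL, 0.0
    for s in sorted(session.sets, key=lambda s: s.start_time):
        cov = min(t_end, s.end_time) - max(t_start, s.start_time)
        if cov > best_cov:
            best_label, best_cov = s.label, cov
    if 2.0 * best_cov >= (t_end - t_start):
        return best_label
    return NULL_LABEL


def start_segments(
    set_: ExerciseSet, cfg: ExerciseConfig, matrix_t0: float
) -> tuple[int, list[tuple[int, int]]]:
    """Half-open repetition-start segments [v, v + floor(w/2)) in samples.

    Returns the counting window length ``w`` for the set's exercise and the
    list of start segments, expressed as sample offsets into a matrix whose
    first sample lies at ``matrix_t0``.
    """
    w = cfg.window_samples(set_.label)
    half = w // 2
    segs = []
    for v in set_.vibration_times:
        v_idx = _round_half_up((v - matrix_t0) * cfg.rate)
        segs.append((v_idx, v_idx + half))
    return w, segs


def label_counting_window(
    window: Window,
    set_: ExerciseSet,
    cfg: ExerciseConfig,
    matrix_t0: float = 0.0,
) -> int:
    """1 iff a whole repetition-start segment lies inside the window."""
    w, segs = start_segments(set_, cfg, matrix_t0)
    if window.data.shape[0] != w:
        raise ValidationError(
            f"window length {window.data.shape[0]} != counting window {w} "
            f"for {set_.label}"
        )
    lo = window.start_index
    hi = lo + w
    return int(any(lo <= a and b <= hi for a, b in segs))


def counting_bits_for_positions(
    positions: np.ndarray, w: int, segments: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Vectorized counting labels for window start positions.

    ``bits[k] = 1`` iff some segment ``[a, b)`` satisfies
    ``positions[k] <= a and b <= positions[k] + w``.
    """
    bits = np.zeros(positions.size, dtype=np.int8)
    for a, b in segments:
        bits[(positions <= a) & (b <= positions + w)] = 1
    return bits


def sample_training_batch(
    windows: Sequence, batch_size: int = 30, rng: Optional[np.random.Generator] = None
):
    """Draw a batch i.i.d. uniformly (with replacement) from a window pool."""
    if len(windows) == 0:
        raise ValidationError("cannot sample from an empty window pool")
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.integers(0, len(windows), size=batch_size)
    if isinstance(windows, np.ndarray):
        return windows[idx]
    return [windows[i] for i in idx]
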