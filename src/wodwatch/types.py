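"""Domain types for smartwatch workout recordings.

A recording session consists of irregularly-timestamped 3-axis streams from up
to two devices (wrist, ankle), each providing an accelerometer (m/s^2), a
gyroscope (rad/s) and a software orientation sensor (angles).  Exercise sets
are annotated with a label, a time range, optional vibration-cued repetition
start times and a declared repetition count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

DEVICES = ("wrist", "ankle")
SENSORS = ("accelerometer", "gyroscope", "orientation")
AXES = ("x", "y", "z")

#: Exercise codes: push-up, pull-up, burpee, kettlebell deadlift, box jump,
#: air squat, sit-up, wall ball, kettlebell press, kettlebell thruster.
EXERCISES = tuple(f"E{i}" for i in range(1, 11))
NULL_LABEL = "NULL"
#: Canonical class order used whenever label ties are broken by lowest index.
CLASSES = EXERCISES + (NULL_LABEL,)

EXPERIENCE_LEVELS = ("beginner", "intermediate", "advanced", "unknown")


class ValidationError(ValueError):
    """A domain invariant was violated."""


class FormatError(ValueError):
    """An on-disk artifact does not conform to the session format."""


@dataclass
class SensorStream:
    """One sensor's irregular timestamped 3-axis samples from one device."""

    device: str
    sensor: str
    timestamps: np.ndarray  # seconds, strictly increasing
    values: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        if self.device not in DEVICES:
            raise ValidationError(f"unknown device {self.device!r}")
        if self.sensor not in SENSORS:
            raise ValidationError(f"unknown sensor {self.sensor!r}")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.ndim != 1:
            raise ValidationError("timestamps must be 1-D")
        if self.values.shape != (self.timestamps.shape[0], 3):
            raise ValidationError(
                f"stream {self.key}: values shape {self.values.shape} does not "
                f"match {self.timestamps.shape[0]} timestamps x 3 axes"
            )
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError(
                f"stream {self.key}: timestamps not strictly increasing"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.device, self.sensor)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class ExerciseSet:
    """One annotated set: a label, a time range, optional repetition cues.

    ``vibration_times`` are the wrist-vibration cues of the constrained
    protocol, one per repetition start.  ``reference_starts`` optionally
    carries ground-truth start times for sets recorded without vibrations
    (unconstrained workouts); it is evaluation-only and never used as a
    training label source.
    """

    label: str
    start_time: float
    end_time: float
    vibration_times: Sequence[float] = field(default_factory=tuple)
    declared_reps: Optional[int] = None
    reference_starts: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValidationError(f"unknown exercise label {self.label!r}")
        if not self.end_time > self.start_time:
            raise ValidationError(
                f"set {self.label}: end_time must exceed start_time"
            )
        vt = np.asarray(self.vibration_times, dtype=float)
        if vt.size:
            if not np.all(np.diff(vt) > 0):
                raise ValidationError(
                    f"set {self.label}: vibration times not strictly increasing"
                )
            if vt[0] < self.start_time or vt[-1] > self.end_time:
                raise ValidationError(
                    f"set {self.label}: vibration time outside set bounds"
                )
            if self.declared_reps is not None and self.declared_reps != vt.size:
                raise ValidationError(
                    f"set {self.label}: declared_reps={self.declared_reps} but "
                    f"{vt.size} vibration times"
                )
        self.vibration_times = tuple(float(t) for t in vt)
        if self.reference_starts is not None:
            self.reference_starts = tuple(float(t) for t in self.reference_starts)
        if self.declared_reps is not None and self.declared_reps < 0:
            raise ValidationError("declared_reps must be nonnegative")


@dataclass
class Session:
    """A participant's annotated recording."""

    participant_id: str
    sets: list[ExerciseSet]
    streams: list[SensorStream]
    experience: str = "unknown"

    def __post_init__(self) -> None:
        if self.experience not in EXPERIENCE_LEVELS:
            raise ValidationError(f"unknown experience {self.experience!r}")
        seen = set()
        for s in self.streams:
            if s.key in seen:
                raise ValidationError(f"duplicate stream {s.key}")
            seen.add(s.key)
        ordered = sorted(self.sets, key=lambda s: s.start_time)
        for a, b in zip(ordered, ordered[1:]):
            if b.start_time < a.end_time:
                raise ValidationError(
                    f"sets {a.label} and {b.label} overlap in time"
                )
        if self.sets and self.streams:
            t0 = min(s.timestamps[0] for s in self.streams if s.timestamps.size)
            t1 = max(s.timestamps[-1] for s in self.streams if s.timestamps.size)
            lo = min(s.start_time for s in self.sets)
            hi = max(s.end_time for s in self.sets)
            # small tolerance: jittered sampling may start just after 0
            if lo < t0 - 0.5 or hi > t1 + 0.5:
                raise ValidationError(
                    "set time range not covered by the session's streams"
                )

    def stream(self, device: str, sensor: str) -> SensorStream:
        for s in self.streams:
            if s.key == (device, sensor):
                return s
        raise KeyError((device, sensor))


@dataclass
class ChannelMatrix:
    """Uniformly resampled multi-channel signal, samples x (3*S) channels."""

    rate: float
    data: np.ndarray  # (n_samples, n_channels)
    channel_order: tuple[tuple[str, str, str], ...]  # (device, sensor, axis)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (samples x channels)")
        c = self.data.shape[1]
        if c % 3 != 0:
            raise ValidationError(f"channel count {c} not divisible by 3")
        if len(self.channel_order) != c:
            raise ValidationError("channel_order length must equal channel count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def slice_time(self, start_s: float, end_s: float) -> "ChannelMatrix":
        """Contiguous sub-matrix covering [start_s, end_s) in session time."""
        i0 = max(0, int(np.ceil((start_s - self.t0) * self.rate - 1e-9)))
        i1 = min(self.n_samples, int(np.floor((end_s - self.t0) * self.rate + 1e-9)) + 1)
        return ChannelMatrix(
            rate=self.rate,
            data=self.data[i0:i1],
            channel_order=self.channel_order,
            t0=self.t0 + i0 / self.rate,
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class ExerciseConfig:
    """Per-exercise minimum repetition duration T_min (seconds).

    T_min for an exercise is the shortest repetition (vibration) interval
    observed for it in the training data.  The counting window length is
    ``w = round(T_min * rate)`` samples.
    """

    t_min: dict[str, float]
    rate: float = 100.0

    def __post_init__(self) -> None:
        for label, t in self.t_min.items():
            if label not in EXERCISES:
                raise ValidationError(f"t_min given for non-exercise {label!r}")
            if not t > 0:
                raise ValidationError(f"t_min[{label}] must be positive")
            if self.window_samples(label) < 2:
                raise ValidationError(f"t_min[{label}] too short for rate {self.rate}")

    def window_samples(self, label: str) -> int:
        """Counting window length in samples for one exercise."""
        return _round_half_up(self.t_min[label] * self.rate)

    def t_min_steps(self, label: str, resolution_s: float) -> float:
        return self.t_min[label] / resolution_s
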