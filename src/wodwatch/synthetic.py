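"""Seeded generator of labeled synthetic smartwatch workouts.

The generator emulates the statistical structure the pipeline assumes rather
than biomechanics: two watches (wrist, ankle) x three sensors x three axes
sampled at a jittered ~100 Hz; per exercise a quasi-periodic multi-channel
signature (class-specific harmonic loadings of the repetition frequency,
phase-locked to the repetition start, plus a short initiation transient —
the acceleration burst that starts a repetition); per-subject variation in
amplitude, phase and tempo; a non-periodic null class (sitting / standing /
walking is emulated as a low-amplitude smoothed random walk); vibration-cued
repetition starts in the constrained protocol.

Class signatures are fixed pseudo-random loadings drawn once from the master
seed, which guarantees inter-class distinctness without hand-designing ten
waveforms.  Everything is byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .signals import CANONICAL_PAIRS
from .types import (
    EXERCISES,
    NULL_LABEL,
    ExerciseSet,
    SensorStream,
    Session,
    ValidationError,
)

N_CHANNELS = 3 * len(CANONICAL_PAIRS)  # 18
SCHEMES = ("constrained", "free10", "one-two-three")
_EXPERIENCE_CYCLE = ("beginner", "intermediate", "advanced")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the simulated data collection.

    Defaults mirror the emulated protocol: sets of 15 vibration-cued
    repetitions of each of ten exercises, repetition intervals between 1.5
    and 4 s depending on the exercise, a 90–120 s null recording, sampling
    at a nominal 100 Hz with ~1 ms timestamp jitter.
    """

    n_subjects: int = 12
    exercises: tuple[str, ...] = EXERCISES
    include_null: bool = True
    reps_per_set: Union[int, tuple[int, int]] = 15
    rep_interval_s: tuple[float, float] = (1.5, 4.0)
    harmonics_per_class: int = 3
    signal_amp: float = 2.0
    start_transient_amp: float = 2.0
    subject_amp_sd: float = 0.15
    subject_phase_sd: float = 0.2
    subject_tempo_sd: float = 0.06
    rep_jitter_sd: float = 0.02  # fractional, lengthens intervals only
    noise_sd: float = 0.10
    walk_sd: float = 0.03
    sampling_jitter_sd: float = 0.001
    null_duration_s: tuple[float, float] = (90.0, 120.0)
    rest_between_sets_s: tuple[float, float] = (4.0, 8.0)
    rate: float = 100.0
    scheme: str = "constrained"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        for name in (
            "signal_amp",
            "start_transient_amp",
            "subject_amp_sd",
            "subject_phase_sd",
            "subject_tempo_sd",
            "rep_jitter_sd",
            "noise_sd",
            "walk_sd",
            "sampling_jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.rep_interval_s[0] > 0:
            raise ValidationError("rep_interval_s must be positive")
        for label in self.exercises:
            if label not in EXERCISES:
                raise ValidationError(f"unknown exercise {label!r}")


class _ClassBank:
    """Per-class signature parameters drawn once from the master seed."""

    def __init__(self, cfg: SyntheticConfig, rng: np.random.Generator):
        n = len(cfg.exercises)
        H = cfg.harmonics_per_class
        lo, hi = cfg.rep_interval_s
        self.base_interval = rng.uniform(lo, hi, size=n)
        decay = 1.0 / np.arange(1, H + 1)
        self.amp = rng.normal(0, 1, size=(n, N_CHANNELS, H)) * decay * cfg.signal_amp
        self.phase = rng.uniform(0, 2 * np.pi, size=(n, N_CHANNELS, H))
        self.bump = rng.normal(0, cfg.start_transient_amp, size=(n, N_CHANNELS))
        # fixed channel baselines: gravity on accelerometer z, zero elsewhere
        self.baseline = np.zeros(N_CHANNELS)
        for i, (device, sensor) in enumerate(CANONICAL_PAIRS):
            if sensor == "accelerometer":
                self.baseline[3 * i + 2] = 9.81


@dataclass
class _SetPlan:
    label: str
    start: float
    end: float
    starts: np.ndarray  # repetition start times (seconds)
    durations: np.ndarray  # per-repetition durations (seconds)
    class_index: int  # -1 for null


def _reps_for_set(cfg: SyntheticConfig, rng: np.random.Generator) -> int:
    if isinstance(cfg.reps_per_set, tuple):
        lo, hi = cfg.reps_per_set
        return int(rng.integers(lo, hi + 1))
    return int(cfg.reps_per_set)


def _plan_subject(
    cfg: SyntheticConfig, bank: _ClassBank, rng: np.random.Generator
) -> list[_SetPlan]:
    tempo = float(rng.lognormal(0.0, cfg.subject_tempo_sd))
    plans: list[_SetPlan] = []
    cursor = 2.0
    if cfg.scheme == "one-two-three":
        rounds = [(r + 1) for r in range(3)]
        schedule = [(c, reps) for reps in rounds for c in range(len(cfg.exercises))]
    else:
        default_reps = 10 if cfg.scheme == "free10" else None
        schedule = [
            (c, default_reps if default_reps else _reps_for_set(cfg, rng))
            for c in range(len(cfg.exercises))
        ]
    for c, n_reps in schedule:
        base = bank.base_interval[c] * tempo
        jitter = np.abs(rng.normal(0, cfg.rep_jitter_sd, size=n_reps))
        durations = base * (1.0 + jitter)
        start = cursor + 1.0  # lead-in before the first repetition
        starts = start + np.concatenate(([0.0], np.cumsum(durations[:-1])))
        end = float(starts[-1] + durations[-1] + 0.3)
        plans.append(
            _SetPlan(
                label=cfg.exercises[c],
                start=cursor,
                end=end,
                starts=starts,
                durations=durations,
                class_index=c,
            )
        )
        cursor = end + float(rng.uniform(*cfg.rest_between_sets_s))
    if cfg.include_null:
        dur = float(rng.uniform(*cfg.null_duration_s))
        plans.append(
            _SetPlan(
                label=NULL_LABEL,
                start=cursor,
                end=cursor + dur,
                starts=np.empty(0),
                durations=np.empty(0),
                class_index=-1,
            )
        )
    return plans


def _sets_from_plans(cfg: SyntheticConfig, plans: list[_SetPlan]) -> list[ExerciseSet]:
    sets = []
    for p in plans:
        if p.class_index < 0:
            sets.append(ExerciseSet(label=p.label, start_time=p.start, end_time=p.end))
        elif cfg.scheme == "constrained":
            sets.append(
                ExerciseSet(
                    label=p.label,
                    start_time=p.start,
                    end_time=p.end,
                    vibration_times=tuple(p.starts),
                    declared_reps=len(p.starts),
                )
            )
        else:
            sets.append(
                ExerciseSet(
                    label=p.label,
                    start_time=p.start,
                    end_time=p.end,
                    declared_reps=len(p.starts),
                    reference_starts=tuple(p.starts),
                )
            )
    return sets


def _smooth_walk_fast(n: int, rng: np.random.Generator, walk_sd: float) -> np.ndarray:
    """Leaky integrated noise y[i] = 0.98*y[i-1] + e[i]: slow non-periodic
    drift emulating posture sway / walking about.  Evaluated blockwise with a
    scaled cumulative sum so it stays vectorized and numerically stable."""
    steps = rng.normal(0, walk_sd, size=n)
    leak = 0.98
    out = np.empty(n)
    acc = 0.0
    block = 2048
    for b in range(0, n, block):
        chunk = steps[b : b + block]
        m = chunk.size
        p = leak ** np.arange(1, m + 1)
        out[b : b + m] = np.cumsum(chunk / p) * p + acc * p
        acc = out[b + m - 1]
    return out


def generate_null_segment(
    duration_s: float, cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Standalone non-exercise stream segment (timestamps, values (n, 3)).

    A low-amplitude smoothed random walk plus white noise; no periodic
    structure above the noise floor.
    """
    if not duration_s > 0:
        raise ValidationError("duration must be positive")
    t = _jittered_timestamps(duration_s, cfg, rng)
    values = np.column_stack(
        [
            _smooth_walk_fast(t.size, rng, cfg.walk_sd)
            + rng.normal(0, cfg.noise_sd, size=t.size)
            for _ in range(3)
        ]
    )
    return t, values


def _jittered_timestamps(
    duration_s: float, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    nominal = 1.0 / cfg.rate
    n = int(np.ceil(duration_s * cfg.rate)) + 1
    dt = nominal + rng.normal(0, cfg.sampling_jitter_sd, size=n)
    dt = np.maximum(dt, nominal * 0.2)  # keep strictly increasing
    t = np.concatenate(([0.0], np.cumsum(dt)))[:-1]
    return t[t <= duration_s + nominal]


def _render_channels(
    t: np.ndarray,
    channel_indices: Sequence[int],
    plans: list[_SetPlan],
    bank: _ClassBank,
    amp_gain: np.ndarray,
    phase_off: np.ndarray,
    background: np.ndarray,  # (len(t), len(channel_indices))
    rng: np.random.Generator,
    cfg: SyntheticConfig,
) -> np.ndarray:
    out = np.empty((t.size, len(channel_indices)))
    for k, ch in enumerate(channel_indices):
        out[:, k] = bank.baseline[ch] + background[:, k]
    H = cfg.harmonics_per_class
    for p in plans:
        if p.class_index < 0 or p.starts.size == 0:
            continue
        active_end = p.starts[-1] + p.durations[-1]
        mask = (t >= p.starts[0]) & (t < active_end)
        if not mask.any():
            continue
        tm = t[mask]
        j = np.clip(np.searchsorted(p.starts, tm, side="right") - 1, 0, None)
        phi = (tm - p.starts[j]) / p.durations[j]
        bump = np.exp(-0.5 * ((phi - 0.1) / 0.06) ** 2)
        for k, ch in enumerate(channel_indices):
            sig = bank.bump[p.class_index, ch] * bump
            for h in range(H):
                sig = sig + bank.amp[p.class_index, ch, h] * np.cos(
                    2 * np.pi * (h + 1) * phi
                    + bank.phase[p.class_index, ch, h]
                    + phase_off[ch]
                )
            out[mask, k] += amp_gain[ch] * sig
    out += rng.normal(0, cfg.noise_sd, size=out.shape)
    return out


def _session_for_subject(
    cfg: SyntheticConfig,
    bank: _ClassBank,
    subject_index: int,
    rng: np.random.Generator,
    render: bool,
) -> Session:
    plans = _plan_subject(cfg, bank, rng)
    sets = _sets_from_plans(cfg, plans)
    streams: list[SensorStream] = []
    if render:
        amp_gain = rng.lognormal(0.0, cfg.subject_amp_sd, size=N_CHANNELS)
        phase_off = rng.normal(0.0, cfg.subject_phase_sd, size=N_CHANNELS)
        t_end = plans[-1].end + 1.0
        for i, (device, sensor) in enumerate(CANONICAL_PAIRS):
            t = _jittered_timestamps(t_end, cfg, rng)
            background = np.column_stack(
                [_smooth_walk_fast(t.size, rng, cfg.walk_sd) for _ in range(3)]
            )
            values = _render_channels(
                t,
                [3 * i, 3 * i + 1, 3 * i + 2],
                plans,
                bank,
                amp_gain,
                phase_off,
                background,
                rng,
                cfg,
            )
            streams.append(
                SensorStream(device=device, sensor=sensor, timestamps=t, values=values)
            )
    return Session(
        participant_id=f"S{subject_index + 1:02d}",
        experience=_EXPERIENCE_CYCLE[subject_index % len(_EXPERIENCE_CYCLE)],
        sets=sets,
        streams=streams,
    )


def _subject_rngs(cfg: SyntheticConfig) -> tuple[np.random.Generator, list]:
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_subjects + 1)
    master = np.random.default_rng(children[0])
    return master, [np.random.default_rng(c) for c in children[1:]]


def generate_dataset(cfg: SyntheticConfig) -> list[Session]:
    """Generate one fully rendered session per subject (deterministic)."""
    master, subject_rngs = _subject_rngs(cfg)
    bank = _ClassBank(cfg, master)
    return [
        _session_for_subject(cfg, bank, i, rng, render=True)
        for i, rng in enumerate(subject_rngs)
    ]


def generate_schedules(cfg: SyntheticConfig) -> list[Session]:
    """Annotation-only sessions (no streams): same sets/cues as the rendered
    dataset under the same seed, at negligible cost."""
    master, subject_rngs = _subject_rngs(cfg)
    bank = _ClassBank(cfg, master)
    return [
        _session_for_subject(cfg, bank, i, rng, render=False)
        for i, rng in enumerate(subject_rngs)
    ]


def ground_truth_table(sessions: Sequence[Session]) -> pd.DataFrame:
    """Per-set ground truth: participant, label, repetition starts, count."""
    rows = []
    for session in sessions:
        for k, s in enumerate(session.sets):
            if s.label == NULL_LABEL:
                continue
            starts = s.vibration_times or s.reference_starts or ()
            count = s.declared_reps if s.declared_reps is not None else len(starts)
            rows.append(
                {
                    "participant": session.participant_id,
                    "set_index": k,
                    "label": s.label,
                    "start_time": s.start_time,
                    "end_time": s.end_time,
                    "n_reps": count,
                    "rep_starts": tuple(starts),
                }
            )
    return pd.DataFrame(rows)
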