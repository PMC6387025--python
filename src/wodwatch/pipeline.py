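"""End-to-end orchestration: pools, training, prediction, benchmarks.

The full pipeline is: resample streams to 100 Hz -> stack selected sensors
into an 18-channel matrix -> recognition CNN on 4 s windows -> majority vote
over overlapping windows (gamma = 0.95) -> minimum-duration smoothing ->
segment the label track -> route each recognized segment to that exercise's
counting CNN -> threshold, mode-smooth and count the binary output.

Two model/training configurations are provided: the full-scale defaults of
:mod:`wodwatch.nets` (5 conv layers, SGD lr 1e-4, up to 100 epochs) and a
desk-scale configuration (``DESK_SPEC`` / ``DESK_TRAIN``) small enough to
train the whole grouped 5-fold benchmark plus ten counting models on one CPU
in minutes; the desk-scale settings are what the bundled benchmarks and the
reproduction script use.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import nets
from .counting import BinarySequence, count_repetitions
from .evaluation import FoldPlan, accuracy_and_confusion, grouped_kfold
from .recognition import LabelSequence, majority_vote, segment_sets, smooth_labels
from .signals import ALL_SENSORS, assemble_channels
from .types import (
    CLASSES,
    NULL_LABEL,
    ChannelMatrix,
    ExerciseConfig,
    Session,
    ValidationError,
)
from .windowing import (
    WindowingConfig,
    counting_bits_for_positions,
    start_segments,
    window_starts,
    window_view,
)

log = logging.getLogger(__name__)

#: Reduced architecture for one-CPU benchmarks: 3 conv layers, temporal
#: stride 2 in the deeper layers, one dense layer of 64 units.
DESK_SPEC = nets.ModelSpec(
    n_conv_layers=3,
    filters=(24, 16, 16),
    first_kernel=(15, 3),
    first_time_stride=2,
    kernel_time=9,
    conv_time_stride=2,
    dense_units=(64,),
    dropout=0.2,
)

#: Matching optimization settings: momentum SGD with a larger step and a
#: tight epoch budget, input normalization on.
DESK_TRAIN = nets.TrainConfig(
    batch_size=30,
    learning_rate=0.02,
    momentum=0.9,
    max_epochs=15,
    early_stopping_patience=3,
    normalize_input=True,
)


def exercise_config_from_sessions(
    sessions: Sequence[Session], rate: float = 100.0
) -> ExerciseConfig:
    """Per-exercise T_min = shortest vibration interval observed."""
    t_min: dict[str, float] = {}
    for session in sessions:
        for s in session.sets:
            if len(s.vibration_times) < 2:
                continue
            shortest = float(np.min(np.diff(s.vibration_times)))
            if s.label not in t_min or shortest < t_min[s.label]:
                t_min[s.label] = shortest
    if not t_min:
        raise ValidationError("no vibration-annotated sets in the given sessions")
    return ExerciseConfig(t_min=t_min, rate=rate)


def _true_track(session: Session, matrix: ChannelMatrix, classes=CLASSES) -> np.ndarray:
    """Ground-truth class index per matrix sample (null outside sets)."""
    idx = {c: i for i, c in enumerate(classes)}
    track = np.full(matrix.n_samples, idx[NULL_LABEL], dtype=np.int64)
    t = matrix.times()
    for s in session.sets:
        track[(t >= s.start_time) & (t < s.end_time)] = idx[s.label]
    return track


def build_recognition_pool(
    sessions: Sequence[Session],
    selection=ALL_SENSORS,
    wcfg: Optional[WindowingConfig] = None,
    stride: Optional[int] = None,
    classes=CLASSES,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labeled recognition windows from whole sessions.

    Returns (X, y, groups): windows (n, W, C) float32, class indices, and the
    participant id of each window (for grouped splits).  ``stride`` defaults
    to a non-overlapping W for training pools.
    """
    wcfg = wcfg or WindowingConfig()
    W = wcfg.window_samples
    stride = stride or W
    idx = {c: i for i, c in enumerate(classes)}
    xs, ys, gs = [], [], []
    for session in sessions:
        matrix = assemble_channels(session, selection, rate=wcfg.rate)
        track = _true_track(session, matrix, classes)
        starts = window_starts(matrix.n_samples, W, stride)
        if starts.size == 0:
            continue
        X = window_view(matrix.data, W, stride)
        # majority-coverage label of each window, vectorized via the track
        labels = np.empty(starts.size, dtype=np.int64)
        null_i = idx[NULL_LABEL]
        for k, s0 in enumerate(starts):
            seg = track[s0 : s0 + W]
            vals, counts = np.unique(seg, return_counts=True)
            best = counts.argmax()
            labels[k] = vals[best] if 2 * counts[best] >= W else null_i
        xs.append(np.ascontiguousarray(X, dtype=np.float32))
        ys.append(labels)
        gs.append(np.full(starts.size, session.participant_id, dtype=object))
    if not xs:
        raise ValidationError("no windows could be extracted from the sessions")
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(gs)


def train_recognizer(
    sessions: Sequence[Session],
    selection=ALL_SENSORS,
    wcfg: Optional[WindowingConfig] = None,
    spec: nets.ModelSpec = DESK_SPEC,
    tcfg: nets.TrainConfig = DESK_TRAIN,
    classes=CLASSES,
    val_sessions: Optional[Sequence[Session]] = None,
) -> tuple[nets.ConvNet, dict]:
    """Train one recognition model on whole sessions."""
    X, y, _ = build_recognition_pool(sessions, selection, wcfg, classes=classes)
    val = None
    if val_sessions:
        Xv, yv, _ = build_recognition_pool(val_sessions, selection, wcfg, classes=classes)
        val = (Xv, yv)
    model = nets.build_model(spec, X.shape[1:], len(classes), seed=tcfg.rng_seed)
    return nets.train(model, (X, y), val, tcfg)


def predict_session(
    model: nets.ConvNet,
    session: Session,
    ecfg: ExerciseConfig,
    selection=ALL_SENSORS,
    wcfg: Optional[WindowingConfig] = None,
    classes=CLASSES,
) -> tuple[LabelSequence, list[tuple[str, float, float]], ChannelMatrix]:
    """Overlapping-window prediction, majority vote and duration smoothing.

    Returns the smoothed per-sample label sequence, its non-null segments
    (label, start_s, end_s) and the assembled channel matrix.
    """
    wcfg = wcfg or WindowingConfig()
    W = wcfg.window_samples
    matrix = assemble_channels(session, selection, rate=wcfg.rate)
    starts = window_starts(matrix.n_samples, W, wcfg.stride_samples)
    if starts.size == 0:
        raise ValidationError("session shorter than one recognition window")
    X = np.ascontiguousarray(
        window_view(matrix.data, W, wcfg.stride_samples), dtype=np.float32
    )
    _, labels = nets.predict_windows(model, X)
    seq = majority_vote(
        list(zip(starts.tolist(), labels.tolist())),
        W,
        matrix.n_samples,
        classes=classes,
        resolution_s=1.0 / wcfg.rate,
        t0=matrix.t0,
    )
    seq = smooth_labels(seq, ecfg)
    return seq, segment_sets(seq), matrix


def build_counting_pool(
    sessions: Sequence[Session],
    label: str,
    ecfg: ExerciseConfig,
    selection=ALL_SENSORS,
    train_stride_divisor: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary-labeled counting windows for one exercise.

    Only vibration-annotated (constrained) sets contribute.  Each set is
    resampled over its own time range; windows of the exercise's counting
    length w slide at stride ``max(1, round(w / train_stride_divisor))`` and
    are labeled 1 iff they fully contain a repetition-start segment.
    """
    w = ecfg.window_samples(label)
    stride = max(1, int(np.floor(w / train_stride_divisor + 0.5)))
    xs, ys = [], []
    for session in sessions:
        for s in session.sets:
            if s.label != label or not s.vibration_times:
                continue
            matrix = assemble_channels(
                session, selection, grid=(s.start_time, s.end_time), rate=ecfg.rate
            )
            if matrix.n_samples < w:
                continue
            positions = window_starts(matrix.n_samples, w, stride)
            _, segs = start_segments(s, ecfg, matrix.t0)
            bits = counting_bits_for_positions(positions, w, segs)
            X = window_view(matrix.data, w, stride)
            xs.append(np.ascontiguousarray(X, dtype=np.float32))
            ys.append(bits.astype(np.int64))
    if not xs:
        raise ValidationError(f"no constrained sets found for exercise {label}")
    return np.concatenate(xs), np.concatenate(ys)


def train_counters(
    sessions: Sequence[Session],
    ecfg: ExerciseConfig,
    selection=ALL_SENSORS,
    spec: nets.ModelSpec = DESK_SPEC,
    tcfg: nets.TrainConfig = DESK_TRAIN,
    labels: Optional[Sequence[str]] = None,
) -> dict[str, nets.ConvNet]:
    """One binary repetition-start model per exercise."""
    labels = list(labels) if labels is not None else sorted(ecfg.t_min)
    models = {}
    for label in labels:
        X, y = build_counting_pool(sessions, label, ecfg, selection)
        model = nets.build_model(spec, X.shape[1:], 2, seed=tcfg.rng_seed)
        model, _ = nets.train(model, (X, y), None, tcfg)
        models[label] = model
    return models


def count_annotated_sets(
    sessions: Sequence[Session],
    counters: dict[str, nets.ConvNet],
    ecfg: ExerciseConfig,
    selection=ALL_SENSORS,
    wcfg: Optional[WindowingConfig] = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Predicted vs true counts per annotated set (ground-truth segmentation).

    Each exercise set is counted with its own model over its annotated time
    range — this isolates counting quality from recognition quality.
    """
    wcfg = wcfg or WindowingConfig(rate=ecfg.rate)
    rows = []
    for session in sessions:
        for k, s in enumerate(session.sets):
            if s.label == NULL_LABEL or s.label not in counters:
                continue
            w = ecfg.window_samples(s.label)
            stride = wcfg.counting_stride(w)
            matrix = assemble_channels(
                session, selection, grid=(s.start_time, s.end_time), rate=ecfg.rate
            )
            pred: Optional[int]
            if matrix.n_samples < w:
                pred = 0
            else:
                X = np.ascontiguousarray(
                    window_view(matrix.data, w, stride), dtype=np.float32
                )
                probs = counters[s.label].predict_proba(X)
                bits = (probs[:, 1] >= threshold).astype(np.int8)
                pred = (
                    count_repetitions(BinarySequence(bits=bits, stride=stride))
                    if bits.any()
                    else 0
                )
            truth = s.declared_reps
            if truth is None:
                truth = len(s.vibration_times)
            rows.append(
                {
                    "participant": session.participant_id,
                    "set_index": k,
                    "label": s.label,
                    "pred": pred,
                    "true": truth,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# benchmarks


@dataclass
class RecognitionCVResult:
    window_accuracy: float
    step_accuracy: float
    fold_window_accuracies: list[float]
    confusion: pd.DataFrame
    n_windows: int
    n_steps: int


def recognition_cv(
    sessions: Sequence[Session],
    plan: Optional[FoldPlan] = None,
    selection=ALL_SENSORS,
    wcfg: Optional[WindowingConfig] = None,
    spec: nets.ModelSpec = DESK_SPEC,
    tcfg: nets.TrainConfig = DESK_TRAIN,
    seed: int = 0,
    classes=CLASSES,
    with_step_accuracy: bool = True,
) -> RecognitionCVResult:
    """Subject-grouped cross-validated recognition benchmark.

    Per fold, a model is trained on the training subjects' windows and scored
    on the held-out subjects: window-level accuracy on non-overlapping
    windows, and (optionally) per-time-step accuracy of the voted + smoothed
    label track against the ground-truth track.
    """
    wcfg = wcfg or WindowingConfig()
    by_id = {s.participant_id: s for s in sessions}
    if plan is None:
        plan = grouped_kfold(sorted(by_id), k=5, seed=seed)
    ecfg = exercise_config_from_sessions(sessions, rate=wcfg.rate)
    y_true_all, y_pred_all = [], []
    step_hits = step_total = 0
    fold_accs = []
    for f, (train_ids, test_ids) in enumerate(plan.folds):
        train_sessions = [by_id[i] for i in train_ids]
        test_sessions = [by_id[i] for i in test_ids]
        fold_tcfg = dataclasses.replace(tcfg, rng_seed=tcfg.rng_seed + f)
        model, _ = train_recognizer(
            train_sessions, selection, wcfg, spec, fold_tcfg, classes
        )
        Xt, yt, _ = build_recognition_pool(test_sessions, selection, wcfg, classes=classes)
        _, pred = nets.predict_windows(model, Xt)
        fold_accs.append(float(np.mean(pred == yt)))
        y_true_all.append(yt)
        y_pred_all.append(pred)
        if with_step_accuracy:
            for session in test_sessions:
                seq, _, matrix = predict_session(
                    model, session, ecfg, selection, wcfg, classes
                )
                truth = _true_track(session, matrix, classes)
                step_hits += int(np.sum(seq.labels == truth))
                step_total += truth.size
    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    acc, confusion = accuracy_and_confusion(y_true, y_pred, range(len(classes)))
    confusion.index = confusion.columns = list(classes)
    return RecognitionCVResult(
        window_accuracy=acc,
        step_accuracy=step_hits / step_total if step_total else float("nan"),
        fold_window_accuracies=fold_accs,
        confusion=confusion,
        n_windows=int(y_true.size),
        n_steps=int(step_total),
    )


def counting_holdout(
    sessions: Sequence[Session],
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    selection=ALL_SENSORS,
    spec: nets.ModelSpec = DESK_SPEC,
    tcfg: nets.TrainConfig = DESK_TRAIN,
    wcfg: Optional[WindowingConfig] = None,
) -> pd.DataFrame:
    """Train per-exercise counters on train subjects, count held-out sets."""
    by_id = {s.participant_id: s for s in sessions}
    train_sessions = [by_id[i] for i in train_ids]
    test_sessions = [by_id[i] for i in test_ids]
    ecfg = exercise_config_from_sessions(train_sessions)
    counters = train_counters(train_sessions, ecfg, selection, spec, tcfg)
    return count_annotated_sets(test_sessions, counters, ecfg, selection, wcfg)
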