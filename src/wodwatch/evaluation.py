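"""Subject-grouped cross-validation plans and the reported metrics.

Because windows from one participant are highly correlated, folds are always
split by participant: every participant's data ends up entirely in the train
or entirely in the test side of each fold.  Recognition is scored by accuracy
and a row-normalized confusion matrix; counting by the mean absolute error
(MAE), mean relative error (MRE) and the fraction of sets whose count is off
by 0, 1, 2 or more than 2 repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .types import ValidationError

log = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    """Participant-level train/test split plan."""

    folds: list[tuple[tuple[str, ...], tuple[str, ...]]]
    scheme: str  # "kfold5" | "loso"

    def __post_init__(self) -> None:
        tested: list[str] = []
        for train, test in self.folds:
            if set(train) & set(test):
                raise ValidationError("train/test overlap within a fold")
            tested.extend(test)
        if len(tested) != len(set(tested)):
            raise ValidationError("a participant is tested in more than one fold")


@dataclass
class CountingMetrics:
    """Counting performance over a collection of sets."""

    mae: float
    mre: float  # fraction, not percent
    bucket_0: float
    bucket_1: float
    bucket_2: float
    bucket_gt2: float
    n_sets: int
    n_not_recognized: int = 0

    @property
    def within_1(self) -> float:
        return self.bucket_0 + self.bucket_1

    def as_row(self) -> dict:
        """Row in the printed-table convention (MRE and buckets in percent)."""
        return {
            "MAE": round(self.mae, 2),
            "MRE_pct": round(100 * self.mre, 1),
            "e0_pct": round(100 * self.bucket_0, 1),
            "e1_pct": round(100 * self.bucket_1, 1),
            "e2_pct": round(100 * self.bucket_2, 1),
            "egt2_pct": round(100 * self.bucket_gt2, 1),
            "n_sets": self.n_sets,
            "n_not_recognized": self.n_not_recognized,
        }


def grouped_kfold(
    participants: Sequence[str], k: int = 5, seed: int = 0
) -> FoldPlan:
    """Partition participants into k near-equal test groups, deterministically."""
    ids = list(participants)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate participant ids")
    if len(ids) < k:
        raise ValidationError(f"need at least {k} participants, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    groups = np.array_split(order, k)
    folds = []
    for g in groups:
        test = tuple(g)
        train = tuple(p for p in ids if p not in set(test))
        folds.append((train, test))
    return FoldPlan(folds=folds, scheme=f"kfold{k}")


def loso_folds(participants: Sequence[str]) -> FoldPlan:
    """Leave-one-subject-out: one fold per participant."""
    ids = list(participants)
    if len(ids) < 2:
        raise ValidationError("LOSO needs at least 2 participants")
    folds = [
        (tuple(p for p in ids if p != test), (test,)) for test in ids
    ]
    return FoldPlan(folds=folds, scheme="loso")


def accuracy_and_confusion(
    true_labels: Sequence,
    predicted_labels: Sequence,
    classes: Sequence,
) -> tuple[float, pd.DataFrame]:
    """Accuracy and a row-normalized confusion matrix over ``classes``.

    Rows are true classes and sum to 1 for classes that occur in
    ``true_labels``; rows of unobserved classes are all zero.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape:
        raise ValidationError("true/predicted label lengths differ")
    acc = float(np.mean(y_true == y_pred))
    cm = _sk_confusion(y_true, y_pred, labels=list(classes)).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cm = np.where(row_sums > 0, cm / row_sums, 0.0)
    return acc, pd.DataFrame(cm, index=list(classes), columns=list(classes))


def counting_metrics(
    pred_counts: Sequence[float],
    true_counts: Sequence[float],
    n_not_recognized: int = 0,
) -> CountingMetrics:
    """MAE, MRE and |error| buckets for per-set repetition counts.

    Sets whose exercise was not recognized are excluded from the error
    statistics and reported via ``n_not_recognized``.  Sets with a zero true
    count are excluded from the MRE (with a warning).
    """
    pred = np.asarray(pred_counts, dtype=float)
    true = np.asarray(true_counts, dtype=float)
    if pred.shape != true.shape:
        raise ValidationError("pred/true count lengths differ")
    if pred.size == 0:
        raise ValidationError("no sets to score")
    err = np.abs(pred - true)
    nonzero = true > 0
    if not nonzero.all():
        log.warning(
            "excluding %d zero-true-count sets from the MRE", int((~nonzero).sum())
        )
    mre = float(np.mean(err[nonzero] / true[nonzero])) if nonzero.any() else 0.0
    return CountingMetrics(
        mae=float(err.mean()),
        mre=mre,
        bucket_0=float(np.mean(err == 0)),
        bucket_1=float(np.mean(err == 1)),
        bucket_2=float(np.mean(err == 2)),
        bucket_gt2=float(np.mean(err > 2)),
        n_sets=int(pred.size),
        n_not_recognized=int(n_not_recognized),
    )


def counting_table(
    per_set: pd.DataFrame, by: str = "label"
) -> pd.DataFrame:
    """Per-exercise counting table (MAE, MRE, |e| buckets) plus a Total row.

    ``per_set`` needs columns ``label``, ``pred`` and ``true``; rows with a
    missing ``pred`` (exercise not recognized) are tallied separately.
    """
    rows = {}
    recognized = per_set[per_set["pred"].notna()]
    for label, grp in recognized.groupby(by, sort=True):
        n_nr = int((per_set[by] == label).sum() - len(grp))
        rows[label] = counting_metrics(grp["pred"], grp["true"], n_nr).as_row()
    total_nr = int(per_set["pred"].isna().sum())
    rows["Total"] = counting_metrics(
        recognized["pred"], recognized["true"], total_nr
    ).as_row()
    return pd.DataFrame.from_dict(rows, orient="index")


def plot_confusion(confusion: pd.DataFrame, path) -> None:
    """Save a row-normalized confusion matrix as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(confusion.to_numpy(), vmin=0, vmax=1, cmap="Blues")
    ax.set_xticks(range(len(confusion.columns)), confusion.columns, rotation=90)
    ax.set_yticks(range(len(confusion.index)), confusion.index)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax, label="fraction of true class")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def collection_summary(per_exercise: pd.DataFrame) -> pd.DataFrame:
    """Dataset overview: per-exercise time, repetitions, fraction of time.

    ``per_exercise`` needs columns ``exercise``, ``time_min`` and ``reps``.
    Adds a ``fraction_of_time`` column (share of total recorded exercise
    time) and a ``Total`` row with the column sums.
    """
    for col in ("exercise", "time_min", "reps"):
        if col not in per_exercise.columns:
            raise ValidationError(f"missing column {col!r}")
    df = per_exercise.set_index("exercise")[["time_min", "reps"]].astype(float)
    total_time = df["time_min"].sum()
    df["fraction_of_time"] = df["time_min"] / total_time
    total = pd.DataFrame(
        {
            "time_min": [total_time],
            "reps": [df["reps"].sum()],
            "fraction_of_time": [1.0],
        },
        index=["Total"],
    )
    out = pd.concat([df, total])
    out["reps"] = out["reps"].astype(int)
    return out
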