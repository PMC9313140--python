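"""Leave-one-subject-out evaluation and the window-length sweep.

LOSO: one fold per participant; the model trains on everyone else and is
tested on the held-out participant, so reported numbers measure
generalisation to an unseen person.  The sweep repeats the whole LOSO
procedure for every window length on a grid, records per-participant
accuracy and per-activity precision/recall/F1 (averaged across
participants with equal weight), and locates the saturation point — the
smallest window length beyond which mean accuracy stops improving by more
than epsilon per grid step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .activities import ACTIVITIES
from .estimator import CNNLSTMClassifier
from .features import FeatureMatrix
from .windowing import WindowSet, segment

__all__ = [
    "loso_splits",
    "confusion_matrix",
    "metrics",
    "find_saturation",
    "SweepReport",
    "sweep_window_lengths",
]

logger = logging.getLogger(__name__)


def loso_splits(participant_ids: Sequence[int]) -> list[tuple[list[int], int]]:
    """One (train_ids, test_id) fold per participant."""
    pids = list(participant_ids)
    if len(pids) < 2:
        raise ValueError("leave-one-subject-out needs >= 2 participants")
    if len(set(pids)) != len(pids):
        raise ValueError("participant ids must be unique")
    return [([p for p in pids if p != test], test) for test in pids]


def confusion_matrix(
    y_true, y_pred, class_order: Sequence[str] = ACTIVITIES
) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    index = {c: i for i, c in enumerate(class_order)}
    conf = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for t, p in zip(np.asarray(y_true).ravel(), np.asarray(y_pred).ravel()):
        conf[index[t], index[p]] += 1
    return conf


def metrics(conf: np.ndarray, class_order: Sequence[str] = ACTIVITIES) -> dict:
    """Accuracy plus per-class precision, recall and F1 from a confusion matrix.

    Zero-denominator precision/recall are defined as 0, and F1 = 0 when
    precision + recall = 0 (a held-out participant may lack predictions
    for a class entirely).
    """
    conf = np.asarray(conf)
    total = conf.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(conf).astype(float)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2.0 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    return {
        "accuracy": float(tp.sum() / total),
        "precision": dict(zip(class_order, precision)),
        "recall": dict(zip(class_order, recall)),
        "f1": dict(zip(class_order, f1)),
    }


def find_saturation(
    window_lengths: Sequence[int],
    mean_accuracy: Sequence[float],
    epsilon: float = 0.01,
) -> int | None:
    """Smallest grid W after which every successive mean-accuracy increment
    is below *epsilon*; ``None`` if the curve keeps climbing."""
    ws = list(window_lengths)
    acc = list(mean_accuracy)
    if len(ws) < 3:
        raise ValueError("saturation detection needs >= 3 grid points")
    order = np.argsort(ws)
    ws = [ws[i] for i in order]
    acc = [acc[i] for i in order]
    increments = np.diff(acc)
    for i, w in enumerate(ws[:-1]):
        if np.all(increments[i:] < epsilon):
            return w
    return None


@dataclass
class SweepReport:
    """Tidy result tables of a window-length sweep."""

    accuracy: pd.DataFrame       # participant, window_length, accuracy
    activity: pd.DataFrame       # window_length, activity, precision, recall, f1
    summary: pd.DataFrame        # window_length, mean_accuracy, sd_accuracy
    failed: list[int] = field(default_factory=list)

    def saturation(self, epsilon: float = 0.01) -> int | None:
        if len(self.summary) < 3:
            return None
        return find_saturation(
            self.summary["window_length"].tolist(),
            self.summary["mean_accuracy"].tolist(),
            epsilon,
        )

    def to_tidy(self) -> pd.DataFrame:
        """Long format: participant, window_length, activity, metric, value."""
        acc = self.accuracy.assign(activity="all", metric="accuracy").rename(
            columns={"accuracy": "value"}
        )
        act = self.activity.melt(
            id_vars=["window_length", "activity"],
            value_vars=["precision", "recall", "f1"],
            var_name="metric", value_name="value",
        ).assign(participant=-1)
        return pd.concat(
            [acc[["participant", "window_length", "activity", "metric", "value"]],
             act[["participant", "window_length", "activity", "metric", "value"]]],
            ignore_index=True,
        )

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_tidy().to_csv(out_dir / "sweep_tidy.csv", index=False)
        summary = {
            "window_lengths": self.summary["window_length"].tolist(),
            "mean_accuracy": self.summary["mean_accuracy"].tolist(),
            "sd_accuracy": self.summary["sd_accuracy"].tolist(),
            "saturation_window_length": self.saturation(),
            "failed_window_lengths": self.failed,
        }
        (out_dir / "sweep_summary.json").write_text(json.dumps(summary, indent=2))


def _run_fold(
    train_ws: WindowSet,
    test_ws: WindowSet,
    estimator_params: dict,
    seed: int,
) -> dict:
    clf = CNNLSTMClassifier(random_state=seed, **estimator_params)
    clf.fit(train_ws.windows, train_ws.labels)
    pred = clf.predict(test_ws.windows)
    conf = confusion_matrix(test_ws.labels, pred)
    return metrics(conf)


def sweep_window_lengths(
    cohort_features: Sequence[FeatureMatrix],
    window_lengths: Sequence[int],
    seed: int = 0,
    estimator_params: Mapping | None = None,
    stride: int = 1,
) -> SweepReport:
    """LOSO-evaluate the classifier at every window length on the grid.

    ``estimator_params`` are forwarded to :class:`CNNLSTMClassifier`
    (architecture, epochs, batch size, ...).  A window length that fails to
    build or train is recorded in ``failed`` and the sweep continues.
    Per-activity metrics are averaged across participants with equal
    weight.  Deterministic under *seed*: each (window length, fold) pair
    gets an independent derived seed.
    """
    if not window_lengths:
        raise ValueError("window_lengths must be non-empty")
    params = dict(estimator_params or {})
    params.setdefault("architecture", "desk")
    pids = [fm.participant_id for fm in cohort_features]
    by_pid = {fm.participant_id: fm for fm in cohort_features}
    acc_rows, act_rows, failed = [], [], []
    root = np.random.SeedSequence(seed)
    for wi, W in enumerate(window_lengths):
        try:
            segmented = {
                pid: segment(by_pid[pid], W, stride) for pid in pids
            }
            fold_metrics = []
            for fi, (train_ids, test_id) in enumerate(loso_splits(pids)):
                fold_seed = int(
                    np.random.SeedSequence([seed, wi, fi]).generate_state(1)[0]
                    % (2**31)
                )
                train_ws = _concat_windows([segmented[p] for p in train_ids])
                res = _run_fold(train_ws, segmented[test_id], params, fold_seed)
                fold_metrics.append((test_id, res))
                acc_rows.append(
                    {"participant": test_id, "window_length": W,
                     "accuracy": res["accuracy"]}
                )
            for activity in ACTIVITIES:
                act_rows.append(
                    {
                        "window_length": W,
                        "activity": activity,
                        "precision": float(np.mean(
                            [m["precision"][activity] for _, m in fold_metrics])),
                        "recall": float(np.mean(
                            [m["recall"][activity] for _, m in fold_metrics])),
                        "f1": float(np.mean(
                            [m["f1"][activity] for _, m in fold_metrics])),
                    }
                )
        except Exception:
            logger.exception("window length %d failed; continuing", W)
            failed.append(W)
    acc = pd.DataFrame(acc_rows)
    summary = (
        acc.groupby("window_length")["accuracy"]
        .agg(mean_accuracy="mean", sd_accuracy="std")
        .reset_index()
        .fillna({"sd_accuracy": 0.0})
        if len(acc)
        else pd.DataFrame(columns=["window_length", "mean_accuracy", "sd_accuracy"])
    )
    return SweepReport(
        accuracy=acc, activity=pd.DataFrame(act_rows), summary=summary, failed=failed
    )


def _concat_windows(parts: Sequence[WindowSet]) -> WindowSet:
    return WindowSet(
        windows=np.concatenate([p.windows for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        participant_ids=np.concatenate([p.participant_ids for p in parts]),
        window_length=parts[0].window_length,
        stride=parts[0].stride,
        feature_names=parts[0].feature_names,
    )
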