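"""Sliding-window segmentation and overlap-ratio bookkeeping.

Feature streams are cut into fixed-length windows of W consecutive samples
at stride s (default 1, i.e. consecutive windows share W−1 samples).  Each
window is labeled by the activity of its **last** sample, and windows never
span a trial boundary, so a window cannot mix activities.

The overlap ratio is the number of samples shared by consecutive windows
over the window length: (W − s)/W, clipped at 0.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix

__all__ = [
    "WindowSet",
    "n_windows",
    "overlap_ratio",
    "overlap_pct",
    "segment",
    "segment_cohort",
    "bookkeeping_table",
    "save_windows",
    "load_windows",
]

logger = logging.getLogger(__name__)


@dataclass
class WindowSet:
    """Order-3 tensor of windows plus one label and participant id each."""

    windows: np.ndarray            # (n_windows, W, n_features)
    labels: np.ndarray             # (n_windows,)
    participant_ids: np.ndarray    # (n_windows,)
    window_length: int
    stride: int
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.windows = np.ascontiguousarray(self.windows, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=object)
        self.participant_ids = np.asarray(self.participant_ids, dtype=np.int64)
        n = len(self.windows)
        if self.windows.ndim != 3 or self.windows.shape[1] != self.window_length:
            raise ValueError("windows must be (n, W, F)")
        if len(self.labels) != n or len(self.participant_ids) != n:
            raise ValueError("labels/participant_ids must match window count")

    def __len__(self) -> int:
        return len(self.windows)

    def subset(self, mask: np.ndarray) -> "WindowSet":
        return WindowSet(
            self.windows[mask], self.labels[mask], self.participant_ids[mask],
            self.window_length, self.stride, self.feature_names,
        )

    def for_participants(self, pids: Sequence[int]) -> "WindowSet":
        return self.subset(np.isin(self.participant_ids, list(pids)))


def n_windows(n_rows: int, window_length: int, stride: int = 1) -> int:
    """Window count for a single contiguous stream of ``n_rows`` samples."""
    if n_rows < window_length:
        return 0
    return (n_rows - window_length) // stride + 1


def overlap_ratio(window_length: int, stride: int = 1) -> float:
    """Fraction of samples shared by consecutive windows: max(0, W−s)/W."""
    if window_length < 1 or stride < 1:
        raise ValueError("window_length and stride must be >= 1")
    return max(0, window_length - stride) / window_length


def overlap_pct(window_length: int, stride: int = 1) -> float:
    """Overlap ratio as a percentage truncated to two decimals (the table
    convention: 44/45 prints as 97.77, not 97.78)."""
    return math.floor(10_000.0 * overlap_ratio(window_length, stride)) / 100.0


def _segment_block(values: np.ndarray, W: int, stride: int) -> np.ndarray:
    count = n_windows(len(values), W, stride)
    if count == 0:
        return np.empty((0, W, values.shape[1]), dtype=values.dtype)
    view = np.lib.stride_tricks.sliding_window_view(values, W, axis=0)
    # view: (N-W+1, F, W) -> (count, W, F)
    return view[::stride].transpose(0, 2, 1)[:count]


def segment(fm: FeatureMatrix, window_length: int, stride: int = 1) -> WindowSet:
    """Segment one participant's feature matrix, per contiguous trial.

    A trial shorter than the window length contributes zero windows and a
    logged warning.  Window labels follow the last-sample rule.
    """
    if window_length < 1 or stride < 1:
        raise ValueError("window_length and stride must be >= 1")
    blocks, labels = [], []
    for tid in np.unique(fm.trial_ids):
        idx = np.flatnonzero(fm.trial_ids == tid)
        vals = fm.values[idx]
        if len(vals) < window_length:
            logger.warning(
                "participant %d trial %d: %d rows < window length %d, skipped",
                fm.participant_id, tid, len(vals), window_length,
            )
            continue
        win = _segment_block(vals, window_length, stride)
        blocks.append(win)
        # label of the last sample of each window
        last = np.arange(window_length - 1, len(vals), stride)[: len(win)]
        labels.append(fm.labels[idx[last]])
    if blocks:
        windows = np.concatenate(blocks)
        labels_arr = np.concatenate(labels)
    else:
        windows = np.empty((0, window_length, fm.values.shape[1]), dtype=np.float32)
        labels_arr = np.empty(0, dtype=object)
    return WindowSet(
        windows=windows,
        labels=labels_arr,
        participant_ids=np.full(len(windows), fm.participant_id, dtype=np.int64),
        window_length=window_length,
        stride=stride,
        feature_names=fm.columns,
    )


def segment_cohort(
    cohort: Sequence[FeatureMatrix], window_length: int, stride: int = 1
) -> WindowSet:
    """Segment every participant and concatenate into one WindowSet."""
    parts = [segment(fm, window_length, stride) for fm in cohort]
    return WindowSet(
        windows=np.concatenate([p.windows for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        participant_ids=np.concatenate([p.participant_ids for p in parts]),
        window_length=window_length,
        stride=stride,
        feature_names=parts[0].feature_names,
    )


def bookkeeping_table(
    trial_rows: Mapping[int, Sequence[int]],
    window_lengths: Sequence[int],
    stride: int = 1,
) -> pd.DataFrame:
    """Per-window-length training/test window counts under leave-one-subject-out.

    ``trial_rows`` maps participant id -> feature-row count per trial.  For
    each window length the table reports the overlap ratio (percent, two
    decimals) and the mean ± SD of training- and test-set window counts over
    the folds (test = the held-out participant's windows).
    """
    pids = sorted(trial_rows)
    rows = []
    for W in window_lengths:
        per_pid = {
            pid: sum(n_windows(n, W, stride) for n in trial_rows[pid]) for pid in pids
        }
        total = sum(per_pid.values())
        test = np.array([per_pid[pid] for pid in pids], dtype=float)
        train = total - test
        rows.append(
            {
                "window_length": W,
                "overlap_pct": overlap_pct(W, stride),
                "train_mean": train.mean(),
                "train_sd": train.std(ddof=1) if len(pids) > 1 else 0.0,
                "test_mean": test.mean(),
                "test_sd": test.std(ddof=1) if len(pids) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk container: .npz archive + JSON sidecar


def save_windows(ws: WindowSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        windows=ws.windows,
        labels=np.asarray(ws.labels, dtype=str),
        participant_ids=ws.participant_ids,
    )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "window_length": ws.window_length,
                "stride": ws.stride,
                "feature_names": list(ws.feature_names),
            },
            indent=2,
        )
    )
    return path


def load_windows(path: str | Path) -> WindowSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path, allow_pickle=False) as arc:
        return WindowSet(
            windows=arc["windows"],
            labels=arc["labels"].astype(object),
            participant_ids=arc["participant_ids"],
            window_length=int(meta["window_length"]),
            stride=int(meta["stride"]),
            feature_names=tuple(meta["feature_names"]),
        )
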