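"""Orientation-invariant heuristic features for triaxial accelerometry.

A pocket-worn phone sits in an arbitrary, participant-specific attitude, so
raw axis values are not comparable across participants.  Nine per-sample
scalars cancel any fixed rotation R of the sensor frame:

====  =========================================================
w1    ||v_n||                 vector norm of the sample
w2    ||Δv_n||                norm of the first time difference
w3    ||Δ²v_n||               norm of the second time difference
w4    ∠(v_n, v_{n+1})         angle between consecutive samples
w5    ∠(Δv_n, Δv_{n+1})
w6    ∠(Δ²v_n, Δ²v_{n+1})
w7    ∠(p_n, p_{n+1}),  p_n = v_n × v_{n+1}
w8    ∠(q_n, q_{n+1}),  q_n = Δv_n × Δv_{n+1}
w9    ∠(r_n, r_{n+1}),  r_n = Δ²v_n × Δ²v_{n+1}
====  =========================================================

Norms and angles are rotation-invariant outright; cross products rotate
covariantly under a proper rotation ((Ra)×(Rb) = R(a×b)), so the angles
between them are invariant too.

w9 reaches four samples ahead, so all columns are truncated to the common
length N−4 and indexed from the first sample of each trial.  Features are
computed per contiguous trial, never across an activity boundary, and are
used raw (unscaled).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .activities import validate_labels
from .preprocess import UniformRecording

__all__ = [
    "FEATURE_NAMES",
    "FeatureMatrix",
    "first_diff",
    "second_diff",
    "angle_between",
    "heuristic_features",
    "extract_features",
    "select_top_features",
    "write_features_csv",
    "read_features_csv",
]

FEATURE_NAMES: tuple[str, ...] = tuple(f"w{i}" for i in range(1, 10))

#: Vectors shorter than this are treated as zero; the angle involving a
#: zero vector is defined as 0 (stationary signals produce constant zero
#: differences, and NaN floods would otherwise dominate static postures).
_ZERO_NORM = 1e-12


@dataclass
class FeatureMatrix:
    """Per-sample heuristic features for one participant, labels aligned."""

    participant_id: int
    values: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray
    columns: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64)
        n, k = self.values.shape
        if len(self.labels) != n or len(self.trial_ids) != n:
            raise ValueError("labels/trial_ids must match value rows")
        if k != len(self.columns):
            raise ValueError("column names must match value columns")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix must not contain missing values")
        validate_labels(np.unique(self.labels))

    def __len__(self) -> int:
        return len(self.values)

    def select(self, indices: Sequence[int]) -> "FeatureMatrix":
        """Column subset, preserving order of *indices*."""
        idx = list(indices)
        return FeatureMatrix(
            self.participant_id,
            self.values[:, idx],
            self.labels,
            self.trial_ids,
            tuple(self.columns[i] for i in idx),
        )


def first_diff(stream: np.ndarray) -> np.ndarray:
    """Δv_n = v_{n+1} − v_n; length N−1."""
    x = np.asarray(stream, dtype=float)
    if len(x) < 2:
        raise ValueError("first difference needs >= 2 samples")
    return np.diff(x, axis=0)


def second_diff(stream: np.ndarray) -> np.ndarray:
    """Δ²v_n = v_{n+2} − 2·v_{n+1} + v_n; length N−2."""
    x = np.asarray(stream, dtype=float)
    if len(x) < 3:
        raise ValueError("second difference needs >= 3 samples")
    return np.diff(x, n=2, axis=0)


def angle_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle in [0, π] between vectors, elementwise over leading axes.

    arccos of the normalised dot product, clamped to [−1, 1]; if either
    vector is (numerically) zero the angle is defined as 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    denom = na * nb
    dot = np.sum(a * b, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(denom > 0, dot / np.where(denom > 0, denom, 1.0), 1.0)
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    zero = (na < _ZERO_NORM) | (nb < _ZERO_NORM)
    return np.where(zero, 0.0, ang)


def heuristic_features(stream: np.ndarray) -> np.ndarray:
    """All nine features for one contiguous stream; shape (N−4, 9)."""
    v = np.asarray(stream, dtype=float)
    n = len(v)
    if n < 5:
        raise ValueError("heuristic features need >= 5 samples per trial")
    d1 = first_diff(v)          # N-1
    d2 = second_diff(v)         # N-2
    p = np.cross(v[:-1], v[1:])     # N-1
    q = np.cross(d1[:-1], d1[1:])   # N-2
    r = np.cross(d2[:-1], d2[1:])   # N-3

    m = n - 4
    cols = [
        np.linalg.norm(v, axis=1)[:m],        # w1
        np.linalg.norm(d1, axis=1)[:m],       # w2
        np.linalg.norm(d2, axis=1)[:m],       # w3
        angle_between(v[:-1], v[1:])[:m],     # w4
        angle_between(d1[:-1], d1[1:])[:m],   # w5
        angle_between(d2[:-1], d2[1:])[:m],   # w6
        angle_between(p[:-1], p[1:])[:m],     # w7
        angle_between(q[:-1], q[1:])[:m],     # w8
        angle_between(r[:-1], r[1:])[:m],     # w9
    ]
    return np.column_stack(cols)


def extract_features(rec: UniformRecording) -> FeatureMatrix:
    """Feature matrix for one participant, computed per contiguous trial.

    Row *i* of a trial's block carries the label of source sample *i* of
    that trial (all identical within a trial by construction).
    """
    vals, labels, tids = [], [], []
    for tid, seg, label in rec.trial_segments():
        w = heuristic_features(seg)
        vals.append(w)
        labels.append(np.full(len(w), label, dtype=object))
        tids.append(np.full(len(w), tid, dtype=np.int64))
    return FeatureMatrix(
        participant_id=rec.participant_id,
        values=np.concatenate(vals),
        labels=np.concatenate(labels),
        trial_ids=np.concatenate(tids),
    )


def select_top_features(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 4,
    random_state: int = 0,
    max_rows: int = 20000,
) -> list[int]:
    """Impurity-ranked top-*k* feature indices.

    Fits a CART decision tree and a random forest under both the Gini and
    the information-gain (entropy) criteria, normalises each ranking's
    importances to sum to 1, and returns the *k* columns with the highest
    mean importance across the four rankings, best first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[1] < k:
        raise ValueError(f"need at least {k} columns, got {X.shape[1]}")
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs >= 2 classes")
    rng = np.random.default_rng(random_state)
    if len(X) > max_rows:
        idx = rng.choice(len(X), size=max_rows, replace=False)
        X, y = X[idx], y[idx]
    rankings = []
    for criterion in ("gini", "entropy"):
        for est in (
            DecisionTreeClassifier(criterion=criterion, random_state=random_state),
            RandomForestClassifier(
                criterion=criterion, n_estimators=50, random_state=random_state,
                n_jobs=1,
            ),
        ):
            est.fit(X, y)
            imp = np.asarray(est.feature_importances_, dtype=float)
            total = imp.sum()
            rankings.append(imp / total if total > 0 else np.full_like(imp, 1 / len(imp)))
    mean_imp = np.mean(rankings, axis=0)
    order = np.argsort(-mean_imp, kind="stable")
    return [int(i) for i in order[:k]]


# ---------------------------------------------------------------------------
# CSV interface: `participant,row_index,trial_id,w1..w9,activity`


def write_features_csv(fm: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(fm.values, columns=list(fm.columns))
    frame.insert(0, "participant", fm.participant_id)
    frame.insert(1, "row_index", np.arange(len(fm)))
    frame.insert(2, "trial_id", fm.trial_ids)
    frame["activity"] = fm.labels
    frame.to_csv(path, index=False, float_format="%.9g")
    return path


def read_features_csv(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    wcols = [c for c in df.columns if c.startswith("w")]
    return FeatureMatrix(
        participant_id=int(df["participant"].iloc[0]),
        values=df[wcols].to_numpy(float),
        labels=df["activity"].to_numpy(object),
        trial_ids=df["trial_id"].to_numpy(np.int64),
        columns=tuple(wcols),
    )
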