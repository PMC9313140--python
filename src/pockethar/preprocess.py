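"""Resampling and imputation: irregular, gappy streams -> uniform 30 Hz.

The recording app throttles between 5 and 19 Hz and drops samples during
connection loss.  Each contiguous activity trial is independently
upsampled to a fixed rate by per-axis linear interpolation through the
observed (non-missing) samples, which simultaneously performs the linear
imputation of interior gaps; leading/trailing gaps take the nearest
observed value.  Resampling never crosses a trial boundary, so no
interpolated sample blends two activities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .activities import validate_labels
from .synthetic import RawRecording

__all__ = [
    "UniformRecording",
    "impute_linear",
    "resample_fixed",
    "write_uniform_csv",
    "read_uniform_csv",
]

DEFAULT_RATE_HZ = 30.0


@dataclass
class UniformRecording:
    """Dense, fully imputed stream at a constant rate.

    ``trial_ids`` index the contiguous activity trials (label runs) the
    samples came from; tick spacing is exactly ``1/rate_hz`` within a trial.
    """

    participant_id: int
    rate_hz: float
    accel: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64)
        n = len(self.accel)
        if self.accel.shape != (n, 3):
            raise ValueError("accel must be (n, 3)")
        if len(self.labels) != n or len(self.trial_ids) != n:
            raise ValueError("labels/trial_ids must match accel length")
        if n < 4:
            raise ValueError("uniform recording needs >= 4 ticks")
        if np.isnan(self.accel).any():
            raise ValueError("uniform recording must not contain missing values")
        validate_labels(np.unique(self.labels))

    def __len__(self) -> int:
        return len(self.accel)

    def trial_segments(self):
        """Yield ``(trial_id, accel_segment, label)`` per contiguous trial."""
        for tid in np.unique(self.trial_ids):
            idx = self.trial_ids == tid
            yield int(tid), self.accel[idx], self.labels[idx][0]


def impute_linear(series: np.ndarray) -> np.ndarray:
    """Fill NaNs by linear interpolation; edges take the nearest observed value.

    Parameters
    ----------
    series : 1-D array with possible NaNs; at least one observed value.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("impute_linear expects a 1-D series")
    obs = ~np.isnan(x)
    if not obs.any():
        raise ValueError("cannot impute an all-missing series")
    if obs.all():
        return x.copy()
    idx = np.arange(len(x))
    # np.interp clamps outside the observed range -> nearest-value edge fill
    return np.interp(idx, idx[obs], x[obs])


def _label_runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of constant-label runs."""
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.concatenate(([0], change, [len(labels)]))
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(len(bounds) - 1)]


def resample_fixed(rec: RawRecording, target_hz: float = DEFAULT_RATE_HZ) -> UniformRecording:
    """Resample one recording to a uniform grid, per contiguous trial.

    Within each trial the grid spans ``[first, last]`` timestamp at spacing
    ``1/target_hz``; each axis is linearly interpolated through its observed
    samples (interior gaps linearly imputed, edge gaps filled with the
    nearest observed value).  Each tick's label is the trial's label, which
    coincides with the nearest-sample rule since labels are constant within
    a trial.
    """
    if target_hz <= 0:
        raise ValueError("target_hz must be > 0")
    accel_parts, label_parts, tid_parts = [], [], []
    for tid, (start, stop) in enumerate(_label_runs(rec.labels)):
        t = rec.timestamps[start:stop].astype(float)
        seg = rec.accel[start:stop]
        step_ms = 1000.0 / target_hz
        # count ticks via multiplication to dodge float-division off-by-one
        n_ticks = int(np.floor((t[-1] - t[0]) * target_hz / 1000.0 + 1e-9)) + 1
        grid = t[0] + np.arange(n_ticks) * step_ms
        cols = []
        for axis in range(3):
            obs = ~np.isnan(seg[:, axis])
            if obs.sum() < 2:
                raise ValueError(
                    f"trial {tid}: need >= 2 observed samples per axis to resample"
                )
            cols.append(np.interp(grid, t[obs], seg[obs, axis]))
        accel_parts.append(np.column_stack(cols))
        label_parts.append(np.full(n_ticks, rec.labels[start], dtype=object))
        tid_parts.append(np.full(n_ticks, tid, dtype=np.int64))
    return UniformRecording(
        participant_id=rec.participant_id,
        rate_hz=float(target_hz),
        accel=np.concatenate(accel_parts),
        labels=np.concatenate(label_parts),
        trial_ids=np.concatenate(tid_parts),
    )


# ---------------------------------------------------------------------------
# CSV interface (same long format, plus a `# rate_hz=` header comment)


def write_uniform_csv(recs: Iterable[UniformRecording], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recs:
        path = out_dir / f"uniform_{rec.participant_id:02d}.csv"
        tick_ms = np.round(np.arange(len(rec)) * 1000.0 / rec.rate_hz).astype(np.int64)
        frame = pd.DataFrame(
            {
                "participant": rec.participant_id,
                "timestamp_ms": tick_ms,
                "ax": rec.accel[:, 0],
                "ay": rec.accel[:, 1],
                "az": rec.accel[:, 2],
                "activity": rec.labels,
                "trial_id": rec.trial_ids,
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# rate_hz={rec.rate_hz:g}\n")
            frame.to_csv(fh, index=False, float_format="%.6f")
        paths.append(path)
    return paths


def read_uniform_csv(path: str | Path) -> UniformRecording:
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("# rate_hz="):
        raise ValueError(f"{path}: missing '# rate_hz=' header")
    rate_hz = float(header.split("=", 1)[1])
    df = pd.read_csv(path, comment="#")
    return UniformRecording(
        participant_id=int(df["participant"].iloc[0]),
        rate_hz=rate_hz,
        accel=df[["ax", "ay", "az"]].to_numpy(float),
        labels=df["activity"].to_numpy(object),
        trial_ids=df["trial_id"].to_numpy(np.int64),
    )
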