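"""Synthetic accelerometer cohorts for pocket-worn smartphone HAR.

Generates labeled triaxial streams with the statistical structure the
downstream analysis assumes:

* a fixed but arbitrary device orientation per participant (the nuisance
  the orientation-invariant features must cancel),
* MET-graded oscillation signatures — amplitude and gait fundamental grow
  monotonically from lying through running at 7 METs,
* irregular sampling (piecewise-constant rate, 5–19 Hz in 10-s blocks),
* short contiguous spans of missing samples (connection dropouts).

Lying is modelled as pure gravity plus sensor noise; sitting carries a
small postural sway on top of a tilted gravity direction.  Under
rotation-invariant features the two postures are therefore separable only
through signal statistics, which makes sitting the hardest class — the
regime the real protocol exhibits.

All quantities are SI: acceleration in m/s^2, gravity-inclusive;
timestamps are integer milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .activities import ACTIVITIES, GRAVITY, validate_labels

__all__ = [
    "Trial",
    "ProtocolSchedule",
    "ParticipantProfile",
    "RawRecording",
    "compute_met",
    "make_protocol",
    "sample_orientation",
    "make_profile",
    "simulate_trial",
    "inject_missing",
    "simulate_participant",
    "simulate_cohort",
    "write_cohort_csv",
    "read_recording_csv",
]

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Trial:
    rank: int
    activity: str
    duration_min: float


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered list of activity trials one participant performs."""

    trials: tuple[Trial, ...]

    def __post_init__(self) -> None:
        ranks = [t.rank for t in self.trials]
        if ranks != list(range(1, len(self.trials) + 1)):
            raise ValueError("trial ranks must be 1..n without gaps")
        validate_labels([t.activity for t in self.trials])

    @property
    def total_minutes(self) -> float:
        return sum(t.duration_min for t in self.trials)

    def scaled(self, factor: float) -> "ProtocolSchedule":
        """Return a copy with every trial duration multiplied by *factor*."""
        if factor <= 0:
            raise ValueError("duration scale factor must be > 0")
        return ProtocolSchedule(
            tuple(replace(t, duration_min=t.duration_min * factor) for t in self.trials)
        )


# Laboratory protocol: order, activity, duration in minutes (65 min total).
_PROTOCOL_ROWS = (
    (1, "lying", 5),
    (2, "sitting", 5),
    (3, "walking", 10),
    (4, "lying", 5),
    (5, "run3MET", 10),
    (6, "lying", 5),
    (7, "run5MET", 10),
    (8, "sitting", 5),
    (9, "run7MET", 10),
)


def make_protocol() -> ProtocolSchedule:
    """The fixed 9-trial, 65-minute laboratory schedule."""
    return ProtocolSchedule(tuple(Trial(r, a, d) for r, a, d in _PROTOCOL_ROWS))


@dataclass(frozen=True)
class ParticipantProfile:
    """Per-participant generative parameters.

    ``orientation`` is the fixed device-in-pocket attitude: a proper
    rotation applied to every body-frame sample.  ``gait_frequency_hz`` is
    the walking fundamental; running fundamentals scale from it.
    """

    participant_id: int
    orientation: np.ndarray
    gait_frequency_hz: float = 1.8
    amplitude_scale: float = 1.0
    noise_sd: float = 0.1
    mean_rate_hz: float = 12.0

    def __post_init__(self) -> None:
        R = np.asarray(self.orientation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("orientation must be a 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
            raise ValueError("orientation must be orthogonal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-10):
            raise ValueError("orientation must be a proper rotation (det=+1)")
        if self.gait_frequency_hz <= 0 or self.amplitude_scale <= 0:
            raise ValueError("gait_frequency_hz and amplitude_scale must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 5.0 <= self.mean_rate_hz <= 19.0:
            raise ValueError("mean_rate_hz must lie in [5, 19]")
        object.__setattr__(self, "orientation", R)


@dataclass
class RawRecording:
    """One participant's irregular, possibly gappy, labeled stream.

    ``accel`` rows may be NaN (missing sample); ``timestamps`` are strictly
    increasing integer milliseconds.
    """

    participant_id: int
    timestamps: np.ndarray
    accel: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.accel = np.asarray(self.accel, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n = len(self.timestamps)
        if self.accel.shape != (n, 3) or len(self.labels) != n:
            raise ValueError("timestamps, accel and labels must have equal length")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        validate_labels(np.unique(self.labels))

    def __len__(self) -> int:
        return len(self.timestamps)


# ---------------------------------------------------------------------------
# operations


def compute_met(oxygen_rate: float, weight: float) -> float:
    """Metabolic equivalent of task.

    Parameters
    ----------
    oxygen_rate : float
        Oxygen consumption rate in mL/minute.
    weight : float
        Body weight in kg.

    Returns
    -------
    float
        Oxygen consumption normalised by the resting rate 3.5 mL/kg/min,
        so 1 MET corresponds to rest.
    """
    if weight <= 0:
        raise ValueError("weight must be > 0 kg")
    if oxygen_rate < 0:
        raise ValueError("oxygen_rate must be >= 0")
    return oxygen_rate / (3.5 * weight)


def sample_orientation(seed: int) -> np.ndarray:
    """Draw a uniformly distributed proper rotation (3x3), deterministic in *seed*."""
    rot = Rotation.random(rng=np.random.default_rng(seed))
    return rot.as_matrix()


# Body-frame signature per activity: oscillation amplitude (m/s^2, before the
# participant's amplitude_scale), fundamental frequency relative to a 1.8 Hz
# walking gait, and the unit gravity direction in the body frame.
_TILT = math.radians(35.0)
_SIGNATURES: dict[str, dict] = {
    "lying":   {"amp": 0.0,  "rel_freq": 0.0,          "g_dir": (0.0, 0.0, 1.0)},
    "sitting": {"amp": 0.15, "rel_freq": 0.5 / 1.8,
                "g_dir": (math.sin(_TILT), 0.0, math.cos(_TILT))},
    "walking": {"amp": 1.2,  "rel_freq": 1.0,          "g_dir": (0.0, 0.0, 1.0)},
    "run3MET": {"amp": 2.0,  "rel_freq": 2.2 / 1.8,    "g_dir": (0.0, 0.0, 1.0)},
    "run5MET": {"amp": 3.0,  "rel_freq": 2.6 / 1.8,    "g_dir": (0.0, 0.0, 1.0)},
    "run7MET": {"amp": 4.0,  "rel_freq": 3.0 / 1.8,    "g_dir": (0.0, 0.0, 1.0)},
}

_RATE_LOW, _RATE_HIGH = 5.0, 19.0
_BLOCK_SECONDS = 10.0


def _irregular_times(duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Sample times (seconds) with piecewise-constant rate per 10-s block."""
    n_blocks = max(1, math.ceil(duration_s / _BLOCK_SECONDS))
    rates = rng.uniform(_RATE_LOW, _RATE_HIGH, size=n_blocks)
    times = []
    t = 0.0
    while t < duration_s:
        block = min(int(t // _BLOCK_SECONDS), n_blocks - 1)
        times.append(t)
        t += 1.0 / rates[block]
    return np.asarray(times)


def simulate_trial(
    activity: str,
    duration_min: float,
    profile: ParticipantProfile,
    seed: int,
) -> RawRecording:
    """Simulate one activity trial for one participant.

    The body-frame signal is gravity along a posture-specific direction
    plus a two-harmonic oscillation whose amplitude and fundamental grow
    with activity intensity, plus white sensor noise; the device-frame
    output is the profile's fixed rotation applied to it.
    """
    if activity not in _SIGNATURES:
        raise ValueError(f"unknown activity {activity!r}")
    if duration_min <= 0:
        raise ValueError("duration must be > 0 minutes")
    sig = _SIGNATURES[activity]
    rng = np.random.default_rng(seed)

    t = _irregular_times(duration_min * 60.0, rng)
    n = len(t)
    phase1, phase2 = rng.uniform(0.0, 2.0 * math.pi, size=2)

    body = np.tile(GRAVITY * np.asarray(sig["g_dir"]), (n, 1))
    amp = sig["amp"] * profile.amplitude_scale
    if amp > 0.0:
        f = sig["rel_freq"] * profile.gait_frequency_hz
        vertical = amp * (
            np.sin(2.0 * math.pi * f * t + phase1)
            + 0.4 * np.sin(4.0 * math.pi * f * t + phase2)
        )
        lateral = 0.3 * amp * np.sin(2.0 * math.pi * f * t + phase2)
        body[:, 2] += vertical
        body[:, 0] += lateral
    if profile.noise_sd > 0.0:
        body += rng.normal(0.0, profile.noise_sd, size=(n, 3))

    device = body @ profile.orientation.T
    timestamps = np.round(t * 1000.0).astype(np.int64)
    # rounding can push the final sample onto the next trial's start tick
    keep = timestamps < int(round(duration_min * 60_000))
    timestamps, device = timestamps[keep], device[keep]
    n = len(timestamps)
    return RawRecording(
        participant_id=profile.participant_id,
        timestamps=timestamps,
        accel=device,
        labels=np.full(n, activity, dtype=object),
    )


def inject_missing(rec: RawRecording, fraction: float, seed: int) -> RawRecording:
    """Mark ~``fraction`` of samples missing (NaN) in short contiguous spans.

    Labels and timestamps are untouched; only accelerometer rows go missing,
    mimicking momentary connection loss between app and server.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    if fraction == 0.0 or len(rec) == 0:
        return rec
    rng = np.random.default_rng(seed)
    n = len(rec)
    target = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    while mask.sum() < target:
        start = int(rng.integers(0, n))
        span = int(rng.geometric(0.25))  # mean span of 4 samples
        mask[start : start + span] = True
    accel = rec.accel.copy()
    accel[mask] = np.nan
    return RawRecording(rec.participant_id, rec.timestamps, accel, rec.labels)


def make_profile(
    participant_id: int,
    seed: int,
    noise_sd: float = 0.1,
    orientation: np.ndarray | None = None,
) -> ParticipantProfile:
    """Draw a participant's generative parameters deterministically from *seed*."""
    rng = np.random.default_rng(seed)
    orient_seed = int(rng.integers(0, 2**31 - 1))
    gait = float(rng.uniform(1.7, 1.9))
    amp_scale = float(rng.uniform(0.9, 1.1))
    if orientation is None:
        orientation = sample_orientation(orient_seed)
    return ParticipantProfile(
        participant_id=participant_id,
        orientation=orientation,
        gait_frequency_hz=gait,
        amplitude_scale=amp_scale,
        noise_sd=noise_sd,
    )


def simulate_participant(
    profile: ParticipantProfile,
    seed: int,
    protocol: ProtocolSchedule | None = None,
    missing_fraction: float = 0.0,
) -> RawRecording:
    """Run one participant through the protocol and concatenate the trials.

    Trial *k* is offset on the timeline by the cumulative nominal duration of
    trials before it, so timestamps stay strictly increasing.  The signal
    randomness is governed by *seed* alone; the orientation enters only as a
    linear map, so re-simulating with a different ``profile.orientation`` but
    the same seed yields an exactly rotated copy of the same stream.
    """
    protocol = protocol or make_protocol()
    trial_ss = np.random.SeedSequence(seed).spawn(len(protocol.trials) + 1)
    parts, offset_ms = [], 0
    for trial, ss in zip(protocol.trials, trial_ss[:-1]):
        rec = simulate_trial(
            trial.activity, trial.duration_min, profile,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        parts.append((rec, offset_ms))
        offset_ms += int(round(trial.duration_min * 60_000))
    timestamps = np.concatenate([r.timestamps + off for r, off in parts])
    accel = np.concatenate([r.accel for r, _ in parts])
    labels = np.concatenate([r.labels for r, _ in parts])
    rec = RawRecording(profile.participant_id, timestamps, accel, labels)
    if missing_fraction > 0.0:
        miss_seed = int(trial_ss[-1].generate_state(1)[0] % (2**31))
        rec = inject_missing(rec, missing_fraction, miss_seed)
    return rec


def simulate_cohort(
    n_participants: int = 42,
    seed: int = 0,
    protocol: ProtocolSchedule | None = None,
    duration_scale: float = 1.0,
    missing_fraction: float = 0.05,
    noise_sd: float = 0.1,
) -> list[RawRecording]:
    """Simulate a cohort, one protocol run per participant.

    Each participant receives an independent orientation, gait frequency,
    amplitude scale and sampling-rate realization.  Fully deterministic
    under *seed*.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants (leave-one-subject-out)")
    protocol = protocol or make_protocol()
    if duration_scale != 1.0:
        protocol = protocol.scaled(duration_scale)
    children = np.random.SeedSequence(seed).spawn(n_participants)
    cohort = []
    for pid, ss in enumerate(children, start=1):
        prof_seed, sig_seed = (int(s % (2**31)) for s in ss.generate_state(2))
        profile = make_profile(pid, prof_seed, noise_sd=noise_sd)
        cohort.append(
            simulate_participant(
                profile, sig_seed, protocol=protocol,
                missing_fraction=missing_fraction,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# CSV interface: long format `participant,timestamp_ms,ax,ay,az,activity`;
# missing accelerometer entries are empty fields.


def _recording_frame(rec: RawRecording) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": rec.participant_id,
            "timestamp_ms": rec.timestamps,
            "ax": rec.accel[:, 0],
            "ay": rec.accel[:, 1],
            "az": rec.accel[:, 2],
            "activity": rec.labels,
        }
    )


def write_cohort_csv(
    cohort: Iterable[RawRecording],
    out_dir: str | Path,
    per_participant: bool = True,
) -> list[Path]:
    """Write a cohort to CSV; one file per participant or a single file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = [_recording_frame(r) for r in cohort]
    paths = []
    if per_participant:
        for rec, frame in zip(cohort, frames):
            path = out_dir / f"participant_{rec.participant_id:02d}.csv"
            frame.to_csv(path, index=False, na_rep="", float_format="%.6f")
            paths.append(path)
    else:
        path = out_dir / "cohort.csv"
        pd.concat(frames, ignore_index=True).to_csv(
            path, index=False, na_rep="", float_format="%.6f"
        )
        paths.append(path)
    return paths


def read_recording_csv(path: str | Path) -> list[RawRecording]:
    """Read one long-format CSV back into per-participant recordings."""
    df = pd.read_csv(path, comment="#")
    recs = []
    for pid, grp in df.groupby("participant", sort=True):
        recs.append(
            RawRecording(
                participant_id=int(pid),
                timestamps=grp["timestamp_ms"].to_numpy(np.int64),
                accel=grp[["ax", "ay", "az"]].to_numpy(float),
                labels=grp["activity"].to_numpy(object),
            )
        )
    return recs
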