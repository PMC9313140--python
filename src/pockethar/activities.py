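"""Activity vocabulary shared across the pipeline.

Six activity classes: two static postures and four treadmill activities,
the running intensities graded by metabolic equivalent of task (MET).
"""

from __future__ import annotations

#: Canonical class order used everywhere (confusion matrices, one-hot
#: encodings, reports).  Static postures first, then increasing intensity.
ACTIVITIES: tuple[str, ...] = (
    "lying",
    "sitting",
    "walking",
    "run3MET",
    "run5MET",
    "run7MET",
)

N_CLASSES = len(ACTIVITIES)

#: Standard gravity, m/s^2.  Accelerometer streams are gravity-inclusive.
GRAVITY = 9.81


def validate_labels(labels) -> None:
    """Raise ``ValueError`` if any label falls outside the 6-class set."""
    bad = set(labels) - set(ACTIVITIES)
    if bad:
        raise ValueError(f"unknown activity labels: {sorted(bad)!r}")
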