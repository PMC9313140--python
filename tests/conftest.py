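"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import pockethar as ph


@pytest.fixture(scope="session")
def micro_cohort():
    """3 participants, heavily shortened protocol — fast unit-test fodder."""
    return ph.simulate_cohort(3, seed=7, duration_scale=0.01, missing_fraction=0.05)


@pytest.fixture(scope="session")
def micro_features(micro_cohort):
    return [ph.extract_features(ph.resample_fixed(r)) for r in micro_cohort]


@pytest.fixture(scope="session")
def desk_cohort_features():
    """The desk-scale study conditions: 8 participants, 78-s protocol.

    Features are extracted once per session and shared by the evaluation
    and acceptance tests.
    """
    cohort = ph.simulate_cohort(8, seed=1, duration_scale=0.02)
    feats = [ph.extract_features(ph.resample_fixed(r)) for r in cohort]
    X = np.concatenate([f.values for f in feats])
    y = np.concatenate([f.labels for f in feats])
    selected = ph.select_top_features(X, y, k=4, random_state=1)
    return [f.select(selected) for f in feats]
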