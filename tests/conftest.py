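from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from keydyn import KeystrokeEvent, TypingSession, generate_cohort


def make_session(presses_ms, releases_ms, pressures=None, subject_id="S1", session_index=1):
    """Handcraft a session from millisecond timestamp lists."""
    if pressures is None:
        pressures = [0.5] * len(presses_ms)
    events = [
        KeystrokeEvent(int(p), int(r), float(q))
        for p, r, q in zip(presses_ms, releases_ms, pressures)
    ]
    return TypingSession(subject_id, session_index, events)


@pytest.fixture
def session3():
    return make_session([0, 200, 500], [100, 350, 650], [0.4, 0.6, 0.5])


@pytest.fixture(scope="session")
def toy_cohort():
    """Small seeded synthetic cohort reused across pipeline tests."""
    return generate_cohort(n_pd=8, n_control=7, sessions_per_subject=8, seed=2024)


@pytest.fixture(scope="session")
def toy_features(toy_cohort):
    from keydyn import extract_feature_table

    return extract_feature_table(toy_cohort.subjects)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
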