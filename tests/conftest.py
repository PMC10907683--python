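import numpy as np
import pandas as pd
import pytest

from phenofuse.simulate import SyntheticTruth, simulate_study


@pytest.fixture(scope="session")
def small_truth():
    return SyntheticTruth(seed=7, n_participants=8, n_weeks=3)


@pytest.fixture(scope="session")
def small_bundle(small_truth):
    """One small synthetic study shared across tests (8 participants,
    3 weeks); regenerating it per test would dominate suite runtime."""
    return simulate_study(small_truth)


@pytest.fixture(scope="session")
def medium_truth():
    return SyntheticTruth(seed=21, n_participants=40, n_weeks=5)


@pytest.fixture(scope="session")
def medium_bundle(medium_truth):
    """A synthetic study large enough for stable ICA estimates (~1350 days
    of panel data)."""
    return simulate_study(medium_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_events(times, classes=None, pid="P0", dates=None, dismissed=None):
    """Build a KeypressEvent list from plain sequences."""
    from phenofuse.keyboard import KeypressEvent

    n = len(times)
    classes = classes or ["alphanumeric"] * n
    dates = dates or [pd.Timestamp("2023-01-02").date()] * n
    dismissed = dismissed or [False] * n
    return [
        KeypressEvent(
            participant_id=pid,
            timestamp=float(t),
            key_class=c,
            date=d,
            keyboard_dismissed=k,
        )
        for t, c, d, k in zip(times, classes, dates, dismissed)
    ]
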