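import numpy as np
import pytest

import corank as cr


@pytest.fixture
def two_subject_cohort():
    """Minimal cohort: two subjects, both events, distinct times."""
    return cr.SurvivalCohort(np.array([1.0, 2.0]), np.array([1, 1]))


@pytest.fixture
def small_cohort():
    """12 subjects, mixed events, distinct times (seeded)."""
    rng = np.random.default_rng(7)
    t = rng.random(12)
    e = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 0])
    return cr.SurvivalCohort.from_unsorted(t, e)


@pytest.fixture
def mixed_tie_cohort():
    """One mixed tie block (event + censored at t=2) plus distinct times."""
    times = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
    events = np.array([1, 1, 0, 0, 1])
    return cr.SurvivalCohort(times, events)


def random_cohort(rng, n, event_rate=0.6, ensure_events=True):
    t = rng.random(n)
    e = (rng.random(n) < event_rate).astype(int)
    if ensure_events and e.sum() == 0:
        e[rng.integers(n)] = 1
    return cr.SurvivalCohort.from_unsorted(t, e)


def random_group(rng, n, n1):
    x = np.zeros(n, dtype=np.int8)
    x[rng.choice(n, n1, replace=False)] = 1
    return cr.GroupAssignment(x)
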