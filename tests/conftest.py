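from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from actichild import EventLog, Event, Recording
from actichild.synthetic import SimConfig, cohort_tables, make_cohort

T0 = pd.Timestamp("2021-05-01 10:00:00")


def make_recording(duration_s=10.0, rate=100.0, subject="kid1", placement="hip",
                   seed=0, start=T0):
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    samples = rng.normal(0, 0.1, size=(n, 3))
    samples[:, 2] += 1.0
    return Recording(subject_id=subject, placement=placement, sample_rate_hz=rate,
                     start_time=start, samples=samples)


def make_log(segments, subject="kid1", start=T0):
    """segments: list of (duration_s, code) laid end to end from `start`."""
    events, t = [], start
    for dur, code in segments:
        end = t + pd.Timedelta(seconds=dur)
        events.append(Event(t, end, code))
        t = end
    return EventLog(subject_id=subject, events=events)


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 subjects x 2 min: enough structure for fast pipeline tests."""
    cfg = SimConfig(n_subjects=4, session_s=120.0, seed=11)
    recs, logs = cohort_tables(make_cohort(cfg))
    return cfg, recs, logs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
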