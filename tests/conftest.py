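import numpy as np
import pandas as pd
import pytest

from hypoval import TraceRecord


def make_record(pressures, index=None, times=None, patient_id="T001", interval=20.0):
    """Build a small in-memory trace from plain lists."""
    n = len(pressures)
    if times is None:
        times = np.arange(n) * interval
    if index is None:
        index = np.full(n, np.nan)
    df = pd.DataFrame({"time_s": np.asarray(times, float),
                       "map_mmhg": np.asarray(pressures, float),
                       "index": np.asarray(index, float)})
    return TraceRecord(patient_id=patient_id, samples=df, sample_interval=interval)


@pytest.fixture
def record_factory():
    return make_record


def random_trace(rng, n_samples, gap_prob=0.0, nan_index_prob=0.0):
    """Random piecewise-blocky pressure/index series that exercises runs,
    recoveries, rescues-like jumps and optional recording gaps."""
    times, t = [], 0.0
    for _ in range(n_samples):
        times.append(t)
        t += 20.0 if rng.random() > gap_prob else 20.0 + rng.choice([80.0, 200.0])
    pressure = np.empty(n_samples)
    level = rng.uniform(55, 90)
    i = 0
    while i < n_samples:
        block = rng.integers(1, 8)
        for _ in range(block):
            if i >= n_samples:
                break
            pressure[i] = np.clip(level + rng.normal(0, 2.0), 40, 110)
            i += 1
        level = np.clip(level + rng.normal(0, 8.0), 45, 100)
    index = np.empty(n_samples)
    i = 0
    level = rng.uniform(0, 100)
    while i < n_samples:
        block = rng.integers(1, 8)
        for _ in range(block):
            if i >= n_samples:
                break
            index[i] = np.nan if rng.random() < nan_index_prob \
                else np.clip(level + rng.normal(0, 5.0), 0, 100)
            i += 1
        level = rng.uniform(0, 100)
    return np.asarray(times), np.round(pressure, 1), np.round(index, 2)
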