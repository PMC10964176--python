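"""Shared fixtures: random event traces and a per-second brute-force oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from briskwalk.accelerometry import ActivityEventSeries

BASE = pd.Timestamp("2023-03-06")


def random_trace(
    rng: np.random.Generator,
    total_seconds: int = 6 * 3600,
    start_offset_s: int | None = None,
) -> ActivityEventSeries:
    """A random labelled daytime trace with integer-second event boundaries.

    Events alternate freely between classes; stepping events get random
    integer step counts, so bout cadences take arbitrary values and bouts
    land at arbitrary offsets relative to epoch boundaries.
    """
    if start_offset_s is None:
        start_offset_s = int(rng.integers(0, 3600))
    t = start_offset_s
    rows = []
    while t < start_offset_s + total_seconds:
        cls = rng.choice(["sedentary", "standing", "stepping"], p=[0.4, 0.2, 0.4])
        dur = int(rng.integers(20, 900))
        dur = min(dur, start_offset_s + total_seconds - t)
        steps = int(rng.integers(1, int(2.5 * dur))) if cls == "stepping" else 0
        rows.append(
            {
                "start": BASE + pd.Timedelta(seconds=t),
                "duration_s": float(dur),
                "activity_class": cls,
                "steps": float(steps),
                "awake": True,
            }
        )
        t += dur
    return ActivityEventSeries("R0001", pd.DataFrame(rows))


def per_second_epoch_steps(series: ActivityEventSeries, epoch_length: int = 60):
    """Brute-force oracle: expand stepping bouts to per-second step rates and
    re-accumulate into epochs aligned to midnight.

    Returns (epoch_index_from_midnight, steps) aligned arrays covering the
    span of the series.
    """
    ev = series.events
    starts = series.start_s.astype(int)
    ends = starts + ev["duration_s"].to_numpy().astype(int)
    lo = (starts.min() // epoch_length) * epoch_length
    hi = int(np.ceil(ends.max() / epoch_length)) * epoch_length
    per_second = np.zeros(hi - lo)
    for s, e, st in zip(starts, ends, ev["steps"].to_numpy()):
        if st:
            per_second[s - lo : e - lo] += st / (e - s)
    n_epochs = (hi - lo) // epoch_length
    epoch_steps = per_second.reshape(n_epochs, epoch_length).sum(axis=1)
    return np.arange(lo // epoch_length, hi // epoch_length), epoch_steps


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230306)
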