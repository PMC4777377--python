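"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest

from actipipe import CountSeries, SimulationConfig, simulate_recording

START = datetime(2014, 1, 6, 0, 0, 0)


def make_series(axis1, epoch_length=60, axis2=None, axis3=None, start=START, subject_id=""):
    """CountSeries from a vertical-axis list; lateral axes default to zero."""
    a1 = np.asarray(axis1, dtype=np.int64)
    a2 = np.zeros_like(a1) if axis2 is None else np.asarray(axis2, dtype=np.int64)
    a3 = np.zeros_like(a1) if axis3 is None else np.asarray(axis3, dtype=np.int64)
    return CountSeries(
        start_time=start,
        epoch_length=epoch_length,
        axis1=a1,
        axis2=a2,
        axis3=a3,
        subject_id=subject_id,
    )


@pytest.fixture(scope="session")
def default_recording():
    """One 7-day subject at the generator's default settings."""
    config = SimulationConfig(n_subjects=1, n_days=7, seed=424242)
    return simulate_recording(config, 0)
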