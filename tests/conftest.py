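import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from taskfmri_qc.types import EventsTable, MotionRecord

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_events(onsets, responses=None, trial_types=None, durations=None,
                rts=None, corrects=None, run_id="sub-001"):
    """Build an EventsTable from short per-trial lists (None = missing)."""
    n = len(onsets)
    responses = responses if responses is not None else ["LEFT"] * n
    rts_given = rts is not None
    rts = list(rts) if rts_given else [0.8] * n
    corrects = list(corrects) if corrects is not None else [True] * n
    for i, r in enumerate(responses):
        if r is None:
            rts[i] = np.nan
            corrects[i] = None
    return EventsTable(run_id=run_id, trials=pd.DataFrame({
        "onset": onsets,
        "duration": durations if durations is not None else [2.0] * n,
        "trial_type": trial_types if trial_types is not None
        else ["CONTROL", "TASK"] * (n // 2) + ["CONTROL"] * (n % 2),
        "response": responses,
        "response_time": rts,
        "correct": corrects,
    }))


def make_motion(n_frames, run_id="sub-001"):
    return MotionRecord(run_id=run_id, trans=np.zeros((n_frames, 3)),
                        rot=np.zeros((n_frames, 3)))


@pytest.fixture
def events_factory():
    return make_events


@pytest.fixture
def motion_factory():
    return make_motion
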