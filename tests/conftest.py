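import numpy as np
import pytest

from twostep.task import SessionData, TaskConfig, TrialRecord


def make_trial(i, a1, s2, a2, level, juice, session_id="s0", forced_stage=0,
               error_code=None, rt1=None, side1=0, fix_rt=None):
    transition = None
    if error_code is None:
        transition = "common" if s2 == a1 else "rare"
    return TrialRecord(
        session_id=session_id, trial_index=i, forced_stage=forced_stage,
        error_code=error_code, a1=a1, s2=s2, transition=transition, a2=a2,
        outcome_level=level, juice_ms=juice, rt1=rt1, side1=side1,
        fix_rt=fix_rt,
    )


def make_session(rows, session_id="s0", subject_id="test"):
    """rows: iterable of (a1, s2, a2, level, juice[, kwargs])."""
    trials = []
    for i, row in enumerate(rows):
        kwargs = {}
        if len(row) == 6:
            *row, kwargs = row
        a1, s2, a2, level, juice = row
        trials.append(make_trial(i, a1, s2, a2, level, juice,
                                 session_id=session_id, **kwargs))
    return SessionData(trials=trials, session_id=session_id,
                       subject_id=subject_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return TaskConfig()


@pytest.fixture
def scripted_session():
    # 5 free trials with a mix of transitions and outcome levels
    return make_session([
        (0, 0, 0, 3, 900.0),
        (0, 1, 1, 1, 0.0),
        (1, 1, 0, 2, 300.0),
        (1, 0, 1, 3, 800.0),
        (0, 0, 0, 2, 250.0),
    ])
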