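import numpy as np
import pandas as pd
import pytest

from cessnet import synth


def make_events(rows):
    """Build a small event log from (user, minutes, action, channel, content,
    thread, author) tuples; timestamps are minutes after the epoch."""
    df = pd.DataFrame(rows, columns=["user_id", "minute", "action", "channel",
                                     "content_id", "thread_id", "author_id"])
    df["timestamp"] = synth.EPOCH + pd.to_timedelta(df.pop("minute"), unit="min")
    df = df[synth.EVENT_COLUMNS]
    df["seq"] = np.arange(len(df), dtype="int64")
    return df


def make_roster(user_ids, reg_minutes=None, trial=True):
    n = len(user_ids)
    reg = reg_minutes if reg_minutes is not None else [0] * n
    return pd.DataFrame({
        "user_id": list(user_ids),
        "registration_time": synth.EPOCH + pd.to_timedelta(reg, unit="min"),
        "is_trial_participant": [trial] * n,
        "is_excluded": [False] * n,
    })


@pytest.fixture(scope="session")
def small_config():
    return synth.GeneratorConfig(n_participants=150, n_background_members=100,
                                 seed=20)


@pytest.fixture(scope="session")
def small_run(small_config):
    events, roster, truth = synth.generate(small_config)
    return events, roster, truth
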