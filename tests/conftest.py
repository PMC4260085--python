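import datetime as dt

import pytest
from hypothesis import settings

import engagement_logviz as elv

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def example_stream():
    return elv.read_log(elv.example_log_path())


@pytest.fixture(scope="session")
def example_key():
    return elv.parse_key_file(elv.example_key_path())


@pytest.fixture(scope="session")
def example_cohort(example_stream, example_key):
    labeled, _ = elv.label_stream(example_stream, example_key)
    return elv.sessionize(labeled)


def make_events(user_id, minute_offsets, event_ids=None, start=None):
    """Raw events for one user at the given minute offsets from start."""
    start = start or dt.datetime(2012, 3, 1, 9, 0)
    event_ids = event_ids or [""] * len(minute_offsets)
    return [
        elv.RawEvent(user_id, start + dt.timedelta(minutes=m), eid)
        for m, eid in zip(minute_offsets, event_ids)
    ]


def label_with(key, events):
    stream = elv.EventStream.from_events(events)
    labeled, _ = elv.label_stream(stream, key)
    return labeled
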