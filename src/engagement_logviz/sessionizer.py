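"""Inactivity-gap sessionization and usage-day extraction.

A *session* is a maximal run of one user's events in which no gap between
consecutive events exceeds the inactivity threshold (default 60 minutes —
generous enough to allow for re-watching videos or composing long text
entries).  A gap strictly greater than the threshold starts a new session;
a gap exactly equal to it does not.  Sessions are the navigation unit of
all downstream views; they may span midnight.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .event_model import LabeledEvent, RawEvent

__all__ = ["SessionConfig", "Session", "segment", "usage_days", "sessionize"]


@dataclass(frozen=True)
class SessionConfig:
    """Sessionization parameters; threshold must be positive."""

    threshold: dt.timedelta = dt.timedelta(minutes=60)

    def __post_init__(self) -> None:
        if self.threshold <= dt.timedelta(0):
            raise ValueError("session threshold must be positive")

    @classmethod
    def from_minutes(cls, minutes: float) -> "SessionConfig":
        return cls(threshold=dt.timedelta(minutes=minutes))


@dataclass
class Session:
    """One user's maximal run of events without an over-threshold gap."""

    user_id: str
    session_index: int  # 1-based, in time order per user
    events: list = field(default_factory=list)

    @property
    def start_time(self) -> dt.datetime:
        return self.events[0].timestamp

    @property
    def end_time(self) -> dt.datetime:
        return self.events[-1].timestamp


def _check_sorted(events: Sequence) -> None:
    for prev, cur in zip(events, events[1:]):
        if cur.timestamp < prev.timestamp:
            raise ValueError(
                "events must be time-sorted before sessionization "
                f"({prev.timestamp} followed by {cur.timestamp})"
            )


def segment(
    events: Sequence[RawEvent | LabeledEvent],
    config: SessionConfig | None = None,
) -> list[Session]:
    """Partition one user's time-sorted events into sessions.

    Splits exactly where the gap to the previous event is strictly greater
    than the threshold.  Labeled events have their ``session_index`` set in
    place.  Unsorted input raises; empty input yields no sessions.
    """
    config = config or SessionConfig()
    if not events:
        return []
    _check_sorted(events)
    user_id = events[0].user_id
    sessions: list[Session] = [Session(user_id=user_id, session_index=1)]
    sessions[0].events.append(events[0])
    for prev, cur in zip(events, events[1:]):
        if cur.user_id != user_id:
            raise ValueError("segment() expects events of a single user")
        if cur.timestamp - prev.timestamp > config.threshold:
            sessions.append(Session(user_id=user_id, session_index=len(sessions) + 1))
        sessions[-1].events.append(cur)
    for session in sessions:
        for ev in session.events:
            if isinstance(ev, LabeledEvent):
                ev.session_index = session.session_index
    return sessions


def usage_days(
    events: Sequence[RawEvent | LabeledEvent],
    *,
    anchor: dt.date | None = None,
) -> list[int]:
    """Sorted day offsets on which a user generated any event.

    Offsets are calendar-day differences from the user's first event date
    (or from ``anchor`` — e.g. an enrollment date — when given).  Day 0 is
    always present for non-empty input unless an earlier anchor shifts it.
    """
    if not events:
        return []
    _check_sorted(events)
    base = anchor or events[0].timestamp.date()
    offsets = {(ev.timestamp.date() - base).days for ev in events}
    return sorted(offsets)


def sessionize(
    labeled_by_user: Mapping[str, Sequence[LabeledEvent]],
    config: SessionConfig | None = None,
) -> dict[str, list[Session]]:
    """Sessionize every user of a labeled stream (cohort form used by views)."""
    return {
        user_id: segment(list(events), config)
        for user_id, events in labeled_by_user.items()
    }
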