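"""Domain types and file I/O for intervention event logs.

A log of a web-based intervention is a table with one row per user action:
a user identifier, a timestamp, and an event identifier (typically a URL
path, possibly empty for the landing page).  This module defines the typed
in-memory representation of such logs — raw events, content labels of the
form ``module.subsection.page``, feature categories, and labeled events —
together with the readers and writers for raw logs and for the delimited
"view table" spreadsheets that back each visualization.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureCategory",
    "APP_CATEGORIES",
    "CATEGORY_ALIASES",
    "ContentLabel",
    "SequenceAssignment",
    "RawEvent",
    "LabeledEvent",
    "EventStream",
    "RowError",
    "LogFormatError",
    "read_log",
    "write_view_table",
    "read_view_table",
]


class LogFormatError(ValueError):
    """Fatal problem with the structure of a log or key file."""


class FeatureCategory(enum.Enum):
    """Closed set of feature (non-content) event categories.

    The first five are the app lanes of the navigation graph and the extra
    rows/columns of the next-action matrix; ``HOME`` is the landing page
    and is displayed in no lane.
    """

    EXERCISE = "Exercise"
    MINDFULNESS = "Mindfulness"
    JOURNAL = "Journal"
    REVIEW = "Review"
    OTHER = "Other"
    HOME = "Home"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


#: Fixed display order of the five app lanes (Home excluded).
APP_CATEGORIES: tuple[FeatureCategory, ...] = (
    FeatureCategory.EXERCISE,
    FeatureCategory.MINDFULNESS,
    FeatureCategory.JOURNAL,
    FeatureCategory.REVIEW,
    FeatureCategory.OTHER,
)

#: Key-file aliases normalized at parse time: a supporter review is the
#: "Review" category; generic "Feature" rows are the catch-all "Other".
CATEGORY_ALIASES: Mapping[str, FeatureCategory] = {
    "Supporter": FeatureCategory.REVIEW,
    "Feature": FeatureCategory.OTHER,
}


@dataclass(frozen=True)
class ContentLabel:
    """Position of a content page in the authored hierarchy.

    Rendered as a dotted string ``module[.subsection[.page]]`` — e.g. ``"2"``,
    ``"1.0.1"``, ``"2.1.0"``.  Module 0 is legal (interventions commonly have
    an introduction module 0).  A bare module label sorts before any of its
    subsection pages.
    """

    module: int
    subsection: int | None = None
    page: int | None = None

    def __post_init__(self) -> None:
        if self.module < 0:
            raise ValueError(f"module must be non-negative, got {self.module}")
        if self.subsection is None and self.page is not None:
            raise ValueError("page requires a subsection")
        for part in (self.subsection, self.page):
            if part is not None and part < 0:
                raise ValueError(f"label parts must be non-negative: {self}")

    @classmethod
    def parse(cls, text: str) -> "ContentLabel":
        """Parse a dotted numeric string; raises ``ValueError`` otherwise."""
        parts = text.strip().split(".")
        if not 1 <= len(parts) <= 3 or not all(p.isdigit() for p in parts):
            raise ValueError(f"not a content label: {text!r}")
        nums = [int(p) for p in parts]
        return cls(*nums)

    @property
    def sort_key(self) -> tuple[int, int, int]:
        # absent parts sort before 0: a bare module precedes its pages
        return (
            self.module,
            -1 if self.subsection is None else self.subsection,
            -1 if self.page is None else self.page,
        )

    def truncated(self) -> str:
        """Coarser ``module.subsection`` display form (``"2.1"``; ``"2"`` if flat)."""
        if self.subsection is None:
            return str(self.module)
        return f"{self.module}.{self.subsection}"

    def __str__(self) -> str:
        parts = [self.module, self.subsection, self.page]
        return ".".join(str(p) for p in parts if p is not None)


@dataclass(frozen=True)
class SequenceAssignment:
    """The meaning of one event identifier.

    Exactly one of ``label``/``category`` is populated: a content page label,
    a feature category, or neither when the identifier is unmapped.
    """

    kind: str  # "content" | "feature" | "unmapped"
    label: ContentLabel | None = None
    category: FeatureCategory | None = None

    def __post_init__(self) -> None:
        if self.kind == "content":
            if self.label is None or self.category is not None:
                raise ValueError("content assignment requires label only")
        elif self.kind == "feature":
            if self.category is None or self.label is not None:
                raise ValueError("feature assignment requires category only")
        elif self.kind == "unmapped":
            if self.label is not None or self.category is not None:
                raise ValueError("unmapped assignment carries no payload")
        else:
            raise ValueError(f"unknown assignment kind {self.kind!r}")

    @classmethod
    def content(cls, label: ContentLabel) -> "SequenceAssignment":
        return cls("content", label=label)

    @classmethod
    def feature(cls, category: FeatureCategory) -> "SequenceAssignment":
        return cls("feature", category=category)

    @classmethod
    def unmapped(cls) -> "SequenceAssignment":
        return cls("unmapped")

    def __str__(self) -> str:
        if self.kind == "content":
            return str(self.label)
        if self.kind == "feature":
            return str(self.category)
        return "Unmapped"


@dataclass(frozen=True)
class RawEvent:
    """One logged action: who, when, what."""

    user_id: str
    timestamp: dt.datetime
    event_id: str = ""  # empty is a valid identifier (the landing page)


@dataclass
class LabeledEvent:
    """A raw event enriched with its assignment, session index and ordinal.

    ``ordinal`` is the rank of the content label in the intended sequence;
    present iff the assignment is content-kind.  ``session_index`` is 1-based
    and assigned by the sessionizer.
    """

    user_id: str
    timestamp: dt.datetime
    event_id: str
    assignment: SequenceAssignment
    session_index: int | None = None
    ordinal: int | None = None


@dataclass(frozen=True)
class RowError:
    """A non-fatal per-row ingestion problem, reported with its file line."""

    line: int  # 1-based physical line in the input file (header is line 1)
    message: str


@dataclass
class EventStream:
    """Events grouped per user, each user's events sorted by time.

    Equal timestamps keep input order (stable sort): same-minute rows are
    common at minute resolution and their order is meaningful.
    """

    users: dict[str, list[RawEvent]] = field(default_factory=dict)
    errors: list[RowError] = field(default_factory=list)

    @classmethod
    def from_events(cls, events: Iterable[RawEvent]) -> "EventStream":
        stream = cls()
        for ev in events:
            stream.users.setdefault(ev.user_id, []).append(ev)
        for evs in stream.users.values():
            evs.sort(key=lambda e: e.timestamp)  # stable: ties keep input order
        return stream

    @property
    def n_events(self) -> int:
        return sum(len(v) for v in self.users.values())

    @property
    def user_ids(self) -> list[str]:
        return list(self.users)

    def __iter__(self) -> Iterator[RawEvent]:
        for evs in self.users.values():
            yield from evs

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": e.user_id, "datetime": e.timestamp, "url": e.event_id}
            for e in self
        ]
        return pd.DataFrame(rows, columns=["id", "datetime", "url"])


_FALLBACK_FORMATS = ("%d/%m/%Y %H:%M", "%d/%m/%Y %H:%M:%S")


def _parse_timestamp(text: str, fmt: str | None) -> dt.datetime:
    text = text.strip()
    if fmt is not None:
        return dt.datetime.strptime(text, fmt)
    try:
        return dt.datetime.fromisoformat(text)
    except ValueError:
        pass
    for f in _FALLBACK_FORMATS:
        try:
            return dt.datetime.strptime(text, f)
        except ValueError:
            continue
    raise ValueError(f"unparseable timestamp {text!r}")


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_log(
    path: str | Path,
    *,
    user_col: str = "id",
    time_col: str = "datetime",
    event_col: str = "url",
    timestamp_format: str | None = None,
    delimiter: str | None = None,
) -> EventStream:
    """Read a raw delimited event log into an :class:`EventStream`.

    The default timestamp dialect is day-first ``DD/MM/YYYY HH:MM``
    (minute-resolution clinical logs); ISO-8601 is accepted automatically,
    and an explicit ``timestamp_format`` overrides both.  The delimiter is
    auto-detected among comma and tab unless given.

    Rows whose timestamp does not parse are skipped, collected on
    ``stream.errors`` with their file line number, and logged; a missing
    required column raises :class:`LogFormatError` naming the column.
    """
    path = Path(path)
    if not path.exists():
        raise LogFormatError(f"log file not found: {path}")
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (user_col, time_col, event_col):
        if col not in df.columns:
            raise LogFormatError(
                f"missing required column {col!r} in {path} "
                f"(found: {list(df.columns)})"
            )
    stream = EventStream()
    events: list[RawEvent] = []
    for idx, vals in enumerate(df.itertuples(index=False, name=None)):
        rec = dict(zip(df.columns, vals))
        try:
            ts = _parse_timestamp(rec[time_col], timestamp_format)
        except ValueError as exc:
            stream.errors.append(RowError(line=idx + 2, message=str(exc)))
            continue
        events.append(RawEvent(str(rec[user_col]), ts, str(rec[event_col])))
    for err in stream.errors:
        logger.warning("%s line %d: %s", path.name, err.line, err.message)
    sorted_stream = EventStream.from_events(events)
    stream.users = sorted_stream.users
    return stream


def write_view_table(view, path: str | Path) -> Path:
    """Write a view table to delimited text (CSV).

    ``view`` is any object with a ``to_frame()`` method (the four view
    products) or a plain DataFrame.  The written file round-trips through
    :func:`read_view_table` without value change at string level.
    """
    path = Path(path)
    frame = view if isinstance(view, pd.DataFrame) else view.to_frame()
    try:
        frame.to_csv(path, index=False)
    except OSError as exc:
        raise LogFormatError(f"cannot write view table to {path}: {exc}") from exc
    return path


def read_view_table(path: str | Path) -> pd.DataFrame:
    """Read back a view-table CSV as strings (exact round-trip of values)."""
    return pd.read_csv(path, dtype=str, keep_default_na=False)
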