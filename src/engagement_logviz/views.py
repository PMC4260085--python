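"""The four visualization-backing tables.

Each view is a small typed product computed from labeled, sessionized
events, with ``to_frame``/``from_frame`` converters so it can be written to
and reconstructed from a delimited spreadsheet:

* **NavigationTrace** — one user's content pages and app uses in sequential
  order, tagged with session index (the individual-engagement view).
* **StripeMatrix** — cohort x day boolean calendar of any-use days.
* **StartFinishView** — first and last content page of every session,
  sorted by the module of the finishing page.
* **TransitionMatrix** — empirical next-action counts/likelihoods between
  content pages (and, optionally, the five app categories), within sessions.

Home events and unmapped identifiers are excluded from every view; a day
with any logged event (including Home) counts as a usage day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .event_model import (
    APP_CATEGORIES,
    ContentLabel,
    FeatureCategory,
    LabeledEvent,
)
from .sessionizer import Session, usage_days

__all__ = [
    "NavPoint",
    "NavigationTrace",
    "StripeMatrix",
    "StartFinishRow",
    "StartFinishView",
    "TransitionMatrix",
    "navigation_view",
    "stripe_view",
    "start_finish_view",
    "next_action_view",
]

Cohort = Mapping[str, Sequence[Session]]

#: matrix index offset of each app category (appended after the K content ordinals)
_APP_INDEX = {cat: i for i, cat in enumerate(APP_CATEGORIES)}


def _included(ev: LabeledEvent) -> bool:
    """Events that enter views: content, or app features other than Home."""
    if ev.assignment.kind == "content":
        return True
    return (
        ev.assignment.kind == "feature"
        and ev.assignment.category is not FeatureCategory.HOME
    )


# ---------------------------------------------------------------------------
# Navigation trace


@dataclass(frozen=True)
class NavPoint:
    step: int  # 0-based position among the user's included events
    session_index: int
    kind: str  # "content" | "feature"
    label: str  # dotted content label or category name
    ordinal: int | None = None  # content only
    category: FeatureCategory | None = None  # feature only


@dataclass
class NavigationTrace:
    """Sequential-order trace of one user's content and app events."""

    user_id: str
    points: list[NavPoint] = field(default_factory=list)
    n_content: int | None = None  # K, for axis scaling when known

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "user_id": self.user_id,
                "step": p.step,
                "session_index": p.session_index,
                "kind": p.kind,
                "label": p.label,
                "ordinal": "" if p.ordinal is None else p.ordinal,
                "category": "" if p.category is None else p.category.value,
            }
            for p in self.points
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "user_id", "step", "session_index", "kind",
                "label", "ordinal", "category",
            ],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, user_id: str | None = None) -> "NavigationTrace":
        df = frame.astype(str)
        if user_id is not None:
            df = df[df["user_id"] == str(user_id)]
        points = []
        uid = str(user_id) if user_id is not None else ""
        for rec in df.to_dict("records"):
            uid = rec["user_id"]
            cat = rec["category"]
            points.append(
                NavPoint(
                    step=int(rec["step"]),
                    session_index=int(rec["session_index"]),
                    kind=rec["kind"],
                    label=rec["label"],
                    ordinal=int(rec["ordinal"]) if rec["ordinal"] != "" else None,
                    category=FeatureCategory(cat) if cat != "" else None,
                )
            )
        ordinals = [p.ordinal for p in points if p.ordinal is not None]
        n_content = (max(ordinals) + 1) if ordinals else None
        return cls(user_id=uid, points=points, n_content=n_content)


def navigation_view(
    sessions: Sequence[Session], *, n_content: int | None = None
) -> NavigationTrace:
    """Trace one user's included events across all sessions in order.

    Home and unmapped events are dropped; consecutive duplicate labels are
    retained (repetition of content is signal, not noise).  Steps are
    consecutive so rendering can insert inter-session gaps from the
    session-index tags.
    """
    if not sessions:
        return NavigationTrace(user_id="", n_content=n_content)
    trace = NavigationTrace(user_id=sessions[0].user_id, n_content=n_content)
    step = 0
    for session in sessions:
        for ev in session.events:
            if not _included(ev):
                continue
            if ev.assignment.kind == "content":
                point = NavPoint(
                    step=step,
                    session_index=session.session_index,
                    kind="content",
                    label=str(ev.assignment.label),
                    ordinal=ev.ordinal,
                )
            else:
                point = NavPoint(
                    step=step,
                    session_index=session.session_index,
                    kind="feature",
                    label=ev.assignment.category.value,
                    category=ev.assignment.category,
                )
            trace.points.append(point)
            step += 1
    if trace.n_content is None:
        ordinals = [p.ordinal for p in trace.points if p.ordinal is not None]
        trace.n_content = (max(ordinals) + 1) if ordinals else 0
    return trace


# ---------------------------------------------------------------------------
# Stripe matrix


@dataclass
class StripeMatrix:
    """Per-user binary calendar of days with any system use.

    ``cells[u, d]`` is True iff user ``users[u]`` generated any event on day
    offset ``d`` (relative to that user's first event).  ``period_marker``
    is the day index of the formal treatment-period end (default 56 = 8
    weeks); use beyond it is common and worth seeing.
    """

    users: list[str] = field(default_factory=list)
    cells: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), dtype=bool))
    period_marker: int = 56

    @property
    def n_days(self) -> int:
        return self.cells.shape[1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"user_id": u, "day": d, "used": int(self.cells[i, d])}
            for i, u in enumerate(self.users)
            for d in range(self.cells.shape[1])
        ]
        return pd.DataFrame(rows, columns=["user_id", "day", "used"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, period_marker: int = 56) -> "StripeMatrix":
        df = frame.astype(str)
        users = list(dict.fromkeys(df["user_id"]))
        n_days = (df["day"].astype(int).max() + 1) if len(df) else 0
        cells = np.zeros((len(users), n_days), dtype=bool)
        index = {u: i for i, u in enumerate(users)}
        for rec in df.to_dict("records"):
            cells[index[rec["user_id"]], int(rec["day"])] = rec["used"] == "1"
        return cls(users=users, cells=cells, period_marker=period_marker)


def stripe_view(cohort: Cohort, *, period_marker: int = 56) -> StripeMatrix:
    """Cohort usage calendar: one row per user, one column per day offset.

    Rows are ordered by first-event date then user id; the day axis spans
    0..D where D is the largest offset anywhere in the cohort.
    """
    per_user_days: dict[str, list[int]] = {}
    first_event: dict[str, object] = {}
    for user_id, sessions in cohort.items():
        events = [ev for s in sessions for ev in s.events]
        if not events:
            continue
        per_user_days[user_id] = usage_days(events)
        first_event[user_id] = events[0].timestamp
    users = sorted(per_user_days, key=lambda u: (first_event[u], u))
    n_days = 1 + max((d for days in per_user_days.values() for d in days), default=-1)
    cells = np.zeros((len(users), n_days), dtype=bool)
    for i, u in enumerate(users):
        cells[i, per_user_days[u]] = True
    return StripeMatrix(users=users, cells=cells, period_marker=period_marker)


# ---------------------------------------------------------------------------
# Start–finish view


@dataclass(frozen=True)
class StartFinishRow:
    user_id: str
    session_index: int
    start_label: ContentLabel
    end_label: ContentLabel
    start_ordinal: int
    end_ordinal: int


@dataclass
class StartFinishView:
    """First and last content page viewed in each session, cohort-wide."""

    rows: list[StartFinishRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "user_id": r.user_id,
                "session_index": r.session_index,
                "start_label": str(r.start_label),
                "end_label": str(r.end_label),
                "start_ordinal": r.start_ordinal,
                "end_ordinal": r.end_ordinal,
            }
            for r in self.rows
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "user_id", "session_index", "start_label",
                "end_label", "start_ordinal", "end_ordinal",
            ],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StartFinishView":
        df = frame.astype(str)
        rows = [
            StartFinishRow(
                user_id=rec["user_id"],
                session_index=int(rec["session_index"]),
                start_label=ContentLabel.parse(rec["start_label"]),
                end_label=ContentLabel.parse(rec["end_label"]),
                start_ordinal=int(rec["start_ordinal"]),
                end_ordinal=int(rec["end_ordinal"]),
            )
            for rec in df.to_dict("records")
        ]
        return cls(rows=rows)


def start_finish_view(cohort: Cohort) -> StartFinishView:
    """One row per session with at least one content event.

    Start/end are the first/last content events *by time* within the
    session; rows are sorted by (finishing module, finishing ordinal), ties
    broken by user id then session index for reproducible files.
    """
    rows: list[StartFinishRow] = []
    for user_id, sessions in cohort.items():
        for session in sessions:
            content = [ev for ev in session.events if ev.assignment.kind == "content"]
            if not content:
                continue
            first, last = content[0], content[-1]
            rows.append(
                StartFinishRow(
                    user_id=user_id,
                    session_index=session.session_index,
                    start_label=first.assignment.label,
                    end_label=last.assignment.label,
                    start_ordinal=first.ordinal,
                    end_ordinal=last.ordinal,
                )
            )
    rows.sort(
        key=lambda r: (r.end_label.module, r.end_ordinal, r.user_id, r.session_index)
    )
    return StartFinishView(rows=rows)


# ---------------------------------------------------------------------------
# Next-action transition matrix


@dataclass
class TransitionMatrix:
    """Next-action counts and likelihoods over content pages (+ app lanes).

    Axes are the K content ordinals in intended order, optionally followed
    by the five app categories as extra indices K..K+4.  ``probs`` is the
    row-normalized count matrix (zero rows stay zero).  Perfectly linear use
    puts all mass on the one-off diagonal ``(i, i+1)``.
    """

    labels: list[str] = field(default_factory=list)
    counts: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), dtype=int))
    n_content: int = 0

    @property
    def probs(self) -> np.ndarray:
        counts = self.counts.astype(float)
        sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(sums > 0, counts / np.where(sums == 0, 1, sums), 0.0)
        return probs

    def to_frame(self) -> pd.DataFrame:
        probs = self.probs
        rows = [
            {
                "from_index": i,
                "to_index": j,
                "from_label": self.labels[i],
                "to_label": self.labels[j],
                "count": int(self.counts[i, j]),
                "prob": repr(float(probs[i, j])),
            }
            for i in range(len(self.labels))
            for j in range(len(self.labels))
        ]
        return pd.DataFrame(
            rows,
            columns=["from_index", "to_index", "from_label", "to_label", "count", "prob"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TransitionMatrix":
        df = frame.astype(str)
        if not len(df):
            return cls()
        n = df["from_index"].astype(int).max() + 1
        labels = [""] * n
        counts = np.zeros((n, n), dtype=int)
        app_names = {c.value for c in APP_CATEGORIES}
        for rec in df.to_dict("records"):
            i, j = int(rec["from_index"]), int(rec["to_index"])
            labels[i] = rec["from_label"]
            labels[j] = rec["to_label"]
            counts[i, j] = int(rec["count"])
        n_content = sum(1 for lab in labels if lab not in app_names)
        return cls(labels=labels, counts=counts, n_content=n_content)


def next_action_view(
    cohort: Cohort,
    n_content: int,
    content_labels: Sequence[ContentLabel] | None = None,
    *,
    include_apps: bool = True,
    across_sessions: bool = False,
    collapse_repeats: bool = False,
) -> TransitionMatrix:
    """Pooled next-action matrix over a cohort.

    Transitions are counted between consecutive included events within each
    session (crossing a session boundary is returning-after-hours, not a
    click, unless ``across_sessions`` is set).  With ``include_apps`` the
    five app categories join the axes after the K content ordinals; without
    it the matrix is content x content and pairs are re-derived over the
    content-only subsequence.  ``collapse_repeats`` merges consecutive
    identical indices before counting, removing the self-transition
    diagonal.
    """
    size = n_content + (len(APP_CATEGORIES) if include_apps else 0)
    counts = np.zeros((size, size), dtype=int)

    def event_index(ev: LabeledEvent) -> int | None:
        if ev.assignment.kind == "content":
            return ev.ordinal
        if include_apps and _included(ev):
            return n_content + _APP_INDEX[ev.assignment.category]
        return None

    for sessions in cohort.values():
        user_seq: list[int] = []
        for session in sessions:
            indices = [
                idx for ev in session.events
                if (idx := event_index(ev)) is not None
            ]
            if across_sessions:
                user_seq.extend(indices)
            else:
                _count_pairs(counts, indices, collapse_repeats)
        if across_sessions:
            _count_pairs(counts, user_seq, collapse_repeats)

    if content_labels is not None:
        labels = [str(lab) for lab in content_labels]
    else:
        labels = [str(i) for i in range(n_content)]
    if include_apps:
        labels = labels + [c.value for c in APP_CATEGORIES]
    return TransitionMatrix(labels=labels, counts=counts, n_content=n_content)


def _count_pairs(counts: np.ndarray, indices: list[int], collapse_repeats: bool) -> None:
    if collapse_repeats:
        indices = [idx for k, idx in enumerate(indices) if k == 0 or idx != indices[k - 1]]
    for a, b in zip(indices, indices[1:]):
        counts[a, b] += 1
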