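"""Synthetic intervention-log generator with known ground truth.

Real intervention logs are rarely shareable, so every view in this package
is exercised on generated cohorts that emulate the salient features of such
data: content organized into ordered modules/subsections/pages, interleaved
app events (journal, mindfulness, exercises, supporter reviews, quizzes),
sessions separated by inactivity gaps, and sharply different usage
archetypes —

* ``linear_completer`` — works through the content in strictly increasing
  intended order, a bit per session;
* ``repeater`` — progresses forward but regularly re-reads earlier
  modules;
* ``app_focused`` — most events are app uses, content visits sparse and
  nonlinear;
* ``burst_user`` — sessions concentrated in 2–4-day clusters separated by
  at least a week of silence.

Gaps are constructed *bounded away* from the 60-minute session threshold
(within-session gaps 0–5 min, between-session gaps ≥ 90 min) so that
sessionization recovers the generator's session boundaries exactly rather
than probabilistically.  Timestamps are emitted at minute resolution.
Generation is fully reproducible from the seed.
"""

from __future__ import annotations

import datetime as dt
import math
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .event_model import ContentLabel, EventStream, FeatureCategory, RawEvent
from .keymap import KeyMap

__all__ = [
    "ARCHETYPES",
    "SyntheticCohortConfig",
    "UserGroundTruth",
    "GroundTruth",
    "generate_cohort",
]

ARCHETYPES = ("linear_completer", "repeater", "app_focused", "burst_user")

#: URLs the generator emits for app events, one per category (Home is "").
_APP_URLS = {
    FeatureCategory.JOURNAL: "journal/",
    FeatureCategory.MINDFULNESS: "mindfulness/",
    FeatureCategory.EXERCISE: "exercise/",
    FeatureCategory.REVIEW: "review/",
    FeatureCategory.OTHER: "quiz/",
}
_APP_WEIGHTS = {
    FeatureCategory.JOURNAL: 0.30,
    FeatureCategory.EXERCISE: 0.25,
    FeatureCategory.MINDFULNESS: 0.20,
    FeatureCategory.REVIEW: 0.15,
    FeatureCategory.OTHER: 0.10,
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort-generation parameters.

    Defaults model an 8-module program (modules 0–7: an introduction module
    0, core modules, and review/optional modules at the end), each module a
    landing page plus 3 subsections of 3 pages, used over a 70-day window —
    longer than the 56-day formally supported period, since real use
    continues past it.  Roughly 3 sessions per week with 4–12 content/app
    events each.
    """

    n_users: int = 20
    n_modules: int = 8
    subsections_per_module: int = 3
    pages_per_subsection: int = 3
    period_days: int = 70
    archetype_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "linear_completer": 0.35,
            "repeater": 0.25,
            "app_focused": 0.20,
            "burst_user": 0.20,
        }
    )
    sessions_per_week: float = 3.0
    session_length_range: tuple[int, int] = (4, 12)
    app_events_per_session: float = 2.0
    seed: int = 0
    start_date: dt.date = dt.date(2012, 3, 1)

    def __post_init__(self) -> None:
        if self.n_users < 0:
            raise ValueError("n_users must be non-negative")
        for name in ("n_modules", "subsections_per_module",
                     "pages_per_subsection", "period_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sessions_per_week <= 0 or self.app_events_per_session < 0:
            raise ValueError("rates must be positive")
        lo, hi = self.session_length_range
        if not (1 <= lo <= hi):
            raise ValueError("session_length_range must satisfy 1 <= lo <= hi")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes in mix: {sorted(unknown)}")
        total = sum(self.archetype_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"archetype proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.archetype_mix.values()):
            raise ValueError("archetype proportions must be non-negative")

    def content_labels(self) -> list[ContentLabel]:
        """Intended content sequence: per module, the landing page then
        subsection pages in order."""
        labels: list[ContentLabel] = []
        for m in range(self.n_modules):
            labels.append(ContentLabel(m))
            for s in range(self.subsections_per_module):
                for p in range(self.pages_per_subsection):
                    labels.append(ContentLabel(m, s, p))
        return labels


@dataclass
class UserGroundTruth:
    """What the generator knows to be true about one user."""

    user_id: str
    archetype: str
    session_sizes: list[int] = field(default_factory=list)  # all events incl. Home
    session_first_last: list[tuple[str | None, str | None]] = field(
        default_factory=list
    )  # dotted content labels; (None, None) for app-only sessions
    usage_days: list[int] = field(default_factory=list)


@dataclass
class GroundTruth:
    users: dict[str, UserGroundTruth] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Per-session long form; usage days joined per user for one CSV."""
        rows = []
        for gt in self.users.values():
            days = "|".join(str(d) for d in gt.usage_days)
            for k, (size, (first, last)) in enumerate(
                zip(gt.session_sizes, gt.session_first_last), start=1
            ):
                rows.append(
                    {
                        "user_id": gt.user_id,
                        "archetype": gt.archetype,
                        "session_index": k,
                        "n_events": size,
                        "first_content": first or "",
                        "last_content": last or "",
                        "usage_days": days,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["user_id", "archetype", "session_index", "n_events",
                     "first_content", "last_content", "usage_days"],
        )


def _poisson(rng: random.Random, lam: float) -> int:
    """Small-mean Poisson draw (Knuth)."""
    if lam <= 0:
        return 0
    limit, k, p = math.exp(-lam), 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def _allocate_archetypes(config: SyntheticCohortConfig, rng: random.Random) -> list[str]:
    """Largest-remainder allocation of archetype counts, then shuffle."""
    quotas = {a: config.archetype_mix.get(a, 0.0) * config.n_users for a in ARCHETYPES}
    counts = {a: int(q) for a, q in quotas.items()}
    short = config.n_users - sum(counts.values())
    for a in sorted(ARCHETYPES, key=lambda a: quotas[a] - counts[a], reverse=True)[:short]:
        counts[a] += 1
    pool = [a for a in ARCHETYPES for _ in range(counts[a])]
    rng.shuffle(pool)
    return pool


def _session_day_slots(
    rng: random.Random, archetype: str, config: SyntheticCohortConfig
) -> list[int]:
    """Day offsets of intended session starts (may repeat for same-day pairs)."""
    slots: list[int] = []
    if archetype == "burst_user":
        day = rng.randint(0, 3)
        while day < config.period_days:
            cur = day
            for d in range(rng.randint(2, 4)):
                cur = day + d
                if cur >= config.period_days:
                    break
                for _ in range(rng.randint(1, 2)):
                    slots.append(cur)
            day = cur + rng.randint(8, 15)  # >= 7 fully quiet days
    else:
        target = max(
            1,
            round(config.sessions_per_week * config.period_days / 7
                  * rng.uniform(0.7, 1.3)),
        )
        day = rng.randint(0, 2)
        while len(slots) < target and day < config.period_days:
            slots.append(day)
            if rng.random() < 0.15 and len(slots) < target:
                slots.append(day)
            day += rng.choices((1, 2, 3, 4), (0.45, 0.30, 0.15, 0.10))[0]
    return slots


def _session_content(
    rng: random.Random, archetype: str, n_content_events: int, ptr: int, n_labels: int
) -> tuple[list[int], int]:
    """Content ordinals for one session plus the advanced forward pointer."""
    if n_content_events == 0:
        return [], ptr
    if archetype == "linear_completer":
        take = min(n_content_events, n_labels - ptr)
        return list(range(ptr, ptr + take)), ptr + take
    if archetype == "app_focused":
        return [rng.randrange(n_labels) for _ in range(n_content_events)], ptr
    # repeater / burst_user: forward chunks with occasional replays of
    # earlier material
    if ptr > 0 and rng.random() < 0.4:
        start = rng.randrange(ptr)
        take = min(n_content_events, ptr - start)
        return list(range(start, start + take)), ptr
    take = min(n_content_events, n_labels - ptr)
    ords = list(range(ptr, ptr + take))
    return ords, ptr + take


def _generate_user(
    rng: random.Random,
    user_id: str,
    archetype: str,
    config: SyntheticCohortConfig,
    labels: Sequence[ContentLabel],
) -> tuple[list[RawEvent], UserGroundTruth]:
    truth = UserGroundTruth(user_id=user_id, archetype=archetype)
    events: list[RawEvent] = []
    n_labels = len(labels)
    ptr = 0
    prev_end: dt.datetime | None = None
    app_cats = list(_APP_WEIGHTS)
    app_w = list(_APP_WEIGHTS.values())

    for day in _session_day_slots(rng, archetype, config):
        start = dt.datetime.combine(
            config.start_date + dt.timedelta(days=day),
            dt.time(rng.randint(8, 20), rng.randint(0, 59)),
        )
        if prev_end is not None and start < prev_end + dt.timedelta(minutes=90):
            start = prev_end + dt.timedelta(minutes=90 + rng.randint(0, 60))

        n_incl = rng.randint(*config.session_length_range)
        if archetype == "app_focused":
            n_app = max(1, math.ceil(0.78 * n_incl))
        else:
            n_app = min(n_incl - 1, _poisson(rng, config.app_events_per_session))
        n_cont = n_incl - n_app
        content_ords, ptr = _session_content(rng, archetype, n_cont, ptr, n_labels)
        if archetype == "linear_completer" and not content_ords and ptr >= n_labels:
            break  # program completed; completers stop

        # interleave apps at random positions, preserving content order
        slots: list[tuple[str, object]] = [("content", o) for o in content_ords]
        for _ in range(n_app):
            slots.insert(
                rng.randint(0, len(slots)), ("app", rng.choices(app_cats, app_w)[0])
            )
        if rng.random() < 0.7:
            slots.insert(0, ("home", None))

        t = start
        session_events: list[RawEvent] = []
        for kind, payload in slots:
            if kind == "home":
                url = ""
            elif kind == "content":
                lab = labels[payload]
                url = (
                    f"content/{lab.module}/"
                    if lab.subsection is None
                    else f"content/{lab.module}/{lab.subsection}/{lab.page}/"
                )
            else:
                url = _APP_URLS[payload]
            session_events.append(RawEvent(user_id, t, url))
            t += dt.timedelta(minutes=rng.randint(0, 5))  # <= 45 within session
        if not session_events:
            continue
        events.extend(session_events)
        prev_end = session_events[-1].timestamp

        truth.session_sizes.append(len(session_events))
        content_labels = [str(labels[o]) for o in content_ords]
        truth.session_first_last.append(
            (content_labels[0], content_labels[-1]) if content_labels else (None, None)
        )

    if events:
        base = events[0].timestamp.date()
        truth.usage_days = sorted({(e.timestamp.date() - base).days for e in events})
    return events, truth


def build_key(config: SyntheticCohortConfig) -> KeyMap:
    """Key file matching the generator's URL scheme."""
    pairs: list[tuple[str, str]] = []
    for lab in config.content_labels():
        if lab.subsection is None:
            pairs.append((f"content/{lab.module}/", str(lab)))
        else:
            pairs.append(
                (f"content/{lab.module}/{lab.subsection}/{lab.page}/", str(lab))
            )
    pairs += [
        ("journal/", "Journal"),
        ("mindfulness/", "Mindfulness"),
        ("exercise/", "Exercise"),
        ("review/", "Review"),
        ("quiz/", "Other"),
    ]
    return KeyMap.from_pairs(pairs)


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[EventStream, KeyMap, GroundTruth]:
    """Generate a reproducible synthetic cohort.

    Returns the raw event stream, the matching key, and the ground truth
    (per user: archetype, session sizes, per-session first/last content
    labels, usage days) against which the processing pipeline can be
    checked exactly.
    """
    rng = random.Random(config.seed)
    archetypes = _allocate_archetypes(config, rng)
    labels = config.content_labels()
    key = build_key(config)

    all_events: list[RawEvent] = []
    truth = GroundTruth()
    width = max(3, len(str(max(config.n_users, 1))))
    for i, archetype in enumerate(archetypes):
        user_id = f"u{i + 1:0{width}d}"
        user_rng = random.Random(rng.getrandbits(32))
        events, user_truth = _generate_user(user_rng, user_id, archetype, config, labels)
        all_events.extend(events)
        truth.users[user_id] = user_truth
    return EventStream.from_events(all_events), key, truth
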