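"""Key-file parsing and event-identifier mapping.

The key file is the curated table that gives raw event identifiers their
meaning: each row maps an identifier pattern (usually a URL path) either to
a content label (``module.subsection.page``) or to a feature category.
Sorting the distinct content labels numerically, module-major, recovers the
author's intended reading order; the rank of a label in that order is its
*content ordinal*, the vertical axis of the navigation graph.

Identifiers need not be unique — several URLs may map to the same piece of
content and then share one ordinal.  Whether an app URL counts as content
(reached inside a page) or as a standalone feature is a curation decision
recorded in the key file, not a heuristic.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .event_model import (
    CATEGORY_ALIASES,
    ContentLabel,
    EventStream,
    FeatureCategory,
    LabeledEvent,
    LogFormatError,
    SequenceAssignment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "KeyEntry",
    "KeyMap",
    "KeyParseError",
    "parse_key_file",
    "map_event",
    "content_ordinal",
    "label_stream",
    "MappingSummary",
]


class KeyParseError(LogFormatError):
    """Malformed or internally inconsistent key file."""


def _normalize_pattern(pattern: str) -> str:
    return pattern.lstrip("/")


def parse_label(text: str) -> SequenceAssignment:
    """Parse a key-file label cell into an assignment.

    Dotted numeric strings are content labels; otherwise the cell must name
    a feature category or one of its aliases (Supporter -> Review,
    Feature -> Other).
    """
    text = text.strip()
    try:
        return SequenceAssignment.content(ContentLabel.parse(text))
    except ValueError:
        pass
    if text in CATEGORY_ALIASES:
        return SequenceAssignment.feature(CATEGORY_ALIASES[text])
    for cat in FeatureCategory:
        if text == cat.value:
            return SequenceAssignment.feature(cat)
    raise KeyParseError(
        f"label {text!r} is neither a dotted content label nor a known "
        f"feature category/alias"
    )


@dataclass(frozen=True)
class KeyEntry:
    """One key-file row: a pattern, its assignment, and — for content —
    the rank of its label in the intended sequence."""

    pattern: str
    assignment: SequenceAssignment
    order_rank: int | None = None


@dataclass
class KeyMap:
    """Parsed key: pattern table plus the content ordinal ranking.

    ``match_mode`` is ``"suffix"`` (exact match wins, else the longest
    pattern that is a suffix of the identifier) or ``"exact"``.  Leading
    slashes are stripped from both patterns and identifiers, so
    ``content/9/53/98/`` and ``/content/9/53/98/`` are the same key.
    """

    entries: list[KeyEntry] = field(default_factory=list)
    match_mode: str = "suffix"
    _by_pattern: dict[str, KeyEntry] = field(default_factory=dict, repr=False)
    _ordinals: dict[ContentLabel, int] = field(default_factory=dict, repr=False)
    _suffix_order: list[str] = field(default_factory=list, repr=False)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], match_mode: str = "suffix"
    ) -> "KeyMap":
        """Build a key from (pattern, label-text) pairs.

        Duplicate patterns with identical assignments are collapsed;
        conflicting assignments for one pattern are an error.
        """
        if match_mode not in ("suffix", "exact"):
            raise ValueError(f"unknown match mode {match_mode!r}")
        assignments: dict[str, SequenceAssignment] = {}
        order: list[str] = []
        for i, (pattern, label_text) in enumerate(pairs, start=1):
            norm = _normalize_pattern(str(pattern).strip())
            try:
                assignment = parse_label(str(label_text))
            except KeyParseError as exc:
                raise KeyParseError(f"key row {i}: {exc}") from None
            if norm in assignments:
                if assignments[norm] != assignment:
                    raise KeyParseError(
                        f"key row {i}: pattern {pattern!r} already mapped to "
                        f"{assignments[norm]} but now {assignment}"
                    )
                continue
            assignments[norm] = assignment
            order.append(norm)

        labels = sorted(
            {a.label for a in assignments.values() if a.kind == "content"},
            key=lambda lab: lab.sort_key,
        )
        ordinals = {lab: rank for rank, lab in enumerate(labels)}

        key = cls(match_mode=match_mode)
        key._ordinals = ordinals
        for norm in order:
            assignment = assignments[norm]
            rank = ordinals[assignment.label] if assignment.kind == "content" else None
            entry = KeyEntry(pattern=norm, assignment=assignment, order_rank=rank)
            key.entries.append(entry)
            key._by_pattern[norm] = entry
        key._suffix_order = sorted(key._by_pattern, key=len, reverse=True)
        return key

    # -- lookup ------------------------------------------------------------

    @property
    def n_content(self) -> int:
        """Number of distinct content labels, K; ordinals run 0..K-1."""
        return len(self._ordinals)

    @property
    def content_labels(self) -> list[ContentLabel]:
        """Content labels in intended order (index == ordinal)."""
        return sorted(self._ordinals, key=self._ordinals.__getitem__)

    def lookup(self, event_id: str) -> SequenceAssignment:
        """Total mapping of one identifier: empty -> Home; no match -> unmapped."""
        norm = _normalize_pattern(event_id.strip())
        if norm == "":
            return SequenceAssignment.feature(FeatureCategory.HOME)
        entry = self._by_pattern.get(norm)
        if entry is not None:
            return entry.assignment
        if self.match_mode == "suffix":
            for pattern in self._suffix_order:
                if pattern and norm.endswith(pattern):
                    return self._by_pattern[pattern].assignment
        return SequenceAssignment.unmapped()

    def ordinal(self, label: ContentLabel) -> int:
        if label not in self._ordinals:
            raise KeyError(f"content label {label} not present in key")
        return self._ordinals[label]


def parse_key_file(
    path: str | Path,
    *,
    pattern_col: str = "pattern",
    label_col: str = "label",
    match_mode: str = "suffix",
    delimiter: str | None = None,
) -> KeyMap:
    """Parse a delimited key file (columns ``pattern``, ``label``)."""
    path = Path(path)
    if not path.exists():
        raise KeyParseError(f"key file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c",
                     dtype=str, keep_default_na=False)
    for col in (pattern_col, label_col):
        if col not in df.columns:
            raise KeyParseError(
                f"missing required column {col!r} in {path} "
                f"(found: {list(df.columns)})"
            )
    pairs = list(zip(df[pattern_col], df[label_col]))
    return KeyMap.from_pairs(pairs, match_mode=match_mode)


def map_event(event_id: str, key: KeyMap) -> SequenceAssignment:
    """Map one event identifier; total and deterministic, never raises."""
    return key.lookup(event_id)


def content_ordinal(label: ContentLabel, key: KeyMap) -> int:
    """Rank of ``label`` in the intended content sequence (0-based)."""
    return key.ordinal(label)


@dataclass
class MappingSummary:
    """Counts from labeling a stream, for the processing log."""

    n_events: int = 0
    n_unmapped: int = 0
    unmapped_ids: Counter = field(default_factory=Counter)


def label_stream(
    stream: EventStream, key: KeyMap, *, strict: bool = False
) -> tuple[dict[str, list[LabeledEvent]], MappingSummary]:
    """Label every event in a stream against a key.

    Returns events per user (original order preserved) plus a summary of
    unmapped identifiers.  In strict mode any unmapped identifier raises;
    by default unmapped events are kept (downstream views skip them) and
    counted.
    """
    summary = MappingSummary()
    labeled: dict[str, list[LabeledEvent]] = {}
    for user_id, events in stream.users.items():
        out: list[LabeledEvent] = []
        for ev in events:
            assignment = key.lookup(ev.event_id)
            summary.n_events += 1
            ordinal = None
            if assignment.kind == "content":
                ordinal = key.ordinal(assignment.label)
            elif assignment.kind == "unmapped":
                summary.n_unmapped += 1
                summary.unmapped_ids[ev.event_id] += 1
                if strict:
                    raise KeyParseError(
                        f"unmapped event identifier {ev.event_id!r} "
                        f"(user {user_id}, {ev.timestamp})"
                    )
            out.append(
                LabeledEvent(
                    user_id=ev.user_id,
                    timestamp=ev.timestamp,
                    event_id=ev.event_id,
                    assignment=assignment,
                    ordinal=ordinal,
                )
            )
        labeled[user_id] = out
    if summary.n_unmapped:
        logger.info(
            "%d of %d events unmapped (%d distinct identifiers)",
            summary.n_unmapped, summary.n_events, len(summary.unmapped_ids),
        )
    return labeled, summary
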