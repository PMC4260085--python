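import numpy as np
import pytest
from hypothesis import given, strategies as st

import engagement_logviz as elv
from engagement_logviz.keymap import KeyMap
from engagement_logviz.sessionizer import SessionConfig
from engagement_logviz.views import (
    navigation_view,
    next_action_view,
    start_finish_view,
    stripe_view,
)

from conftest import label_with, make_events


@pytest.fixture(scope="module")
def tiny_key():
    """Four content pages (two modules) plus one app pattern per category."""
    return KeyMap.from_pairs(
        [
            ("c/1/", "1"),
            ("c/1/1/", "1.1.0"),
            ("c/1/2/", "1.1.1"),
            ("c/2/", "2"),
            ("j/", "Journal"),
            ("m/", "Mindfulness"),
            ("e/", "Exercise"),
            ("r/", "Review"),
            ("q/", "Other"),
        ]
    )


def cohort_of(tiny_key, user_rows, threshold=60):
    """user_rows: {user: [(minute, event_id), ...]} -> sessionized cohort."""
    labeled = {}
    for user, rows in user_rows.items():
        minutes = [m for m, _ in rows]
        ids = [e for _, e in rows]
        labeled.update(label_with(tiny_key, make_events(user, minutes, ids)))
    return elv.sessionize(labeled, SessionConfig.from_minutes(threshold))


class TestNavigationView:
    def test_home_dropped_content_and_apps_kept(self, tiny_key):
        cohort = cohort_of(tiny_key, {"u": [(0, ""), (1, "c/1/1/"), (2, "j/")]})
        trace = navigation_view(cohort["u"])
        assert [(p.step, p.label) for p in trace.points] == [
            (0, "1.1.0"),
            (1, "Journal"),
        ]
        assert trace.points[0].ordinal == tiny_key.ordinal(
            elv.ContentLabel.parse("1.1.0")
        )

    def test_only_home_or_unmapped_gives_empty_trace(self, tiny_key):
        cohort = cohort_of(tiny_key, {"u": [(0, ""), (1, "zzz")]})
        assert navigation_view(cohort["u"]).points == []

    def test_fixture_user_content_subsequence_matches_printed_order(
        self, example_cohort, example_key
    ):
        trace = navigation_view(example_cohort["8"], n_content=example_key.n_content)
        content = [p.label for p in trace.points if p.kind == "content"]
        assert content[:5] == ["1", "1.0.1", "1.1.0", "1.1.0", "1.1.1"]

    def test_trace_length_counts_mapped_non_home_events(
        self, example_cohort, example_key
    ):
        trace = navigation_view(example_cohort["8"])
        oracle = sum(
            1
            for s in example_cohort["8"]
            for ev in s.events
            if ev.assignment.kind == "content"
            or (
                ev.assignment.kind == "feature"
                and ev.assignment.category is not elv.FeatureCategory.HOME
            )
        )
        assert len(trace.points) == oracle
        assert [p.step for p in trace.points] == list(range(oracle))

    def test_consecutive_duplicates_retained(self, tiny_key):
        cohort = cohort_of(tiny_key, {"u": [(0, "c/1/1/"), (1, "c/1/1/")]})
        trace = navigation_view(cohort["u"])
        assert [p.label for p in trace.points] == ["1.1.0", "1.1.0"]

    def test_order_preserving_ordinals(self, example_cohort, example_key):
        trace = navigation_view(example_cohort["8"])
        for p in trace.points:
            if p.kind == "content":
                assert p.ordinal == elv.content_ordinal(
                    elv.ContentLabel.parse(p.label), example_key
                )


class TestStripeView:
    def test_single_user_single_day(self, tiny_key):
        cohort = cohort_of(tiny_key, {"u": [(0, "c/1/")]})
        matrix = stripe_view(cohort)
        assert matrix.users == ["u"]
        assert matrix.cells.shape == (1, 1) and matrix.cells[0, 0]

    def test_burst_days_exactly_marked(self, tiny_key):
        day = 24 * 60
        rows = [(d * day, "c/1/") for d in (0, 1, 2, 20, 21, 60)]
        cohort = cohort_of(tiny_key, {"u": rows})
        matrix = stripe_view(cohort)
        assert list(np.flatnonzero(matrix.cells[0])) == [0, 1, 2, 20, 21, 60]

    def test_row_counts_equal_usage_day_sets(self, example_cohort):
        matrix = stripe_view(example_cohort)
        for i, user in enumerate(matrix.users):
            events = [ev for s in example_cohort[user] for ev in s.events]
            assert matrix.cells[i].sum() == len(elv.usage_days(events))

    def test_rows_ordered_by_first_event_then_id(self, tiny_key):
        day = 24 * 60
        cohort = cohort_of(
            tiny_key,
            {"b": [(0, "c/1/")], "a": [(day, "c/1/")], "c": [(0, "c/1/")]},
        )
        assert stripe_view(cohort).users == ["b", "c", "a"]


class TestStartFinishView:
    def test_single_content_event_degenerate(self, tiny_key):
        cohort = cohort_of(tiny_key, {"u": [(0, "c/2/")]})
        (row,) = start_finish_view(cohort).rows
        assert str(row.start_label) == str(row.end_label) == "2"

    def test_start_end_by_time_not_by_ordinal(self, tiny_key):
        cohort = cohort_of(
            tiny_key, {"u": [(0, "c/1/2/"), (1, "c/2/"), (2, "c/1/1/")]}
        )
        (row,) = start_finish_view(cohort).rows
        assert (str(row.start_label), str(row.end_label)) == ("1.1.1", "1.1.0")

    def test_app_only_sessions_produce_no_row(self, tiny_key):
        cohort = cohort_of(tiny_key, {"u": [(0, "j/"), (1, "m/")]})
        assert start_finish_view(cohort).rows == []

    def test_sorted_by_finishing_module_then_ordinal(self, tiny_key):
        cohort = cohort_of(
            tiny_key,
            {
                "u": [(0, "c/2/"), (200, "c/1/1/")],  # two sessions
                "v": [(0, "c/1/2/")],
            },
        )
        rows = start_finish_view(cohort).rows
        ends = [(r.end_label.module, r.end_ordinal) for r in rows]
        assert ends == sorted(ends)

    def test_removing_app_events_preserves_rows(self, tiny_key):
        with_apps = {"u": [(0, "j/"), (1, "c/1/1/"), (2, "m/"), (3, "c/2/"), (4, "e/")]}
        without = {"u": [(1, "c/1/1/"), (3, "c/2/")]}
        rows_a = start_finish_view(cohort_of(tiny_key, with_apps)).rows
        rows_b = start_finish_view(cohort_of(tiny_key, without)).rows
        assert [(r.start_label, r.end_label) for r in rows_a] == [
            (r.start_label, r.end_label) for r in rows_b
        ]

    def test_rows_never_exceed_session_count(self, example_cohort):
        rows = start_finish_view(example_cohort).rows
        assert len(rows) <= sum(len(s) for s in example_cohort.values())


class TestNextActionView:
    def test_single_transition(self, tiny_key):
        cohort = cohort_of(tiny_key, {"u": [(0, "c/1/1/"), (1, "c/1/2/")]})
        tm = next_action_view(cohort, tiny_key.n_content, tiny_key.content_labels)
        i = tiny_key.ordinal(elv.ContentLabel.parse("1.1.0"))
        j = tiny_key.ordinal(elv.ContentLabel.parse("1.1.1"))
        assert tm.counts[i, j] == 1 and tm.counts.sum() == 1

    def test_strictly_linear_user_gives_one_off_diagonal(self, tiny_key):
        rows = [(k, url) for k, url in enumerate(["c/1/", "c/1/1/", "c/1/2/", "c/2/"])]
        cohort = cohort_of(tiny_key, {"u": rows})
        tm = next_action_view(cohort, tiny_key.n_content, tiny_key.content_labels)
        probs = tm.probs
        for i in range(tiny_key.n_content - 1):
            assert probs[i, i + 1] == 1.0

    def test_no_transition_across_session_boundary(self, tiny_key):
        cohort = cohort_of(tiny_key, {"u": [(0, "c/1/"), (200, "c/1/1/")]})
        tm = next_action_view(cohort, tiny_key.n_content, tiny_key.content_labels)
        assert tm.counts.sum() == 0
        tm2 = next_action_view(
            cohort, tiny_key.n_content, tiny_key.content_labels, across_sessions=True
        )
        assert tm2.counts.sum() == 1

    def test_apps_occupy_extra_indices(self, tiny_key):
        cohort = cohort_of(tiny_key, {"u": [(0, "c/2/"), (1, "j/")]})
        tm = next_action_view(cohort, tiny_key.n_content, tiny_key.content_labels)
        i = tiny_key.ordinal(elv.ContentLabel.parse("2"))
        j = tiny_key.n_content + list(elv.APP_CATEGORIES).index(
            elv.FeatureCategory.JOURNAL
        )
        assert tm.counts[i, j] == 1
        assert tm.labels[j] == "Journal"

    def test_content_only_mode_recounts_over_content_subsequence(self, tiny_key):
        cohort = cohort_of(
            tiny_key, {"u": [(0, "c/1/"), (1, "j/"), (2, "c/1/1/")]}
        )
        with_apps = next_action_view(
            cohort, tiny_key.n_content, tiny_key.content_labels
        )
        content_only = next_action_view(
            cohort, tiny_key.n_content, tiny_key.content_labels, include_apps=False
        )
        i = tiny_key.ordinal(elv.ContentLabel.parse("1"))
        j = tiny_key.ordinal(elv.ContentLabel.parse("1.1.0"))
        assert with_apps.counts[i, j] == 0  # journal interrupts the pair
        assert content_only.counts[i, j] == 1
        assert content_only.counts.shape == (tiny_key.n_content, tiny_key.n_content)

    def test_collapse_repeats_removes_diagonal(self, tiny_key):
        cohort = cohort_of(
            tiny_key, {"u": [(0, "c/1/1/"), (1, "c/1/1/"), (2, "c/1/2/")]}
        )
        default = next_action_view(cohort, tiny_key.n_content, tiny_key.content_labels)
        collapsed = next_action_view(
            cohort, tiny_key.n_content, tiny_key.content_labels, collapse_repeats=True
        )
        i = tiny_key.ordinal(elv.ContentLabel.parse("1.1.0"))
        assert default.counts[i, i] == 1
        assert collapsed.counts[i, i] == 0 and collapsed.counts.sum() == 1

    @given(st.lists(st.integers(0, 8), min_size=0, max_size=40), st.integers(0, 3))
    def test_conservation_and_normalization_laws(self, codes, n_extra_users):
        """Total counts equal the pair-enumeration oracle; rows of probs sum
        to 1 or 0."""
        key = KeyMap.from_pairs(
            [(f"c/{k}/", str(k)) for k in range(5)]
            + [("j/", "Journal"), ("e/", "Exercise"), ("h/", "Other"), ("zz/", "Review")]
        )
        urls = [f"c/{k}/" for k in range(5)] + ["j/", "e/", "h/", "zz/"]
        # varied gaps: some split the stream (40 > 25), some do not (5)
        minute, rows = 0, []
        for m, c in enumerate(codes):
            minute += 5 if m % 3 else 40
            rows.append((minute, urls[c]))
        user_rows = {"u": rows}
        for k in range(n_extra_users):
            user_rows[f"x{k}"] = rows[: len(rows) // 2]
        cohort = cohort_of(key, user_rows, threshold=25)
        tm = next_action_view(cohort, key.n_content, key.content_labels)
        oracle = sum(
            max(0, len(s.events) - 1)
            for sessions in cohort.values()
            for s in sessions
        )
        assert tm.counts.sum() == oracle
        row_sums = tm.probs.sum(axis=1)
        assert all(abs(s - 1) < 1e-9 or s == 0 for s in row_sums)
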