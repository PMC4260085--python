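"""Engagement analysis and visualization for web-based-intervention event logs.

The package turns a raw click log (user id, timestamp, event identifier)
and a curated key file (identifier -> content label or feature category,
plus the intended content order) into four visualization-backing tables —
navigation trace, stripe calendar, start–finish rows, next-action
transition matrix — and static renderings of each, with a synthetic-cohort
generator providing ground truth for end-to-end checks.
"""

from importlib import resources as _resources
from pathlib import Path as _Path

__version__ = "0.1.0"

from .event_model import (  # noqa: F401
    APP_CATEGORIES,
    ContentLabel,
    EventStream,
    FeatureCategory,
    LabeledEvent,
    LogFormatError,
    RawEvent,
    SequenceAssignment,
    read_log,
    read_view_table,
    write_view_table,
)
from .keymap import (  # noqa: F401
    KeyEntry,
    KeyMap,
    KeyParseError,
    content_ordinal,
    label_stream,
    map_event,
    parse_key_file,
)
from .sessionizer import (  # noqa: F401
    Session,
    SessionConfig,
    segment,
    sessionize,
    usage_days,
)
from .views import (  # noqa: F401
    NavigationTrace,
    StartFinishRow,
    StartFinishView,
    StripeMatrix,
    TransitionMatrix,
    navigation_view,
    next_action_view,
    start_finish_view,
    stripe_view,
)
from .render import RenderSpec, render_view  # noqa: F401
from .synth import (  # noqa: F401
    ARCHETYPES,
    GroundTruth,
    SyntheticCohortConfig,
    generate_cohort,
)


def example_log_path() -> _Path:
    """Path to the bundled single-session example log (63 rows)."""
    return _Path(_resources.files("engagement_logviz") / "data" / "table1_log.csv")


def example_key_path() -> _Path:
    """Path to the key file matching the bundled example log."""
    return _Path(_resources.files("engagement_logviz") / "data" / "table1_key.csv")
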