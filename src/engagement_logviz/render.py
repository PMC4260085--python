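"""Static renderings of the four engagement views.

Conventions follow the views they draw: the navigation graph is a line
over content ordinals with per-session color alternation, horizontal gaps
between sessions and five app lanes across the top; the stripe graph fills
used days per user with a vertical marker at the formal period end; the
start–finish graph draws a light circle on the starting and a dark circle
on the finishing content page of each session; the next-action heat map
puts the origin at the lower left so strictly linear use forms a diagonal
from the lower-left corner, warmer color meaning higher likelihood.

Rendering never mutates a view; quantitative checks belong on view data,
not pixels.  SVG output is byte-deterministic (fixed hash salt, no
embedded date) so identical inputs yield identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless; must precede pyplot import

import matplotlib.pyplot as plt
import numpy as np

from .event_model import APP_CATEGORIES
from .views import (
    NavigationTrace,
    StartFinishView,
    StripeMatrix,
    TransitionMatrix,
)

__all__ = ["RenderSpec", "render_view"]

#: alternating session hues for the navigation graph
_SESSION_COLORS = ("#1f77b4", "#d62728")
_GAP_STEPS = 2  # horizontal blank steps inserted between sessions


@dataclass(frozen=True)
class RenderSpec:
    """What to draw and where.

    ``kind`` is one of navigation / stripe / start_finish / heatmap and must
    match the view object supplied.  Width/height are in pixels at ``dpi``.
    """

    kind: str
    path: str | Path
    width: int = 1000
    height: int = 500
    dpi: int = 100
    cmap: str = "YlOrRd"  # heat map: warmer = higher probability
    period_marker_color: str = "#444444"


_VIEW_TYPES = {
    "navigation": NavigationTrace,
    "stripe": StripeMatrix,
    "start_finish": StartFinishView,
    "heatmap": TransitionMatrix,
}


def render_view(view, spec: RenderSpec) -> Path:
    """Render ``view`` per ``spec``; returns the written path.

    Output format follows the path suffix (``.png`` or ``.svg``).  An empty
    view still produces a valid image with axes and a "no data" note.
    """
    if spec.kind not in _VIEW_TYPES:
        raise ValueError(f"unknown view kind {spec.kind!r}")
    if not isinstance(view, _VIEW_TYPES[spec.kind]):
        raise ValueError(
            f"view of type {type(view).__name__} does not match kind {spec.kind!r}"
        )
    with plt.rc_context({"svg.hashsalt": "engagement-logviz"}):
        fig, ax = plt.subplots(
            figsize=(spec.width / spec.dpi, spec.height / spec.dpi), dpi=spec.dpi
        )
        try:
            _DRAWERS[spec.kind](view, ax, spec)
            fig.tight_layout()
            fig.savefig(spec.path, metadata=_metadata(Path(spec.path)))
        finally:
            plt.close(fig)
    return Path(spec.path)


def _metadata(path: Path) -> dict:
    # strip volatile creation dates so re-renders are byte-identical
    if path.suffix.lower() == ".svg":
        return {"Date": None}
    if path.suffix.lower() == ".png":
        return {"Software": "engagement-logviz"}
    return {}


def _annotate_empty(ax) -> None:
    ax.annotate(
        "no data", xy=(0.5, 0.5), xycoords="axes fraction",
        ha="center", va="center", fontsize=14, color="gray",
    )


def _draw_navigation(trace: NavigationTrace, ax, spec: RenderSpec) -> None:
    ax.set_xlabel("events in sequential order (sessions separated)")
    ax.set_ylabel("content page (intended order)")
    ax.set_title(f"Navigation graph — user {trace.user_id}" if trace.user_id else
                 "Navigation graph")
    if not trace.points:
        _annotate_empty(ax)
        return
    n_content = trace.n_content or 1
    lane_base = n_content + 1  # app lanes float above the content axis
    # displayed x: step plus a fixed gap for every session break before it
    xs: dict[int, float] = {}
    seen_sessions: list[int] = []
    for p in trace.points:
        if not seen_sessions or p.session_index != seen_sessions[-1]:
            seen_sessions.append(p.session_index)
        xs[p.step] = p.step + _GAP_STEPS * (len(seen_sessions) - 1)

    for session_index in seen_sessions:
        pts = [p for p in trace.points if p.session_index == session_index]
        color = _SESSION_COLORS[session_index % 2]
        content = [p for p in pts if p.kind == "content"]
        if content:
            ax.plot(
                [xs[p.step] for p in content],
                [p.ordinal for p in content],
                marker="o", markersize=3, linewidth=1, color=color,
            )
        feats = [p for p in pts if p.kind == "feature"]
        if feats:
            lanes = {cat: i for i, cat in enumerate(APP_CATEGORIES)}
            ax.scatter(
                [xs[p.step] for p in feats],
                [lane_base + lanes[p.category] for p in feats],
                marker="s", s=12, color=color,
            )
    for i, cat in enumerate(APP_CATEGORIES):
        ax.axhline(lane_base + i, color="0.9", linewidth=0.5, zorder=0)
    ax.set_yticks(
        list(range(0, n_content, max(1, n_content // 12)))
        + [lane_base + i for i in range(len(APP_CATEGORIES))],
        labels=[str(t) for t in range(0, n_content, max(1, n_content // 12))]
        + [c.value for c in APP_CATEGORIES],
    )


def _draw_stripe(matrix: StripeMatrix, ax, spec: RenderSpec) -> None:
    ax.set_xlabel("day of treatment period")
    ax.set_ylabel("user")
    ax.set_title("Stripe graph — days with any use")
    if not matrix.users or matrix.n_days == 0:
        _annotate_empty(ax)
        return
    for i, user in enumerate(matrix.users):
        days = np.flatnonzero(matrix.cells[i])
        ax.broken_barh([(d - 0.4, 0.8) for d in days], (i - 0.35, 0.7),
                       color="#2b6cb0")
    if matrix.period_marker < matrix.n_days:
        ax.axvline(matrix.period_marker, color=spec.period_marker_color,
                   linestyle="--", linewidth=1)
    ax.set_yticks(range(len(matrix.users)), labels=matrix.users, fontsize=7)
    ax.set_xlim(-0.6, max(matrix.n_days, matrix.period_marker + 1))
    ax.invert_yaxis()


def _draw_start_finish(view: StartFinishView, ax, spec: RenderSpec) -> None:
    ax.set_xlabel("content page (intended order)")
    ax.set_ylabel("session (sorted by finishing page)")
    ax.set_title("Start–finish graph — light start, dark end")
    if not view.rows:
        _annotate_empty(ax)
        return
    for y, row in enumerate(view.rows):
        ax.plot([row.start_ordinal, row.end_ordinal], [y, y],
                color="0.8", linewidth=0.8, zorder=1)
        ax.scatter([row.start_ordinal], [y], s=14, facecolor="#aec7e8",
                   edgecolor="#1f77b4", linewidth=0.5, zorder=2)
        ax.scatter([row.end_ordinal], [y], s=14, color="#08306b", zorder=3)
    ax.invert_yaxis()


def _draw_heatmap(matrix: TransitionMatrix, ax, spec: RenderSpec) -> None:
    ax.set_xlabel("current page")
    ax.set_ylabel("next page")
    ax.set_title("Next-action heat map")
    if matrix.counts.size == 0 or matrix.counts.sum() == 0:
        _annotate_empty(ax)
        return
    probs = matrix.probs
    # transpose: x = current page, y = next page; origin lower-left so
    # strictly linear use draws a diagonal from the lower-left corner
    im = ax.imshow(
        probs.T, origin="lower", cmap=spec.cmap, aspect="auto",
        interpolation="nearest", vmin=0.0, vmax=max(probs.max(), 1e-12),
    )
    ax.figure.colorbar(im, ax=ax, label="likelihood of next action")
    if matrix.n_content and matrix.n_content < len(matrix.labels):
        # separate the app lanes from the content block
        ax.axvline(matrix.n_content - 0.5, color="k", linewidth=0.7)
        ax.axhline(matrix.n_content - 0.5, color="k", linewidth=0.7)
    step = max(1, len(matrix.labels) // 20)
    ticks = list(range(0, len(matrix.labels), step))
    ax.set_xticks(ticks, labels=[matrix.labels[t] for t in ticks],
                  rotation=90, fontsize=6)
    ax.set_yticks(ticks, labels=[matrix.labels[t] for t in ticks], fontsize=6)


_DRAWERS = {
    "navigation": _draw_navigation,
    "stripe": _draw_stripe,
    "start_finish": _draw_start_finish,
    "heatmap": _draw_heatmap,
}
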