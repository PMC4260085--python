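# Methods

## Data model

A log row is `(user_id, timestamp, event_id)`.  Timestamps are naive local
times at minute-or-finer resolution; no timezone conversion is attempted
because intervention logs typically carry none.  The default input dialect
is day-first `DD/MM/YYYY HH:MM` (the provenance of the bundled excerpt);
ISO-8601 is accepted automatically and an explicit format can be supplied.
Within a user, events are ordered by `(timestamp, input row index)` — the
stable sort keeps the meaning of same-minute runs, which are common at
minute resolution.  An empty `event_id` is a valid identifier (the landing
page), not an error.

## Key mapping

The key file is curation, not inference: each row maps an identifier
pattern to a content label `module[.subsection[.page]]` or a feature
category.  Matching is exact-first, then longest-suffix, after stripping a
leading `/` from both sides — real logs mix `content/9/53/98/` and
`/content/9/53/98/`, and site-prefixed URLs should still resolve.  Anchor
fragments (`#content2`) are part of the pattern because distinct anchors
can denote distinct sub-pages.  Several patterns may share one label (the
same content is reachable via several URLs) and then share one ordinal.
The same app reached in-content versus standalone is distinguished only by
the key file's entries, since app URLs often do not encode their access
location.  Mapping is total: unknown identifiers become `unmapped`, are
excluded from all views, and are counted in the processing summary; a
strict mode turns them into errors.

Content ordinals are assigned by sorting the distinct labels by
`(module, subsection, page)` with absent parts first, so a module's landing
page (`2`) precedes its subsection pages (`2.0.1`, `2.1.0`, …).  Labels
carry the full triple; a `truncated()` form (`2.1`) is derived for display
rather than stored, keeping maximal information.

## Sessionization

A session is a maximal run of one user's events in which every consecutive
gap is ≤ θ; a gap **strictly greater** than θ starts a new session, so a
gap of exactly θ does not split.  Default θ = 60 minutes — deliberately
generous, making allowance for users re-watching videos or composing long
text entries; a shorter θ suits analyses where session *duration* matters
(it does not enter these views).  Sessions are computed over the full log
and may span midnight; usage days mark every calendar date touched by any
event, relative to the user's own first event because logs carry no
enrollment field (an anchor-date override exists for cohorts that have
one).

The bundled excerpt's printed session-number column disagrees with this
rule in one place (two events 3 h 52 min apart share a printed session);
the package follows the rule, and the printed column is kept in the
fixture as reference text only.

## Views

Home events and unmapped identifiers are excluded from every view; any
logged event (including Home) marks a usage day.

* **Navigation trace** — included events in order, numbered 0..n−1, each
  tagged with its session index so rendering can insert inter-session gaps.
  Consecutive duplicate labels are retained: repetition of content is
  signal.
* **Stripe matrix** — rows ordered by first-event date then user id; the
  day axis spans the largest offset in the cohort.  The period marker
  defaults to day 56 (an 8-week program); use beyond it is expected and
  worth seeing.
* **Start–finish** — per session with ≥ 1 content event, the first and last
  content event *by time* (an app between them does not move either end).
  Rows sort by (finishing module, finishing ordinal), ties broken by
  (user id, session index) so output files are reproducible.
* **Next-action matrix** — transitions are counted between consecutive
  included events **within a session**: crossing a session boundary is
  returning-after-hours, not a click, and pooling the two would conflate
  navigation with scheduling (an `across_sessions` flag includes them for
  sensitivity analysis).  Counts are pooled over users rather than averaged
  per user — the pooled matrix answers "what does the next click look like
  in this cohort's traffic"; per-user averaging would weight a two-session
  user like a sixty-session one.  Self-transitions sit on the diagonal by
  default; `collapse_repeats` merges consecutive duplicates first.  Both
  analyses are legitimate and the default is the more literal one.  The
  five app categories join the axes as indices K..K+4 (category-level, not
  per-app-instance), in the fixed documented order Exercise, Mindfulness,
  Journal, Review, Other.

Row-normalization maps counts to empirical likelihoods; zero rows stay
zero rather than becoming uniform, so unvisited pages are visibly empty.

## Rendering

All quantitative content lives in the view tables; figures are a faithful
drawing of them and assertions are made on view data, never pixels.  The
heat map is drawn with its origin at the lower left so strictly linear use
forms a diagonal from the lower-left corner, warmer color meaning higher
likelihood.  Navigation sessions alternate between two hues rather than a
per-session palette, which stays legible for users with many dozens of
sessions.  SVG output fixes the hash salt and omits the creation date, so
identical inputs produce byte-identical files.  The interactive affordances
of an exploratory tool (cursor, zoom, details-on-demand) are out of scope;
SVG element identity is preserved for downstream tooling.

## Synthetic cohorts

The generator emulates the features of real intervention logs that the
views depend on: content organized into ordered modules, interleaved app
events, inactivity-separated sessions, and heterogeneous usage styles.
Defaults (chosen once as a realistic mid-size program):

| parameter | default | meaning |
|---|---|---|
| `n_modules` | 8 | modules 0–7: intro module 0, review/optional at the end |
| `subsections_per_module` × `pages_per_subsection` | 3 × 3 | plus a landing page → K = 80 content pages |
| `period_days` | 70 | longer than the 56-day formal period |
| `sessions_per_week` | 3.0 | per user, ±30% user-level jitter |
| `session_length_range` | (4, 12) | content+app events per session |
| `app_events_per_session` | 2.0 | Poisson mean (app-focused users override) |
| archetype mix | 0.35 / 0.25 / 0.20 / 0.20 | linear / repeater / app-focused / burst |

Archetypes: *linear completers* emit content in strictly increasing ordinal
order and stop when the program is done; *repeaters* progress forward but
replay earlier chunks (probability 0.4 per session); *app-focused* users
emit ≥ 70 % feature events with sparse nonlinear content visits; *burst
users* cluster sessions in 2–4-day runs separated by ≥ 7 quiet days.
Within-session gaps are drawn from 0–5 min and between-session gaps from
≥ 90 min — both bounded away from the 60-minute threshold — so
sessionization recovers the generated boundaries *exactly*, and the
recovery tests can demand 100 % agreement instead of a tolerance.
Timestamps are emitted at minute resolution to match the fidelity of the
target logs.

What the generator does **not** emulate: unmapped/malformed URLs (rate
zero by default), timezone or clock anomalies, platform-specific URL
schemes, and any calibration to real cohorts (no real per-user parameters
were available to fit).  Passing the recovery tests therefore shows the
pipeline is exact on well-formed logs with separable sessions; it does not
certify behavior on logs whose true inter-action gaps straddle the
threshold, where sessionization is definitionally sensitive to θ.

## Numerical and degenerate-input choices

Probabilities compare exactly against 1 within 1e−9 in the matrix-law
tests (row sums are ratios of small integers; the tolerance absorbs only
float division).  Empty inputs flow through: an empty log yields empty
views, which render as valid images annotated "no data".  Unsorted input
to the sessionizer is an error rather than silently re-sorted, because
ingestion already sorts and a caller-supplied unsorted sequence indicates
a bug upstream.  Ties everywhere break on stable, documented keys so that
re-running the pipeline reproduces files byte-for-byte.

## Problem sizes used in the checks

The bundled excerpt is one user and 63 events.  The property suites use
1,000 random streams of ≤ 40 events for the sessionizer oracle, five
50-user synthetic cohorts (~15–20 k events each) for ground-truth
recovery, and a 30-user cohort for the transition-matrix laws — sizes at
which the brute-force oracles are unambiguous and the full suite runs in
seconds.
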