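"""Compute the four visualization-backing tables from the bundled log.

Each view is a small table that can be written to CSV with
``write_view_table`` and inspected before rendering: the navigation trace
(one user's content/app events in order), the stripe calendar (used days),
the start-finish rows (first and last content page per session), and the
next-action transition matrix (content ordinals plus five app lanes).
"""

import engagement_logviz as elv

stream = elv.read_log(elv.example_log_path())
key = elv.parse_key_file(elv.example_key_path())
labeled, _ = elv.label_stream(stream, key)
cohort = elv.sessionize(labeled)

trace = elv.navigation_view(cohort["8"], n_content=key.n_content)
print(f"navigation trace: {len(trace.points)} points (Home events excluded)")
print("  first content labels:",
      [p.label for p in trace.points if p.kind == "content"][:5])

stripe = elv.stripe_view(cohort)
print(f"stripe matrix: {len(stripe.users)} user(s) x {stripe.n_days} day(s), "
      f"{int(stripe.cells.sum())} used day-cells")

sf = elv.start_finish_view(cohort)
for row in sf.rows:
    print(f"start-finish: session {row.session_index} went "
          f"{row.start_label} -> {row.end_label}")

tm = elv.next_action_view(cohort, key.n_content, key.content_labels)
print(f"next-action matrix: {tm.counts.shape[0]}x{tm.counts.shape[1]} "
      f"({key.n_content} content + 5 app lanes), {tm.counts.sum()} transitions")
i = key.ordinal(elv.ContentLabel.parse("2.2.0"))
j = key.ordinal(elv.ContentLabel.parse("2.2.1"))
print(f"  P(next=2.2.1 | current=2.2.0) = {tm.probs[i, j]:.2f}")
# Row-normalized counts: a strictly linear reader would put probability 1
# on every one-off diagonal cell (i, i+1).
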