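"""Map a raw click log to labels and split it into sessions.

Loads the bundled single-session excerpt (one user, 63 events), maps every
URL through the key file, and sessionizes with the default 60-minute
inactivity threshold.  The printed numbers are the event count, how many
events are content pages vs features, and the session boundaries the
threshold rule produces.
"""

import engagement_logviz as elv

stream = elv.read_log(elv.example_log_path())
key = elv.parse_key_file(elv.example_key_path())
labeled, summary = elv.label_stream(stream, key)
cohort = elv.sessionize(labeled)

print(f"events: {stream.n_events}, users: {len(stream.users)}")
print(f"distinct content pages in key: {key.n_content}")
kinds: dict[str, int] = {}
for ev in labeled["8"]:
    name = "content" if ev.assignment.kind == "content" else str(ev.assignment)
    kinds[name] = kinds.get(name, 0) + 1
print(f"assignment counts: {dict(sorted(kinds.items()))}")
print(f"unmapped identifiers: {summary.n_unmapped}")
for session in cohort["8"]:
    print(
        f"session {session.session_index}: {len(session.events)} events, "
        f"{session.start_time:%H:%M} - {session.end_time:%H:%M}"
    )
# A >60-minute pause splits the afternoon from the lunchtime activity:
# repeated interaction within a session, inactivity between sessions.
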