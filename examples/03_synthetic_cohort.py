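"""Generate a synthetic cohort and verify the pipeline recovers its truth.

The generator emits multi-week logs for four usage archetypes with known
session boundaries (gaps constructed strictly on either side of the
60-minute threshold), then the ordinary pipeline — mapping, sessionization,
views — is run on the raw log and compared against that ground truth.
"""

import engagement_logviz as elv

config = elv.SyntheticCohortConfig(n_users=20, seed=42)
stream, key, truth = elv.generate_cohort(config)
print(f"generated {stream.n_events} events for {len(stream.users)} users "
      f"over a {config.period_days}-day period")

by_archetype = {}
for gt in truth.users.values():
    by_archetype[gt.archetype] = by_archetype.get(gt.archetype, 0) + 1
print("archetype mix:", dict(sorted(by_archetype.items())))

labeled, _ = elv.label_stream(stream, key)
cohort = elv.sessionize(labeled)

recovered = 0
for user, sessions in cohort.items():
    gt = truth.users[user]
    events = [ev for s in sessions for ev in s.events]
    ok = (
        [len(s.events) for s in sessions] == gt.session_sizes
        and elv.usage_days(events) == gt.usage_days
    )
    recovered += ok
print(f"session boundaries + usage days recovered exactly: "
      f"{recovered}/{len(cohort)} users")

sessions_per_user = sum(len(s) for s in cohort.values()) / len(cohort)
print(f"mean sessions per user: {sessions_per_user:.1f}")
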