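"""Simulate a two-group go/stop cohort and look at the raw trial table.

Builds the default cohort — a high-bias arm (starting point z = 0.43) and
a control arm (z = 0.30), 15 subjects each, five blocks of 30 go + 10 stop
trials — and prints the first rows plus per-group trial counts. The rt_ms
column is the response time from motion onset; the collision the subject
is timing happens at 1000 ms, so go RTs below 1000 are early predictions.
"""

from stopddm import SessionConfig, default_group_specs, simulate_cohort

trials = simulate_cohort(default_group_specs(), SessionConfig(), seed=1)

print(trials.head(8).to_string(index=False))
print()
print("trials per group and type:")
print(trials.groupby(["group", "type"]).size().unstack())
print()
print("mean go RT (ms) by group — the high-bias arm responds earlier:")
print(trials.loc[trials["type"] == "go"].groupby("group")["rt_ms"].mean().round(1))
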