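"""Race-model and temporal-estimation statistics on a simulated cohort.

Applies the RT exclusion window (go RTs outside [0, 1250] ms dropped),
computes per-subject race summaries — mean go RT, SSD50 (mean presented
stop-signal delay, which the 1-up/1-down staircase drives to the
50%-response point), mean-method SSRT = mean RT_go - SSD50, inhibition
accuracy — and the Table-style group aggregate. The high-bias arm should
show shorter go RTs, larger absolute temporal estimation errors (|RT -
1000 ms|) and a smaller SSD50.
"""

import json

from stopddm import (
    SessionConfig,
    default_group_specs,
    exclusion_filter,
    group_summary,
    simulate_cohort,
    summarize_subjects,
    two_sample_t,
)

trials = simulate_cohort(default_group_specs(), SessionConfig(), seed=1)
kept, log = exclusion_filter(trials)
print(f"excluded {log['n_excluded_slow']} slow and {log['n_excluded_fast']} "
      f"fast go trials of {log['n_go']}")

race = summarize_subjects(kept)
print("\nper-subject summaries (first rows):")
print(race.head(4).round(1).to_string(index=False))

summary = group_summary(kept)
print("\ngroup aggregate, mean (SD):")
print(json.dumps(summary, indent=2))

# two-stage group comparison of SSD50 (subject means -> Welch t)
g = race.groupby("group")["ssd50"]
(m1, s1, n1), (m2, s2, n2) = [
    (v.mean(), v.std(ddof=1), v.size) for _, v in g
]
t = two_sample_t(m1, s1, n1, m2, s2, n2)
print(f"\nSSD50 group difference: t = {t.statistic:.2f}, df = {t.df:.2f} "
      "(two-stage subject-mean Welch test)")
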