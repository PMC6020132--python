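"""The 1-up/1-down staircase converges on the 50%-response delay.

Simulates a long run of stop trials for a single subject. After a burn-in,
the symmetric fixed-step staircase balances signal-respond and signal-stop
trials, so the proportion of responses approaches 50% and the mean
presented SSD estimates the subject's SSD50. The mean-method stop-signal
reaction time is then mean go RT minus that SSD50.
"""

import numpy as np

from stopddm import (
    DDMParams,
    SessionConfig,
    SubjectParams,
    mean_rt,
    simulate_session,
    ssrt_mean_method,
)

subject = SubjectParams(
    ddm=DDMParams(a=8.86, z=0.43, v=8.48, t=0.28),
    ssrt_mean_ms=300.0,
    ssrt_sd_ms=50.0,
)
config = SessionConfig(n_blocks=200, go_per_block=0, stop_per_block=50)
trials = simulate_session(subject, config, np.random.default_rng(1))

stops = trials.loc[trials["type"] == "stop"].iloc[500:]
pct_respond = 100 * (stops["outcome"] == "signal-respond").mean()
ssd50 = stops["ssd_ms"].mean()
go_ms = 1000 * mean_rt(subject.ddm)

print(f"stop trials simulated: {len(stops)} (after discarding 500)")
print(f"signal-respond rate:   {pct_respond:.1f}%  (staircase target: 50%)")
print(f"mean presented SSD:    {ssd50:.1f} ms  (the SSD50 estimate)")
print(f"mean go RT:            {go_ms:.1f} ms (closed form)")
print(f"mean-method SSRT:      {ssrt_mean_method(go_ms, ssd50):.1f} ms "
      f"(generating stop latency: ~300 ms)")
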