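"""Race-model summaries: SSD50, mean-method SSRT, inhibition accuracy.

Under the independent horse-race account, a stop trial ends in successful
inhibition iff the go process' latency exceeds ``SSD + SSRT``. The 1-up/
1-down staircase drives the presented SSD to the delay at which the subject
responds on half the stop trials (SSD50); the mean method then estimates
the covert stop latency as ``SSRT = mean RT_go - SSD50``.

All quantities here are in milliseconds and computed per subject from the
standard trial table; exclusion of aberrant go RTs is expected to have
happened upstream (see :func:`stopddm.behavioral.exclusion_filter`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RaceSummary",
    "ssd50",
    "ssrt_mean_method",
    "inhibition_accuracy",
    "context_independence_check",
    "rt_trend_slope",
    "summarize_subjects",
]


@dataclass(frozen=True)
class RaceSummary:
    """Per-subject race-model summary (times in ms)."""

    subject: str
    group: str
    mean_rt_go: float
    mean_rt_signal_respond: float
    ssd50: float
    ssrt: float
    inhibition_accuracy: float
    skewness_rt_go: float
    rt_trend_slope: float
    n_go_used: int
    n_stop: int


def ssd50(stop_trials: pd.DataFrame, reversals_only: bool = False) -> float:
    """Staircase estimate of the 50%-response SSD for one subject.

    The default is the arithmetic mean of the presented SSDs over all
    experimental stop trials. With ``reversals_only`` the mean is taken
    over staircase reversal points (trials where the staircase changed
    direction) instead. Returns NaN if there are no usable trials.
    """
    ssds = stop_trials.loc[stop_trials["type"] == "stop", "ssd_ms"].to_numpy(float)
    if ssds.size == 0:
        return float("nan")
    if reversals_only:
        if ssds.size < 3:
            return float("nan")
        steps = np.sign(np.diff(ssds))
        rev = np.flatnonzero((steps[:-1] != 0) & (steps[1:] != 0) & (steps[:-1] != steps[1:]))
        if rev.size == 0:
            return float("nan")
        return float(np.mean(ssds[rev + 1]))
    return float(np.mean(ssds))


def ssrt_mean_method(mean_rt_go: float, ssd50_ms: float) -> float:
    """Mean-method stop-signal reaction time: ``mean RT_go - SSD50`` (ms)."""
    return mean_rt_go - ssd50_ms


def inhibition_accuracy(stop_trials: pd.DataFrame) -> float:
    """Fraction of stop trials ending in successful inhibition (signal-stop)."""
    st = stop_trials.loc[stop_trials["type"] == "stop"]
    if len(st) == 0:
        return float("nan")
    return float((st["outcome"] == "signal-stop").mean())


def context_independence_check(trials: pd.DataFrame) -> dict:
    """Compare signal-respond and go RT means for one subject.

    The race model predicts the signal-respond RT distribution is the go
    RT distribution censored from above, hence its mean is smaller. Reports
    both means, their difference (go minus signal-respond), and a flag that
    is True when the prediction holds. Means are NaN when either side has
    no responded trials.
    """
    go = trials.loc[
        (trials["type"] == "go") & trials["responded"], "rt_ms"
    ].to_numpy(float)
    sr = trials.loc[trials["outcome"] == "signal-respond", "rt_ms"].to_numpy(float)
    if go.size == 0 or sr.size == 0:
        return {
            "mean_rt_go": float("nan"),
            "mean_rt_signal_respond": float("nan"),
            "difference": float("nan"),
            "signal_respond_faster": None,
        }
    m_go, m_sr = float(np.mean(go)), float(np.mean(sr))
    return {
        "mean_rt_go": m_go,
        "mean_rt_signal_respond": m_sr,
        "difference": m_go - m_sr,
        "signal_respond_faster": bool(m_sr < m_go),
    }


def rt_trend_slope(go_trials: pd.DataFrame) -> float:
    """OLS slope of go RT on trial number (ms per trial) for one subject.

    A stability check for the mean method: the estimate is unreliable when
    go RT drifts across the session.
    """
    g = go_trials.loc[(go_trials["type"] == "go") & go_trials["responded"]]
    if len(g) < 3:
        return float("nan")
    res = stats.linregress(g["trial"].to_numpy(float), g["rt_ms"].to_numpy(float))
    return float(res.slope)


def summarize_subjects(trials: pd.DataFrame, reversals_only: bool = False) -> pd.DataFrame:
    """Per-subject race summaries over a (filtered) trial table.

    Go-trial statistics use responded go trials only; skewness is the
    adjusted Fisher–Pearson standardized third moment.
    """
    rows = []
    for (sid, grp), sub in trials.groupby(["subject", "group"], sort=True):
        go = sub.loc[(sub["type"] == "go") & sub["responded"], "rt_ms"].to_numpy(float)
        mean_go = float(np.mean(go)) if go.size else float("nan")
        s50 = ssd50(sub, reversals_only=reversals_only)
        cic = context_independence_check(sub)
        rows.append(
            RaceSummary(
                subject=sid,
                group=grp,
                mean_rt_go=mean_go,
                mean_rt_signal_respond=cic["mean_rt_signal_respond"],
                ssd50=s50,
                ssrt=ssrt_mean_method(mean_go, s50),
                inhibition_accuracy=inhibition_accuracy(sub),
                skewness_rt_go=float(stats.skew(go, bias=False)) if go.size > 2 else float("nan"),
                rt_trend_slope=rt_trend_slope(sub),
                n_go_used=int(go.size),
                n_stop=int((sub["type"] == "stop").sum()),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
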