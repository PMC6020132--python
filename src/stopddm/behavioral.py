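"""Temporal-estimation error, trial exclusion, group summaries and t-tests.

The temporal estimation error (TEE) of a go response is the response time
minus the collision time; a response is *early* when TEE <= 0 ms (the
boundary counts as early). Group comparisons here are two-stage: per-trial
or per-subject quantities are aggregated to subject means, and groups are
compared with ordinary two-sample statistics. Full mixed-effects
regressions with subject random effects are deliberately not fitted; the
two-stage route reproduces the same fixed-effect directions and is labelled
as such in every report this module emits.

p-values are not computed: the statistics and degrees of freedom carry all
the implementable content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .race import summarize_subjects

__all__ = [
    "TestResult",
    "compute_tee",
    "add_tee",
    "exclusion_filter",
    "two_sample_t",
    "paired_t",
    "group_summary",
]

#: Go trials outside this RT window (ms) are excluded before analysis.
RT_MAX_MS = 1250.0
RT_MIN_MS = 0.0


@dataclass(frozen=True)
class TestResult:
    """A t statistic with its degrees of freedom and input summaries."""

    statistic: float
    df: float
    variant: str  # 'welch' | 'pooled' | 'paired'
    m1: float
    sd1: float
    n1: int
    m2: float
    sd2: float
    n2: int


def compute_tee(rt_ms: float, collision_time_ms: float = 1000.0) -> tuple[float, str]:
    """TEE of one response and its sign ('early' iff TEE <= 0 ms)."""
    tee = rt_ms - collision_time_ms
    return tee, ("early" if tee <= 0 else "late")


def add_tee(trials: pd.DataFrame, collision_time_ms: float = 1000.0) -> pd.DataFrame:
    """Return a copy with ``tee_ms`` and ``sign`` columns on responded go trials."""
    out = trials.copy()
    out["tee_ms"] = np.nan
    out["sign"] = pd.NA
    mask = (out["type"] == "go") & out["responded"]
    out.loc[mask, "tee_ms"] = out.loc[mask, "rt_ms"] - collision_time_ms
    out.loc[mask, "sign"] = np.where(out.loc[mask, "tee_ms"] <= 0, "early", "late")
    return out


def exclusion_filter(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop go trials with RT > 1250 ms or RT < 0 ms; keep everything else.

    Bounds are strict (RT exactly 1250 or 0 ms is retained). Returns the
    retained table (a new frame; the input is never mutated) and a log of
    counts and proportions, overall and per group.
    """
    is_go = (trials["type"] == "go") & trials["responded"]
    too_slow = is_go & (trials["rt_ms"] > RT_MAX_MS)
    too_fast = is_go & (trials["rt_ms"] < RT_MIN_MS)
    drop = too_slow | too_fast
    n_go = int(is_go.sum())
    log = {
        "n_go": n_go,
        "n_excluded_slow": int(too_slow.sum()),
        "n_excluded_fast": int(too_fast.sum()),
        "prop_excluded_slow": float(too_slow.sum() / n_go) if n_go else 0.0,
        "prop_excluded_fast": float(too_fast.sum() / n_go) if n_go else 0.0,
        "per_group": {},
    }
    for grp, sub in trials.groupby("group", sort=True):
        g_go = (sub["type"] == "go") & sub["responded"]
        n = int(g_go.sum())
        log["per_group"][grp] = {
            "n_go": n,
            "n_excluded_slow": int((g_go & (sub["rt_ms"] > RT_MAX_MS)).sum()),
            "n_excluded_fast": int((g_go & (sub["rt_ms"] < RT_MIN_MS)).sum()),
        }
    return trials.loc[~drop].reset_index(drop=True), log


def two_sample_t(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int,
    variant: str = "welch",
) -> TestResult:
    """Two-sample t statistic from group summaries.

    ``welch`` uses the unpooled standard error with Welch–Satterthwaite
    degrees of freedom; ``pooled`` the classical equal-variance statistic
    with ``n1 + n2 - 2`` df. With zero variance in both groups the
    statistic is 0 when the means agree and undefined (raises) otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        if m1 == m2:
            df = n1 + n2 - 2
            return TestResult(0.0, float(df), variant, m1, sd1, n1, m2, sd2, n2)
        raise ValueError("zero variance in both groups with unequal means")
    if variant == "welch":
        se2_1, se2_2 = sd1**2 / n1, sd2**2 / n2
        se2 = se2_1 + se2_2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1))
    elif variant == "pooled":
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return TestResult(float(t), float(df), variant, m1, sd1, n1, m2, sd2, n2)


def paired_t(x, y) -> TestResult:
    """Paired t on matched subject means (df = n - 1)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired samples must match in length (>= 2)")
    d = x - y
    sd = float(np.std(d, ddof=1))
    n = d.size
    if sd == 0:
        t = 0.0 if np.mean(d) == 0 else np.inf * np.sign(np.mean(d))
    else:
        t = float(np.mean(d) / (sd / np.sqrt(n)))
    return TestResult(
        t, float(n - 1), "paired",
        float(np.mean(x)), float(np.std(x, ddof=1)), n,
        float(np.mean(y)), float(np.std(y, ddof=1)), n,
    )


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    if x.size == 0:
        return float("nan"), float("nan")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return float(np.mean(x)), sd


def group_summary(
    trials: pd.DataFrame, collision_time_ms: float = 1000.0
) -> dict:
    """Per-group aggregate of the headline task statistics.

    Expects a filtered trial table. Absolute TEE, go RT, signal-respond RT
    and inhibition accuracy are summarized over trials; SSD50 and SSRT over
    subjects (one mean-method value per subject). Values are
    ``[mean, sd]`` pairs; accuracy is in percent. Groups with no subjects
    are omitted.
    """
    out: dict = {"method": "two-stage subject-mean analysis (no mixed-effects model)"}
    summaries = summarize_subjects(trials)
    for grp, sub in trials.groupby("group", sort=True):
        go_rt = sub.loc[(sub["type"] == "go") & sub["responded"], "rt_ms"].to_numpy(float)
        sr_rt = sub.loc[sub["outcome"] == "signal-respond", "rt_ms"].to_numpy(float)
        stop = sub.loc[sub["type"] == "stop"]
        inhibited = (stop["outcome"] == "signal-stop").to_numpy(float) * 100.0
        per_subj = summaries.loc[summaries["group"] == grp]
        entry = {
            "Abs TEE ms": _mean_sd(np.abs(go_rt - collision_time_ms)),
            "RT_go ms": _mean_sd(go_rt),
            "RT_Signal-Respond ms": _mean_sd(sr_rt),
            "Inhibition accuracy %": _mean_sd(inhibited),
            "SSD_50 ms": _mean_sd(per_subj["ssd50"].to_numpy(float)),
            "SSRT ms": _mean_sd(per_subj["ssrt"].to_numpy(float)),
            "n_subjects": int(per_subj.shape[0]),
        }
        out[grp] = entry
    return out
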