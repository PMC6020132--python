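"""Synthetic two-group cohorts for the temporal-prediction stop-signal task.

The task: a moving disc collides with a stationary one 1000 ms after motion
onset; on go trials the subject presses a key at the predicted collision
moment, and on stop trials a colour change presented at the stop-signal
delay (SSD) instructs withholding. The SSD follows a symmetric 1-up/1-down
staircase (default step 30 ms): up after a successful stop, down after a
failed one, which tracks the delay at which the subject responds on 50% of
stop trials.

Generative structure per subject:

* go process — one-choice diffusion (:mod:`stopddm.ddm`); the go RT is
  drawn on every trial, stop or not, so context independence holds by
  construction;
* stop process — a latency (SSRT) drawn per stop trial from a normal
  distribution truncated at zero;
* race rule — the response is inhibited iff ``rt_go > ssd + ssrt``
  (ties respond).

Internally the diffusion runs in seconds; the trial table and every config
field that describes the task timeline are in milliseconds. The conversion
happens exactly once, where a sampled RT enters a trial record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ddm import DDMParams, sample_rts

__all__ = [
    "GroupSpec",
    "SessionConfig",
    "SubjectParams",
    "TABLE_COLUMNS",
    "draw_subject",
    "simulate_stop_trial",
    "simulate_session",
    "simulate_cohort",
    "default_group_specs",
    "write_trial_table",
    "read_trial_table",
]

#: Column schema of the standard trial table (tab-separated on disk).
TABLE_COLUMNS = [
    "subject",
    "group",
    "block",
    "trial",
    "type",
    "ssd_ms",
    "responded",
    "rt_ms",
    "outcome",
]


@dataclass(frozen=True)
class GroupSpec:
    """Group-level generating distributions for one cohort arm.

    DDM fields are means and between-subject SDs on the scales of
    :class:`~stopddm.ddm.DDMParams` (``t`` in seconds); the stop-process
    latency distribution is in milliseconds and is shared by all subjects
    of the group (its SD is trial-to-trial variability).
    """

    label: str
    n_subjects: int = 15
    a_mean: float = 8.86
    a_sd: float = 1.0
    z_mean: float = 0.43
    z_sd: float = 0.12
    v_mean: float = 8.48
    v_sd: float = 0.2
    t_mean: float = 0.28
    t_sd: float = 0.05
    ssrt_mean_ms: float = 300.0
    ssrt_sd_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("a_sd", "z_sd", "v_sd", "t_sd", "ssrt_sd_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        # means must sit inside the parameter domains
        DDMParams(self.a_mean, self.z_mean, self.v_mean, self.t_mean)
        if self.ssrt_mean_ms <= 0:
            raise ValueError("ssrt_mean_ms must be positive")


@dataclass(frozen=True)
class SessionConfig:
    """Task structure of one experimental session (all times in ms)."""

    n_blocks: int = 5
    go_per_block: int = 30
    stop_per_block: int = 10
    staircase_step_ms: float = 30.0
    initial_ssd_ms: float = 500.0
    ssd_min_ms: float = 30.0
    ssd_max_ms: float = 2400.0
    collision_time_ms: float = 1000.0
    response_deadline_ms: float = 2700.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.staircase_step_ms < 0:
            raise ValueError("staircase_step_ms must be >= 0")
        if not (0 < self.collision_time_ms < self.response_deadline_ms):
            raise ValueError("collision_time_ms must lie in (0, response_deadline_ms)")
        if not (0 < self.ssd_min_ms <= self.ssd_max_ms < self.response_deadline_ms):
            raise ValueError("ssd bounds must satisfy 0 < min <= max < deadline")
        if not (self.ssd_min_ms <= self.initial_ssd_ms <= self.ssd_max_ms):
            raise ValueError("initial_ssd_ms must lie within the ssd bounds")


@dataclass(frozen=True)
class SubjectParams:
    """One simulated subject: go-process DDM plus stop-process latency."""

    ddm: DDMParams
    ssrt_mean_ms: float
    ssrt_sd_ms: float


# (lower, upper) domains for the truncated-normal subject draws
_DOMAINS = {
    "a": (0.0, np.inf),
    "z": (0.0, 1.0),
    "v": (0.0, np.inf),
    "t": (0.0, np.inf),
}


def _truncnorm_draw(mean: float, sd: float, lo: float, hi: float, rng) -> float:
    if sd == 0.0:
        if not (lo <= mean <= hi):
            raise ValueError(f"degenerate draw: mean {mean} outside [{lo}, {hi}]")
        return mean
    alpha, beta = (lo - mean) / sd, (hi - mean) / sd
    mass = stats.norm.cdf(beta) - stats.norm.cdf(alpha)
    if mass < 1e-6:
        raise ValueError(
            f"truncated-normal mass {mass:.2e} below 1e-6: mean {mean} lies far "
            f"outside [{lo}, {hi}]"
        )
    return float(stats.truncnorm.rvs(alpha, beta, loc=mean, scale=sd, random_state=rng))


def truncnorm_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Mean of a normal truncated to [lo, hi] (used as a test oracle)."""
    if sd == 0.0:
        return mean
    alpha, beta = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.mean(alpha, beta, loc=mean, scale=sd))


def draw_subject(spec: GroupSpec, seed=None) -> SubjectParams:
    """Draw one subject's parameters from the group's generating distributions.

    Each DDM parameter is drawn from a normal truncated to its domain;
    boundary values on open intervals are nudged inward so the resulting
    :class:`DDMParams` is always valid. ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = {}
    for name in ("a", "z", "v", "t"):
        lo, hi = _DOMAINS[name]
        x = _truncnorm_draw(
            getattr(spec, f"{name}_mean"), getattr(spec, f"{name}_sd"), lo, hi, rng
        )
        vals[name] = x
    # open-interval guards (probability-zero events, but keep the type valid)
    tiny = 1e-9
    vals["a"] = max(vals["a"], tiny)
    vals["v"] = max(vals["v"], tiny)
    vals["z"] = min(max(vals["z"], tiny), 1.0 - tiny)
    return SubjectParams(
        ddm=DDMParams(**vals),
        ssrt_mean_ms=spec.ssrt_mean_ms,
        ssrt_sd_ms=spec.ssrt_sd_ms,
    )


def _draw_ssrt_ms(subject: SubjectParams, rng) -> float:
    if subject.ssrt_sd_ms == 0.0:
        return subject.ssrt_mean_ms
    alpha = (0.0 - subject.ssrt_mean_ms) / subject.ssrt_sd_ms
    return float(
        stats.truncnorm.rvs(
            alpha, np.inf, loc=subject.ssrt_mean_ms, scale=subject.ssrt_sd_ms,
            random_state=rng,
        )
    )


def simulate_stop_trial(subject: SubjectParams, ssd_ms: float, rng) -> dict:
    """Run the race on one stop trial at the given SSD.

    The go RT and the stop latency are drawn independently; the response is
    inhibited iff ``rt_go > ssd + ssrt`` (a tie counts as responding). The
    returned record has ``outcome`` 'signal-stop' (no RT) or
    'signal-respond' (RT equal to the go RT that escaped inhibition).
    """
    rt_go_ms = 1000.0 * float(sample_rts(subject.ddm, 1, rng)[0])
    ssrt_ms = _draw_ssrt_ms(subject, rng)
    inhibited = rt_go_ms > ssd_ms + ssrt_ms
    return {
        "type": "stop",
        "ssd_ms": ssd_ms,
        "responded": not inhibited,
        "rt_ms": None if inhibited else rt_go_ms,
        "outcome": "signal-stop" if inhibited else "signal-respond",
    }


def simulate_session(
    subject: SubjectParams,
    config: SessionConfig,
    rng,
    subject_id: str = "s01",
    group: str = "group",
) -> pd.DataFrame:
    """Simulate one subject's session as a trial-table DataFrame.

    Stop trials occupy random positions within each block; the staircase
    SSD is carried across blocks, moved one step up after each signal-stop
    and one step down after each signal-respond, clamped to the bounds.
    Overlong go RTs are recorded as-is — exclusion is a downstream step.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = []
    ssd = float(config.initial_ssd_ms)
    trial_no = 0
    per_block = config.go_per_block + config.stop_per_block
    for block in range(1, config.n_blocks + 1):
        stop_pos = set(
            rng.choice(per_block, size=config.stop_per_block, replace=False).tolist()
        )
        for pos in range(per_block):
            trial_no += 1
            if pos in stop_pos:
                rec = simulate_stop_trial(subject, ssd, rng)
                if rec["outcome"] == "signal-stop":
                    ssd = min(ssd + config.staircase_step_ms, config.ssd_max_ms)
                else:
                    ssd = max(ssd - config.staircase_step_ms, config.ssd_min_ms)
            else:
                rt_ms = 1000.0 * float(sample_rts(subject.ddm, 1, rng)[0])
                rec = {
                    "type": "go",
                    "ssd_ms": None,
                    "responded": True,
                    "rt_ms": rt_ms,
                    "outcome": "go",
                }
            rows.append(
                {
                    "subject": subject_id,
                    "group": group,
                    "block": block,
                    "trial": trial_no,
                    **rec,
                }
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def simulate_cohort(
    specs: list[GroupSpec], config: SessionConfig, seed: int | None = None
) -> pd.DataFrame:
    """Simulate all groups into one trial table with unique subject ids.

    Fully reproducible from ``(specs, config, seed)``; ``seed`` overrides
    ``config.seed`` when given. Per-subject RNG streams are spawned from
    the master seed so subjects are independent.
    """
    if len(specs) < 1:
        raise ValueError("at least one GroupSpec is required")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate group labels: {labels}")
    master = seed if seed is not None else config.seed
    ss = np.random.SeedSequence(master)
    n_total = sum(s.n_subjects for s in specs)
    children = ss.spawn(n_total)
    frames = []
    k = 0
    for spec in specs:
        for j in range(spec.n_subjects):
            rng = np.random.default_rng(children[k])
            k += 1
            subj = draw_subject(spec, rng)
            sid = f"{spec.label}-{j + 1:02d}"
            frames.append(simulate_session(subj, config, rng, sid, spec.label))
    return pd.concat(frames, ignore_index=True)


def default_group_specs() -> list[GroupSpec]:
    """The default two-arm cohort: a high-bias arm and a control arm.

    The arms share threshold, drift and non-decision time; the contrast is
    carried by the relative starting point z (0.43 vs 0.30), which makes
    the high-bias arm respond earlier and tolerate shorter stop-signal
    delays. Stop latencies differ slightly (309 vs 276 ms means).
    """
    return [
        GroupSpec(label="SZ", z_mean=0.43, ssrt_mean_ms=308.7),
        GroupSpec(label="control", z_mean=0.30, ssrt_mean_ms=275.84),
    ]


def write_trial_table(df: pd.DataFrame, path) -> None:
    """Write the standard tab-separated trial table (empty = missing)."""
    out = df.copy()
    out["responded"] = out["responded"].astype(bool).astype(int)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trial_table`."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"subject": str, "group": str, "type": str, "outcome": str},
    )
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    df["responded"] = df["responded"].astype(bool)
    return df[TABLE_COLUMNS]
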