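"""End-to-end pipeline: simulate -> validate -> filter -> analyze -> fit.

A run is driven by a :class:`RunConfig` (optionally loaded from a YAML
file) and writes every artifact into one output directory: the trial
table, the exclusion log, per-subject race summaries, the group aggregate
(JSON and markdown), the model-comparison table, the winning model's
posterior trace in long format, and a plain-text log recording the master
seed, library versions, per-stage counts and artifact checksums. Stage
seeds are spawned from the master seed with ``numpy.random.SeedSequence``,
so every stage is independently reproducible and no stage mutates an
upstream file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavioral import exclusion_filter, group_summary, paired_t, two_sample_t
from .cohort import (
    GroupSpec,
    SessionConfig,
    default_group_specs,
    read_trial_table,
    simulate_cohort,
    write_trial_table,
)
from .hierarchical import MCMCConfig, ModelSpec, compare_models, posterior_proportion
from .race import summarize_subjects

__all__ = ["RunConfig", "load_config", "run_pipeline", "validate_table", "render_report"]


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    seed: int = 0
    outdir: str = "stopddm-run"
    groups: list[GroupSpec] = field(default_factory=default_group_specs)
    session: SessionConfig = field(default_factory=SessionConfig)
    mcmc: MCMCConfig = field(default_factory=lambda: MCMCConfig(n_chains=2))
    models: tuple[int, ...] = (1, 2, 3, 4)
    fit_models: bool = True


def load_config(path) -> RunConfig:
    """Load a RunConfig from a flat YAML file (missing blocks use defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "outdir" in raw:
        kwargs["outdir"] = str(raw["outdir"])
    if "groups" in raw:
        kwargs["groups"] = [GroupSpec(**g) for g in raw["groups"]]
    if "session" in raw:
        kwargs["session"] = SessionConfig(**raw["session"])
    if "mcmc" in raw:
        kwargs["mcmc"] = MCMCConfig(**raw["mcmc"])
    if "models" in raw:
        kwargs["models"] = tuple(int(m) for m in raw["models"])
    if "fit_models" in raw:
        kwargs["fit_models"] = bool(raw["fit_models"])
    return RunConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_table(path) -> dict:
    """Schema check of a trial table; returns per-rule violation counts."""
    report = {"path": str(path), "valid": False, "violations": {}}
    try:
        df = read_trial_table(path)
    except Exception as exc:  # unreadable or missing columns
        report["error"] = str(exc)
        return report
    v = report["violations"]
    v["bad_type"] = int((~df["type"].isin(["go", "stop"])).sum())
    v["bad_outcome"] = int((~df["outcome"].isin(["go", "signal-respond", "signal-stop"])).sum())
    v["go_with_ssd"] = int(((df["type"] == "go") & df["ssd_ms"].notna()).sum())
    v["stop_without_ssd"] = int(((df["type"] == "stop") & df["ssd_ms"].isna()).sum())
    v["negative_ssd"] = int((df["ssd_ms"] < 0).sum())
    v["responded_without_rt"] = int((df["responded"] & df["rt_ms"].isna()).sum())
    v["rt_without_response"] = int((~df["responded"] & df["rt_ms"].notna()).sum())
    v["outcome_type_mismatch"] = int(
        (
            ((df["type"] == "go") & (df["outcome"] != "go"))
            | ((df["type"] == "stop") & (df["outcome"] == "go"))
        ).sum()
    )
    v["signal_stop_responded"] = int(((df["outcome"] == "signal-stop") & df["responded"]).sum())
    report["n_rows"] = int(len(df))
    report["valid"] = all(c == 0 for c in v.values())
    return report


def _group_tests(race_df: pd.DataFrame, trials: pd.DataFrame, collision_ms: float) -> dict:
    """Two-stage group comparisons on subject means (Welch) and the
    paired context-independence check per group."""
    groups = sorted(race_df["group"].unique())
    out = {"method": "two-stage subject-mean analysis (no mixed-effects model)"}
    if len(groups) == 2:
        g1, g2 = groups
        per_subj_tee = (
            trials.loc[(trials["type"] == "go") & trials["responded"]]
            .assign(abs_tee=lambda d: (d["rt_ms"] - collision_ms).abs())
            .groupby(["subject", "group"])["abs_tee"]
            .mean()
            .reset_index()
        )
        comps = {
            "abs_tee": (per_subj_tee, "abs_tee"),
            "mean_rt_go": (race_df, "mean_rt_go"),
            "ssd50": (race_df, "ssd50"),
            "ssrt": (race_df, "ssrt"),
        }
        for name, (df, col) in comps.items():
            a = df.loc[df["group"] == g1, col].to_numpy(float)
            b = df.loc[df["group"] == g2, col].to_numpy(float)
            if a.size >= 2 and b.size >= 2:
                r = two_sample_t(
                    float(np.mean(a)), float(np.std(a, ddof=1)), a.size,
                    float(np.mean(b)), float(np.std(b, ddof=1)), b.size,
                )
                out[name] = {"comparison": f"{g1} vs {g2}", "t": r.statistic, "df": r.df,
                             "variant": r.variant}
    for g in groups:
        sub = race_df.loc[race_df["group"] == g]
        ok = sub["mean_rt_signal_respond"].notna() & sub["mean_rt_go"].notna()
        if ok.sum() >= 2:
            r = paired_t(
                sub.loc[ok, "mean_rt_go"].to_numpy(float),
                sub.loc[ok, "mean_rt_signal_respond"].to_numpy(float),
            )
            out[f"context_independence[{g}]"] = {
                "t": r.statistic, "df": r.df, "variant": "paired",
                "signal_respond_faster": bool(r.m2 < r.m1),
            }
    return out


def render_report(outdir) -> str:
    """Render the run's markdown report from its JSON artifacts."""
    outdir = Path(outdir)
    lines = ["# stopddm run report", ""]
    gs_path = outdir / "group_summary.json"
    if gs_path.exists():
        gs = json.loads(gs_path.read_text())
        lines += ["## Group summary (mean (SD))", ""]
        groups = [k for k in gs if k not in ("method",)]
        rows = sorted({r for g in groups for r in gs[g] if r != "n_subjects"})
        lines.append("| statistic | " + " | ".join(groups) + " |")
        lines.append("|---" * (len(groups) + 1) + "|")
        for r in rows:
            cells = [f"{gs[g][r][0]:.2f} ({gs[g][r][1]:.2f})" for g in groups]
            lines.append(f"| {r} | " + " | ".join(cells) + " |")
        lines += ["", f"_{gs['method']}_", ""]
    cmp_path = outdir / "model_comparison.tsv"
    if cmp_path.exists():
        cmp_df = pd.read_csv(cmp_path, sep="\t")
        lines += ["## Model comparison (DIC, lower wins)", "",
                  cmp_df.to_markdown(index=False), ""]
    fr_path = outdir / "fit_report.json"
    if fr_path.exists():
        fr = json.loads(fr_path.read_text())
        lines += ["## Winning model", "", f"model {fr['winner']}",
                  f"posterior proportions: {fr.get('posterior_proportions', {})}", ""]
    text = "\n".join(lines) + "\n"
    (outdir / "report.md").write_text(text)
    return text


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and return the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"stopddm {__version__} | numpy {np.__version__} | pandas {pd.__version__}",
        f"master seed: {config.seed}",
    ]
    ss = np.random.SeedSequence(config.seed)
    sim_seed, fit_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    # 1. simulate
    trials = simulate_cohort(list(config.groups), config.session, seed=sim_seed)
    trials_path = outdir / "trials.tsv"
    write_trial_table(trials, trials_path)
    log.append(f"simulate: {len(trials)} trials, seed {sim_seed}")

    # 2. validate
    report = validate_table(trials_path)
    (outdir / "validation.json").write_text(json.dumps(report, indent=2))
    log.append(f"validate: valid={report['valid']}")

    # 3. exclusion
    trials = read_trial_table(trials_path)
    filtered, excl = exclusion_filter(trials)
    write_trial_table(filtered, outdir / "trials_filtered.tsv")
    (outdir / "exclusion_log.json").write_text(json.dumps(excl, indent=2))
    log.append(
        f"exclude: {excl['n_excluded_slow']} slow + {excl['n_excluded_fast']} fast "
        f"of {excl['n_go']} go trials"
    )

    # 4. race + behavioral summaries
    race_df = summarize_subjects(filtered)
    race_df.to_csv(outdir / "race_summaries.tsv", sep="\t", index=False)
    gs = group_summary(filtered, config.session.collision_time_ms)
    (outdir / "group_summary.json").write_text(json.dumps(gs, indent=2))
    agg_rows = [
        {"group": g, "statistic": stat, "mean": vals[0], "sd": vals[1]}
        for g in gs
        if g != "method"
        for stat, vals in gs[g].items()
        if stat != "n_subjects"
    ]
    pd.DataFrame(agg_rows).to_csv(outdir / "group_summary.tsv", sep="\t", index=False)
    tests = _group_tests(race_df, filtered, config.session.collision_time_ms)
    (outdir / "group_tests.json").write_text(json.dumps(tests, indent=2))
    log.append(f"analyze: {len(race_df)} subjects")

    # 5. hierarchical fits + DIC comparison
    if config.fit_models:
        mcmc = MCMCConfig(
            n_samples=config.mcmc.n_samples,
            burn_in=config.mcmc.burn_in,
            n_chains=config.mcmc.n_chains,
            adapt=config.mcmc.adapt,
            seed=fit_seed,
            store_subject_draws=config.mcmc.store_subject_draws,
        )
        specs = [ModelSpec.from_id(m) for m in config.models]
        comparison = compare_models(filtered, specs, config=mcmc)
        comparison.table.to_csv(outdir / "model_comparison.tsv", sep="\t", index=False)
        winner = comparison.results[comparison.winner_id]
        pp = {}
        if len(winner.groups) == 2:
            g1, g2 = winner.groups
            for p in sorted(winner.spec.free_by_group):
                pp[f"P({p}[{g1}] > {p}[{g2}])"] = posterior_proportion(winner, p, g1, g2)
        fit_report = {
            "winner": comparison.winner_id,
            "dic": {int(r["model"]): float(r["dic"]) for _, r in comparison.table.iterrows()},
            "p_d": {int(r["model"]): float(r["p_d"]) for _, r in comparison.table.iterrows()},
            "posterior_proportions": pp,
            "rhat": winner.rhat,
            "ess": winner.ess,
            "mcmc_seed": fit_seed,
        }
        (outdir / "fit_report.json").write_text(json.dumps(fit_report, indent=2))
        rows = []
        for name, draws in winner.posterior.items():
            for c in range(draws.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "draw": np.arange(draws.shape[1]),
                            "parameter": name,
                            "value": draws[c],
                        }
                    )
                )
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / "posterior_trace.tsv", sep="\t", index=False
        )
        log.append(
            f"fit: models {list(config.models)}, winner {comparison.winner_id}, "
            f"seed {fit_seed}"
        )

    # 6. report + checksums
    render_report(outdir)
    for p in sorted(outdir.iterdir()):
        if p.name != "log.txt" and p.is_file():
            log.append(f"sha256 {p.name} {_sha256(p)}")
    (outdir / "log.txt").write_text("\n".join(log) + "\n")
    return outdir
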