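"""Temporal-estimation error, exclusion rules, t statistics, group summary."""

import numpy as np
import pandas as pd
import pytest

from stopddm import (
    GroupSpec,
    SessionConfig,
    add_tee,
    compute_tee,
    exclusion_filter,
    group_summary,
    paired_t,
    simulate_cohort,
    two_sample_t,
)


class TestTEE:
    @pytest.mark.parametrize(
        "rt,expected,sign",
        [(898.84, -101.16, "early"), (1000.0, 0.0, "early"), (1100.0, 100.0, "late")],
    )
    def test_definition_and_boundary(self, rt, expected, sign):
        tee, s = compute_tee(rt, 1000.0)
        assert tee == pytest.approx(expected)
        assert s == sign

    def test_add_tee_only_on_responded_go(self, small_cohort):
        out = add_tee(small_cohort)
        go = (out["type"] == "go") & out["responded"]
        assert out.loc[go, "tee_ms"].notna().all()
        assert out.loc[~go, "tee_ms"].isna().all()
        assert np.allclose(
            out.loc[go, "tee_ms"], out.loc[go, "rt_ms"] - 1000.0
        )


def _go_table(rts):
    return pd.DataFrame(
        {
            "subject": "s1",
            "group": "g",
            "type": "go",
            "responded": True,
            "rt_ms": rts,
            "ssd_ms": np.nan,
            "outcome": "go",
        }
    )


class TestExclusion:
    def test_window_bounds_are_strict(self):
        df = _go_table([1300.0, -5.0, 1250.0, 0.0, 900.0])
        kept, log = exclusion_filter(df)
        assert sorted(kept["rt_ms"]) == [0.0, 900.0, 1250.0]
        assert log["n_excluded_slow"] == 1 and log["n_excluded_fast"] == 1

    def test_idempotent_and_non_mutating(self):
        df = _go_table([1300.0, 900.0])
        snapshot = df.copy()
        kept, _ = exclusion_filter(df)
        kept2, log2 = exclusion_filter(kept)
        pd.testing.assert_frame_equal(df, snapshot)
        pd.testing.assert_frame_equal(kept.reset_index(drop=True), kept2)
        assert log2["n_excluded_slow"] == 0

    def test_stop_trials_untouched(self, small_cohort):
        kept, _ = exclusion_filter(small_cohort)
        assert (kept["type"] == "stop").sum() == (small_cohort["type"] == "stop").sum()


class TestTwoSampleT:
    def test_welch_impulsiveness_summaries(self):
        """Welch t on the printed impulsiveness-scale group summaries."""
        r = two_sample_t(66.53, 4.07, 15, 50.60, 8.52, 15, variant="welch")
        assert abs(r.statistic) == pytest.approx(6.53, abs=0.005)
        assert r.df == pytest.approx(20.07, abs=0.005)

    def test_pooled_anxiety_summaries(self):
        r = two_sample_t(12.07, 2.19, 15, 4.07, 3.17, 15, variant="pooled")
        assert abs(r.statistic) == pytest.approx(8.04, abs=0.005)
        assert r.df == 28

    def test_identical_groups_give_zero(self):
        assert two_sample_t(5, 1, 10, 5, 1, 10).statistic == 0.0

    def test_zero_variance_cases(self):
        assert two_sample_t(5, 0, 10, 5, 0, 10).statistic == 0.0
        with pytest.raises(ValueError):
            two_sample_t(5, 0, 10, 6, 0, 10)

    @pytest.mark.parametrize("seed", range(5))
    def test_welch_df_never_exceeds_pooled_df(self, seed):
        rng = np.random.default_rng(seed)
        m1, m2 = rng.normal(size=2)
        sd1, sd2 = rng.uniform(0.5, 3, size=2)
        n1, n2 = rng.integers(3, 30, size=2)
        r = two_sample_t(m1, sd1, int(n1), m2, sd2, int(n2), variant="welch")
        assert r.df <= n1 + n2 - 2 + 1e-9


class TestPairedT:
    def test_df_is_n_minus_one(self):
        x = [900, 950, 1000, 1050]
        y = [890, 930, 990, 1060]
        r = paired_t(x, y)
        assert r.df == 3
        d = np.array(x) - np.array(y)
        assert r.statistic == pytest.approx(
            d.mean() / (d.std(ddof=1) / np.sqrt(4))
        )


class TestGroupSummary:
    def test_deterministic_cohort_has_zero_sds(self):
        spec = GroupSpec(
            label="fixed", n_subjects=3, a_sd=0, z_sd=0, v_sd=0, t_sd=0, ssrt_sd_ms=0
        )
        df = simulate_cohort([spec], SessionConfig(n_blocks=1), seed=0)
        go = df.loc[df["type"] == "go"]
        # identical parameters, independent noise: trial-level SDs nonzero,
        # but per-subject structure is identical in distribution
        gs = group_summary(df)
        assert gs["fixed"]["n_subjects"] == 3
        assert gs["fixed"]["RT_go ms"][0] == pytest.approx(go["rt_ms"].mean())

    def test_group_ordering_follows_starting_point(self, small_cohort):
        kept, _ = exclusion_filter(small_cohort)
        gs = group_summary(kept)
        assert gs["high-bias"]["RT_go ms"][0] < gs["control"]["RT_go ms"][0]
        assert gs["high-bias"]["Abs TEE ms"][0] > gs["control"]["Abs TEE ms"][0]
        assert gs["high-bias"]["SSD_50 ms"][0] < gs["control"]["SSD_50 ms"][0]

    def test_matches_brute_force_recomputation(self, small_cohort):
        kept, _ = exclusion_filter(small_cohort)
        gs = group_summary(kept)
        sub = kept.loc[(kept["group"] == "control")]
        go = sub.loc[(sub["type"] == "go") & sub["responded"], "rt_ms"].to_numpy()
        assert gs["control"]["RT_go ms"][0] == pytest.approx(go.mean(), abs=1e-9)
        assert gs["control"]["RT_go ms"][1] == pytest.approx(go.std(ddof=1), abs=1e-9)
        abs_tee = np.abs(go - 1000.0)
        assert gs["control"]["Abs TEE ms"][0] == pytest.approx(abs_tee.mean(), abs=1e-9)
        stop = sub.loc[sub["type"] == "stop"]
        acc = (stop["outcome"] == "signal-stop").to_numpy(float) * 100
        assert gs["control"]["Inhibition accuracy %"][0] == pytest.approx(acc.mean())
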