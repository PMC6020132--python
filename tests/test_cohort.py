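"""Cohort simulator: subject draws, race rule, staircase, trial tables."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stopddm import (
    GroupSpec,
    SessionConfig,
    SubjectParams,
    DDMParams,
    draw_subject,
    mean_rt,
    simulate_cohort,
    simulate_session,
    simulate_stop_trial,
    read_trial_table,
    write_trial_table,
)
from stopddm.cohort import _truncnorm_draw, truncnorm_mean


class TestDrawSubject:
    def test_zero_sd_returns_group_means(self):
        spec = GroupSpec(label="g", a_sd=0, z_sd=0, v_sd=0, t_sd=0)
        subj = draw_subject(spec, seed=0)
        assert subj.ddm == DDMParams(spec.a_mean, spec.z_mean, spec.v_mean, spec.t_mean)

    def test_draws_respect_domains_and_mean(self):
        spec = GroupSpec(label="g", z_mean=0.43, z_sd=0.12, t_mean=0.05, t_sd=0.05)
        rng = np.random.default_rng(1)
        draws = [draw_subject(spec, rng) for _ in range(2000)]
        zs = np.array([d.ddm.z for d in draws])
        assert np.all((zs > 0) & (zs < 1))
        assert all(d.ddm.a > 0 and d.ddm.v > 0 and d.ddm.t >= 0 for d in draws)
        expected = truncnorm_mean(0.43, 0.12, 0.0, 1.0)
        assert abs(zs.mean() - expected) < 3 * 0.12 / np.sqrt(len(zs))

    def test_far_outside_mean_is_configuration_error(self):
        with pytest.raises(ValueError, match="1e-06|far"):
            _truncnorm_draw(-10.0, 1.0, 0.0, np.inf, np.random.default_rng(0))


class TestRaceRule:
    def test_inhibits_when_go_slower_than_stop_plus_delay(self, near_deterministic_900ms):
        rec = simulate_stop_trial(near_deterministic_900ms, 590.0, np.random.default_rng(0))
        assert rec["outcome"] == "signal-stop"
        assert rec["rt_ms"] is None and not rec["responded"]

    def test_responds_when_stop_finishes_first(self, near_deterministic_900ms):
        rec = simulate_stop_trial(near_deterministic_900ms, 650.0, np.random.default_rng(0))
        assert rec["outcome"] == "signal-respond"
        assert rec["responded"] and rec["rt_ms"] == pytest.approx(900.0, abs=3.0)

    def test_response_rate_matches_convolution(self, bias_params):
        """P(respond | SSD) = E_SSRT[F_go(SSD + SSRT)] by numerical integration."""
        subj = SubjectParams(ddm=bias_params, ssrt_mean_ms=300.0, ssrt_sd_ms=50.0)
        ssd = 500.0
        rng = np.random.default_rng(4)
        n = 10_000
        responded = sum(
            simulate_stop_trial(subj, ssd, rng)["responded"] for _ in range(n)
        ) / n
        from stopddm import decision_cdf
        alpha = -300.0 / 50.0
        tn = stats.truncnorm(alpha, np.inf, loc=300.0, scale=50.0)
        grid, w = np.polynomial.legendre.leggauss(80)
        lo, hi = tn.ppf(1e-9), tn.ppf(1 - 1e-9)
        x = 0.5 * (hi - lo) * grid + 0.5 * (hi + lo)
        p_true = np.sum(
            w * 0.5 * (hi - lo) * tn.pdf(x) * decision_cdf((ssd + x) / 1000.0, bias_params)
        )
        assert abs(responded - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / n)


class TestSession:
    def _subject(self):
        return SubjectParams(
            ddm=DDMParams(8.86, 0.43, 8.48, 0.28), ssrt_mean_ms=300.0, ssrt_sd_ms=50.0
        )

    def test_record_counts_default_config(self):
        df = simulate_session(self._subject(), SessionConfig(), np.random.default_rng(0))
        assert len(df) == 200
        assert (df["type"] == "go").sum() == 150
        assert (df["type"] == "stop").sum() == 50

    def test_staircase_steps_up_after_stop_down_after_respond(self):
        df = simulate_session(self._subject(), SessionConfig(), np.random.default_rng(2))
        stops = df.loc[df["type"] == "stop"].reset_index(drop=True)
        for i in range(len(stops) - 1):
            prev, nxt = stops.loc[i], stops.loc[i + 1]
            if prev["outcome"] == "signal-stop":
                assert nxt["ssd_ms"] == min(prev["ssd_ms"] + 30.0, 2400.0)
            else:
                assert nxt["ssd_ms"] == max(prev["ssd_ms"] - 30.0, 30.0)

    def test_zero_step_keeps_initial_ssd(self):
        cfg = SessionConfig(staircase_step_ms=0.0, initial_ssd_ms=600.0)
        df = simulate_session(self._subject(), cfg, np.random.default_rng(0))
        assert (df.loc[df["type"] == "stop", "ssd_ms"] == 600.0).all()

    def test_staircase_converges_to_half_responding(self):
        """1-up/1-down with symmetric steps tracks the 50%-response SSD."""
        cfg = SessionConfig(n_blocks=300, go_per_block=0, stop_per_block=40)
        df = simulate_session(self._subject(), cfg, np.random.default_rng(8))
        stops = df.loc[df["type"] == "stop"].iloc[500:]
        rate = (stops["outcome"] == "signal-respond").mean()
        assert abs(rate - 0.5) < 0.02


class TestCohort:
    def test_counts_and_determinism(self, two_group_specs):
        cfg = SessionConfig(n_blocks=2)
        df1 = simulate_cohort(two_group_specs, cfg, seed=9)
        df2 = simulate_cohort(two_group_specs, cfg, seed=9)
        assert len(df1) == 2 * 4 * 2 * 40
        b1, b2 = io.StringIO(), io.StringIO()
        write_trial_table(df1, b1)
        write_trial_table(df2, b2)
        assert b1.getvalue() == b2.getvalue()

    def test_duplicate_labels_rejected(self):
        specs = [GroupSpec(label="x"), GroupSpec(label="x")]
        with pytest.raises(ValueError, match="duplicate"):
            simulate_cohort(specs, SessionConfig(), seed=0)

    def test_higher_z_group_is_faster(self, small_cohort, two_group_specs):
        means = (
            small_cohort.loc[small_cohort["type"] == "go"]
            .groupby("group")["rt_ms"]
            .mean()
        )
        predicted = {
            s.label: 1000.0 * mean_rt(DDMParams(s.a_mean, s.z_mean, s.v_mean, s.t_mean))
            for s in two_group_specs
        }
        assert means["high-bias"] < means["control"]
        assert (predicted["high-bias"] < predicted["control"]) == (
            means["high-bias"] < means["control"]
        )

    def test_signal_respond_faster_than_go(self, small_cohort):
        """Censoring by the race makes signal-respond RTs a truncated-from-
        above version of the go RT distribution."""
        sr = small_cohort.loc[small_cohort["outcome"] == "signal-respond", "rt_ms"]
        go = small_cohort.loc[small_cohort["type"] == "go", "rt_ms"]
        assert sr.mean() < go.mean()

    def test_round_trip_table_io(self, small_cohort, tmp_path):
        path = tmp_path / "trials.tsv"
        write_trial_table(small_cohort, path)
        back = read_trial_table(path)
        assert list(back.columns) == list(small_cohort.columns)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), small_cohort.reset_index(drop=True),
            check_dtype=False,
        )
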