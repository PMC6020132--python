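"""Hierarchical fit machinery: model specs, DIC, PP, sampler bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from stopddm import (
    DDMParams,
    GroupSpec,
    MCMCConfig,
    ModelSpec,
    Priors,
    PriorSpec,
    SessionConfig,
    dic,
    fit_hddm,
    posterior_proportion,
    sample_rts,
    simulate_cohort,
)
from stopddm.ddm import wald_logpdf


class TestModelSpec:
    @pytest.mark.parametrize(
        "mid,free",
        [(0, set()), (1, {"z", "v"}), (2, {"z"}), (3, {"v"}), (4, {"a"})],
    )
    def test_catalogue(self, mid, free):
        assert set(ModelSpec.from_id(mid).free_by_group) == free

    def test_t_never_group_varying(self):
        with pytest.raises(ValueError):
            ModelSpec(9, frozenset({"t"}))

    def test_mismatched_free_set_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(2, frozenset({"v"}))
        with pytest.raises(ValueError):
            ModelSpec.from_id(7)


class TestDIC:
    def test_degenerate_trace(self):
        val, p_d = dic(np.full(100, -123.4), -123.4)
        assert p_d == 0.0
        assert val == -123.4

    def test_brute_force_identity(self):
        rng = np.random.default_rng(0)
        dev = rng.normal(500, 10, size=(2, 400))
        point = 490.0
        val, p_d = dic(dev, point)
        assert p_d == pytest.approx(dev.mean() - point, abs=1e-10)
        assert val == pytest.approx(2 * dev.mean() - point, abs=1e-10)

    def test_non_finite_draw_is_named(self):
        dev = np.zeros(10)
        dev[7] = np.inf
        with pytest.raises(ValueError, match="7"):
            dic(dev, 0.0)

    def test_conjugate_normal_effective_parameters(self):
        """Known-variance normal mean: pD equals the posterior-variance
        shrinkage factor n * Var(theta | x)."""
        rng = np.random.default_rng(5)
        n, tau = 40, 3.0
        x = rng.normal(1.0, 1.0, size=n)
        post_var = 1.0 / (n + 1.0 / tau**2)
        post_mean = post_var * n * x.mean()
        draws = rng.normal(post_mean, np.sqrt(post_var), size=20_000)

        def deviance(theta):
            return np.sum((x[None, :] - np.atleast_1d(theta)[:, None]) ** 2) + n * np.log(
                2 * np.pi
            )

        dev_trace = np.array([deviance(t) for t in draws])
        _, p_d = dic(dev_trace, deviance(draws.mean()))
        assert p_d == pytest.approx(n * post_var, rel=0.05)


def _mini_result(draws_a, draws_b):
    """A minimal FitResult stand-in for posterior_proportion."""
    from stopddm.hierarchical import FitResult

    return FitResult(
        spec=ModelSpec.from_id(2),
        groups=["A", "B"],
        subjects=[],
        posterior={"mu_z[A]": np.asarray(draws_a), "mu_z[B]": np.asarray(draws_b)},
        deviance=np.zeros((1, 2)),
        point_deviance=0.0,
        dic=0.0,
        p_d=0.0,
        rhat={},
        ess={},
        converged=True,
        subject_posterior_mean={},
        subject_draws=None,
        n_retained=2,
        accept_rates={},
    )


class TestPosteriorProportion:
    def test_fully_ordered(self):
        res = _mini_result([[0.5, 0.6]], [[0.1, 0.2]])
        assert posterior_proportion(res, "z", "A", "B") == 1.0

    def test_mirrored(self):
        res = _mini_result([[0.5, 0.1]], [[0.1, 0.5]])
        assert posterior_proportion(res, "z", "A", "B") == 0.5

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(1, 500)), rng.normal(size=(1, 500))
        res = _mini_result(a, b)
        assert posterior_proportion(res, "z", "A", "B") == np.mean(a > b)

    def test_non_varying_parameter_is_usage_error(self):
        res = _mini_result([[0.5]], [[0.1]])
        with pytest.raises(ValueError, match="not group-varying"):
            posterior_proportion(res, "v", "A", "B")


TINY_MCMC = MCMCConfig(n_samples=300, burn_in=100, n_chains=1, adapt=150, seed=0)


def _tiny_cohort(seed=0, z2=0.30):
    specs = [
        GroupSpec(label="A", n_subjects=3, z_mean=0.43),
        GroupSpec(label="B", n_subjects=3, z_mean=z2),
    ]
    return simulate_cohort(specs, SessionConfig(n_blocks=1), seed=seed)


class TestFitBookkeeping:
    def test_trace_counts_and_keys(self):
        res = fit_hddm(_tiny_cohort(), ModelSpec.from_id(2), config=TINY_MCMC)
        assert res.n_retained == 200
        assert set(res.posterior) == {
            "mu_a", "sigma_a", "mu_z[A]", "mu_z[B]", "sigma_z",
            "mu_v", "sigma_v", "mu_t", "sigma_t",
        }
        assert res.deviance.shape == (1, 200)
        assert np.all(np.isfinite(res.deviance))
        assert res.dic == pytest.approx(res.deviance.mean() + res.p_d)

    def test_shared_fit_has_single_means(self):
        res = fit_hddm(_tiny_cohort(), ModelSpec.from_id(0), config=TINY_MCMC)
        assert "mu_z" in res.posterior and "mu_z[A]" not in res.posterior

    def test_group_varying_model_needs_two_groups(self):
        df = _tiny_cohort()
        df = df.loc[df["group"] == "A"]
        with pytest.raises(ValueError, match="two group"):
            fit_hddm(df, ModelSpec.from_id(2), config=TINY_MCMC)

    def test_zero_rt_subject_is_data_error(self):
        df = _tiny_cohort()
        first_go = df.index[(df["type"] == "go") & (df["subject"] == "A-01")][0]
        df.loc[first_go, "rt_ms"] = 0.0
        with pytest.raises(ValueError, match="non-decision"):
            fit_hddm(df, ModelSpec.from_id(2), config=TINY_MCMC, apply_exclusion=False)


class TestSingleSubjectAgainstMLE:
    def test_posterior_tracks_mle_in_identified_coordinates(self):
        """One subject, many trials, weak priors: posterior means of the
        identified functions (a(1-z), v, t) sit near the numerical MLE."""
        params = DDMParams(8.86, 0.43, 8.48, 0.28)
        rts = sample_rts(params, 3000, seed=17)
        df = pd.DataFrame(
            {
                "subject": "s1",
                "group": "g",
                "block": 1,
                "trial": np.arange(rts.size),
                "type": "go",
                "ssd_ms": np.nan,
                "responded": True,
                "rt_ms": rts * 1000.0,
                "outcome": "go",
            }
        )

        from scipy import stats as sps

        def nll(x):
            kappa, v, t = x
            d = rts - t
            if np.any(d <= 0) or kappa <= 0 or v <= 0 or t < 0:
                return 1e9
            # independent parametrization: scipy invgauss with mean
            # kappa/v and shape kappa^2
            mu, lam = kappa / v, kappa**2
            return -np.sum(sps.invgauss.logpdf(d, mu / lam, scale=lam))

        mle = optimize.minimize(
            nll, x0=[4.0, 7.0, 0.2], method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        weak = Priors(
            mean={
                "a": PriorSpec(5.0, 50.0, 0.0, np.inf),
                "z": PriorSpec(0.5, 0.25, 0.0, 1.0),
                "v": PriorSpec(5.0, 50.0, 0.0, np.inf),
                "t": PriorSpec(0.3, 3.0, 0.0, np.inf),
            },
            sd_scale={"a": 1.0, "z": 0.2, "v": 1.0, "t": 1.0},
        )
        cfg = MCMCConfig(
            n_samples=3000, burn_in=200, n_chains=1, adapt=800, seed=3,
            store_subject_draws=True,
        )
        res = fit_hddm(df, ModelSpec.from_id(0), priors=weak, config=cfg)
        # the posterior spreads along the weakly identified t-ridge, so the
        # mode (the minimum-deviance draw; priors are near-flat) is the
        # right point to compare with the MLE, not the posterior mean
        c, d = np.unravel_index(np.argmin(res.deviance), res.deviance.shape)
        kappa_mode = float(
            res.subject_draws["a"][c, d, 0] * (1 - res.subject_draws["z"][c, d, 0])
        )
        v_mode = float(res.subject_draws["v"][c, d, 0])
        t_mode = float(res.subject_draws["t"][c, d, 0])
        kappa_hat, v_hat, t_hat = mle.x
        assert kappa_mode == pytest.approx(kappa_hat, rel=0.03)
        assert v_mode == pytest.approx(v_hat, rel=0.02)
        assert t_mode == pytest.approx(t_hat, abs=0.02)
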