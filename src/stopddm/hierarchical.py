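"""Hierarchical Bayesian estimation of the one-choice diffusion model.

Each subject's responded go RTs (seconds, post-exclusion) follow the
shifted-Wald likelihood of :mod:`stopddm.ddm`. Subject parameters are
drawn from group-level normal distributions truncated to each parameter's
domain; a model variant declares which parameter means differ by group:

* model 1 — starting point ``z`` and drift ``v`` vary by group;
* model 2 — only ``z`` varies (prior-bias account);
* model 3 — only ``v`` varies (sensory-gain account);
* model 4 — only the threshold ``a`` varies (strategic-slowing account);
* model 0 — nothing varies (shared fit, the null structure).

The non-decision time ``t`` is never group-split. Between-subject SDs are
shared across groups; only means vary.

Sampling is adaptive random-walk Metropolis-within-Gibbs with proposals on
log scales for ``a`` and ``v``, the logit scale for ``z``, and the natural
scale for ``t``. Because the likelihood depends on ``a`` and ``z`` only
through ``a (1 - z)``, an extra joint proposal moves each subject along
that likelihood ridge at no data cost, which is what makes ``z`` mix.
Proposal scales adapt only during a dedicated warm-up phase; the retained
chain (``n_samples`` draws, first ``burn_in`` discarded) runs with frozen
scales. Model comparison uses the deviance information criterion with the
classic effective-parameter count ``pD = mean deviance - deviance at the
posterior means``; the plug-in point is formed in the likelihood's
identified coordinates (log a(1-z), logit z, log v, t) so it stays on the
posterior ridge and the resulting DIC is reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .behavioral import exclusion_filter
from .ddm import wald_logpdf

__all__ = [
    "ModelSpec",
    "MCMCConfig",
    "PriorSpec",
    "Priors",
    "FitResult",
    "ModelComparison",
    "fit_hddm",
    "dic",
    "posterior_proportion",
    "compare_models",
]

PARAMS = ("a", "z", "v", "t")

_MODEL_FREE_SETS = {
    0: frozenset(),
    1: frozenset({"z", "v"}),
    2: frozenset({"z"}),
    3: frozenset({"v"}),
    4: frozenset({"a"}),
}

_DOMAINS = {
    "a": (0.0, np.inf),
    "z": (0.0, 1.0),
    "v": (0.0, np.inf),
    "t": (0.0, np.inf),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which group-level means are free to differ between groups."""

    model_id: int
    free_by_group: frozenset

    def __post_init__(self) -> None:
        if "t" in self.free_by_group:
            raise ValueError("t is never group-split")
        if not self.free_by_group <= {"a", "z", "v"}:
            raise ValueError(f"unknown parameters in {set(self.free_by_group)}")
        expected = _MODEL_FREE_SETS.get(self.model_id)
        if expected is not None and frozenset(self.free_by_group) != expected:
            raise ValueError(
                f"model {self.model_id} is defined with free set {set(expected)}"
            )

    @classmethod
    def from_id(cls, model_id: int) -> "ModelSpec":
        if model_id not in _MODEL_FREE_SETS:
            raise ValueError(f"unknown model id {model_id}")
        return cls(model_id, _MODEL_FREE_SETS[model_id])


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``n_samples`` draws are generated after ``adapt`` frozen-in warm-up
    iterations; the first ``burn_in`` of them are discarded, so
    ``n_samples - burn_in`` draws per chain are retained.
    """

    n_samples: int = 10_000
    burn_in: int = 200
    n_chains: int = 4
    adapt: int = 1_000
    seed: int | None = None
    store_subject_draws: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_samples):
            raise ValueError("need 0 <= burn_in < n_samples")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.adapt < 0:
            raise ValueError("adapt must be >= 0")


@dataclass(frozen=True)
class PriorSpec:
    """Truncated-normal prior: Normal(loc, scale^2) restricted to [lo, hi]."""

    loc: float
    scale: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.scale <= 0 or not self.lo < self.hi:
            raise ValueError("invalid prior specification")


@dataclass(frozen=True)
class Priors:
    """Weakly informative priors at the scale of the task (seconds, s = 1).

    ``mean`` holds the group-mean priors; ``sd_scale`` the half-normal
    scales of the between-subject SDs.
    """

    mean: dict = field(
        default_factory=lambda: {
            "a": PriorSpec(5.0, 5.0, 0.0, np.inf),
            "z": PriorSpec(0.5, 0.25, 0.0, 1.0),
            "v": PriorSpec(5.0, 5.0, 0.0, np.inf),
            "t": PriorSpec(0.3, 0.3, 0.0, np.inf),
        }
    )
    sd_scale: dict = field(
        default_factory=lambda: {"a": 1.0, "z": 0.2, "v": 1.0, "t": 1.0}
    )


@dataclass
class FitResult:
    """Posterior draws and model-comparison statistics for one model."""

    spec: ModelSpec
    groups: list
    subjects: list
    posterior: dict          # name -> (n_chains, n_retained) array
    deviance: np.ndarray     # (n_chains, n_retained)
    point_deviance: float
    dic: float
    p_d: float
    rhat: dict
    ess: dict
    converged: bool
    subject_posterior_mean: dict   # param -> (n_subjects,) natural scale
    subject_draws: dict | None
    n_retained: int
    accept_rates: dict

    def mu_key(self, param: str, group: str | None = None) -> str:
        if param in self.spec.free_by_group:
            if group is None:
                raise ValueError(f"{param} is group-varying; a group is required")
            return f"mu_{param}[{group}]"
        return f"mu_{param}"


def dic(deviance_draws, point_deviance: float) -> tuple[float, float]:
    """Deviance information criterion from a deviance trace.

    ``pD = mean(D) - D(posterior mean)``; ``DIC = mean(D) + pD``.
    """
    dev = np.asarray(deviance_draws, float).ravel()
    if dev.size < 1:
        raise ValueError("need at least one deviance draw")
    if not np.all(np.isfinite(dev)):
        bad = int(np.flatnonzero(~np.isfinite(dev))[0])
        raise ValueError(f"non-finite deviance at draw {bad}")
    dbar = float(np.mean(dev))
    p_d = dbar - float(point_deviance)
    return dbar + p_d, p_d


def posterior_proportion(result: FitResult, parameter: str, group_a: str, group_b: str) -> float:
    """Fraction of retained draws with group A's mean above group B's."""
    if parameter not in result.spec.free_by_group:
        raise ValueError(
            f"{parameter!r} is not group-varying in model {result.spec.model_id}"
        )
    da = result.posterior[f"mu_{parameter}[{group_a}]"]
    db = result.posterior[f"mu_{parameter}[{group_b}]"]
    return float(np.mean(da > db))


# ---------------------------------------------------------------- internals


def _log_trunc_mass(m, sd, lo, hi):
    """log of the normal mass on [lo, hi] (the truncation normalizer)."""
    if np.isinf(hi):
        z = ndtr((np.asarray(m) - lo) / sd)
    else:
        z = ndtr((hi - np.asarray(m)) / sd) - ndtr((lo - np.asarray(m)) / sd)
    return np.log(np.clip(z, 1e-300, None))


class _SamplerState:
    """One chain's state: subject parameters, hypers, cached likelihoods."""

    def __init__(self, data, spec, priors, rng):
        self.data = data
        self.spec = spec
        self.priors = priors
        self.rng = rng
        S = data.n_subjects
        G = data.n_groups
        # moment-matched initial values, dispersed across chains: given a
        # tentative non-decision time (a chain-specific fraction of each
        # subject's minimum RT), invert the Wald mean/variance for the
        # remaining distance and drift so every chain starts on the
        # data-supported manifold rather than at the prior location
        t0 = rng.uniform(0.3, 0.8) * data.min_rt
        m_hat = np.array([r[m].mean() for r, m in zip(data.rt_mat, data.mask)])
        w_hat = np.array(
            [max(r[m].var(), 1e-6) for r, m in zip(data.rt_mat, data.mask)]
        )
        mu0 = np.maximum(m_hat - t0, 0.05)
        kappa0 = np.sqrt(mu0**3 / w_hat)
        z0 = np.clip(0.5 + 0.08 * rng.standard_normal(S), 0.2, 0.8)
        self.theta = {
            "a": kappa0 / (1.0 - z0),
            "z": z0,
            "v": kappa0 / mu0,
            "t": t0,
        }
        self.mu = {}
        for p in PARAMS:
            n_levels = G if p in spec.free_by_group else 1
            base = np.array([np.mean(self.theta[p])] * n_levels)
            self.mu[p] = base
        self.sd = {p: 0.5 * priors.sd_scale[p] for p in PARAMS}
        self.sd["z"] = min(self.sd["z"], 0.1)
        self.ll = self._loglik_all()
        # proposal scales
        self.subj_step = {
            "a": np.full(S, 0.15), "z": np.full(S, 0.2),
            "v": np.full(S, 0.1), "t": np.full(S, 0.02),
            "ridge": np.full(S, 0.3),
            "tshift": np.full(S, 0.02),
            "tskew": np.full(S, 0.02),
        }
        self.mu_step = {p: np.full(len(self.mu[p]), _MU_STEP0[p]) for p in PARAMS}
        self.sd_step = {p: 0.4 for p in PARAMS}
        self.group_ridge_step = np.full(G, 0.1)
        self.global_ridge_step = 0.1
        self.global_tshift_step = 0.01
        self.global_tskew_step = 0.01

    # vectorized shifted-Wald log-likelihood per subject
    def _loglik(self, a, z, v, t):
        d = self.data.rt_mat - t[:, None]
        bad = (d <= 0) & self.data.mask
        safe = np.where(self.data.mask & ~bad, d, 1.0)
        az = a * (1.0 - z)
        mu = az / v
        lam = az * az
        lp = wald_logpdf(safe, mu[:, None], lam[:, None])
        out = np.where(self.data.mask & ~bad, lp, 0.0).sum(axis=1)
        out[bad.any(axis=1)] = -np.inf
        return out

    def _loglik_all(self):
        return self._loglik(self.theta["a"], self.theta["z"], self.theta["v"], self.theta["t"])

    def _mu_of(self, p):
        """Per-subject group mean for parameter p."""
        m = self.mu[p]
        if len(m) == 1:
            return np.full(self.data.n_subjects, m[0])
        return m[self.data.group_idx]

    # -- subject-level updates ------------------------------------------
    def update_subject_param(self, p):
        rng = self.rng
        S = self.data.n_subjects
        th = self.theta[p]
        step = self.subj_step[p]
        eps = step * rng.standard_normal(S)
        if p in ("a", "v"):
            prop = th * np.exp(eps)
            jac_cur, jac_prop = np.log(th), np.log(prop)
            valid = np.isfinite(prop) & (prop > 0)
        elif p == "z":
            x = np.log(th) - np.log1p(-th)
            xp = x + eps
            prop = 1.0 / (1.0 + np.exp(-xp))
            prop = np.clip(prop, 1e-12, 1 - 1e-12)
            jac_cur = np.log(th) + np.log1p(-th)
            jac_prop = np.log(prop) + np.log1p(-prop)
            valid = np.ones(S, bool)
        else:  # t, natural scale
            prop = th + eps
            jac_cur = jac_prop = np.zeros(S)
            valid = prop >= 0
        cand = {q: self.theta[q] for q in PARAMS}
        cand[p] = np.where(valid, prop, th)
        ll_prop = self._loglik(cand["a"], cand["z"], cand["v"], cand["t"])
        m, s = self._mu_of(p), self.sd[p]
        pr_cur = -0.5 * ((th - m) / s) ** 2
        pr_prop = -0.5 * ((cand[p] - m) / s) ** 2
        logr = (ll_prop - self.ll) + (pr_prop - pr_cur) + (jac_prop - jac_cur)
        logr = np.where(valid, logr, -np.inf)
        accept = np.log(rng.uniform(size=S)) < logr
        self.theta[p] = np.where(accept, cand[p], th)
        self.ll = np.where(accept, ll_prop, self.ll)
        self.acc[p] += accept

    def update_subject_ridge(self):
        """Joint (a, z) move holding a(1-z) fixed: likelihood-neutral."""
        rng = self.rng
        S = self.data.n_subjects
        a, z = self.theta["a"], self.theta["z"]
        eps = self.subj_step["ridge"] * rng.standard_normal(S)
        a_p = a * np.exp(eps)
        omz_p = (1.0 - z) * np.exp(-eps)
        valid = (omz_p > 0) & (omz_p < 1) & np.isfinite(a_p)
        z_p = 1.0 - omz_p
        ma, mz = self._mu_of("a"), self._mu_of("z")
        sa, sz = self.sd["a"], self.sd["z"]

        def kern(av, zv):
            return (
                -0.5 * ((av - ma) / sa) ** 2
                - 0.5 * ((zv - mz) / sz) ** 2
                + np.log(av)
                + np.log1p(-zv)
            )

        logr = np.where(valid, kern(a_p, np.where(valid, z_p, z)) - kern(a, z), -np.inf)
        accept = np.log(rng.uniform(size=S)) < logr
        self.theta["a"] = np.where(accept, a_p, a)
        self.theta["z"] = np.where(accept, z_p, z)
        self.acc["ridge"] += accept

    def update_subject_tshift(self):
        """Joint (t, v) move holding the mean RT t + a(1-z)/v fixed.

        The non-decision shift and the Wald mean are nearly confounded at
        realistic trial counts; a random walk in (t, mean RT) coordinates
        crosses that ridge. The likelihood does change (the Wald variance
        moves with its mean), so this is a full Metropolis step with the
        Jacobian of v as a function of the fixed mean, 2 log v - log a(1-z).
        """
        rng = self.rng
        S = self.data.n_subjects
        t, v = self.theta["t"], self.theta["v"]
        az = self.theta["a"] * (1.0 - self.theta["z"])
        mu_dec = az / v
        delta = self.subj_step["tshift"] * rng.standard_normal(S)
        t_p = t + delta
        mu_p = mu_dec - delta
        valid = (t_p >= 0) & (mu_p > 0)
        v_p = np.where(valid, az / np.where(mu_p > 0, mu_p, 1.0), v)
        ll_prop = self._loglik(self.theta["a"], self.theta["z"], v_p, np.where(valid, t_p, t))
        mt, st_ = self._mu_of("t"), self.sd["t"]
        mv, sv = self._mu_of("v"), self.sd["v"]
        pr_cur = -0.5 * ((t - mt) / st_) ** 2 - 0.5 * ((v - mv) / sv) ** 2 + 2.0 * np.log(v)
        pr_prop = (
            -0.5 * ((np.where(valid, t_p, t) - mt) / st_) ** 2
            - 0.5 * ((v_p - mv) / sv) ** 2
            + 2.0 * np.log(v_p)
        )
        logr = np.where(valid, (ll_prop - self.ll) + (pr_prop - pr_cur), -np.inf)
        accept = np.log(rng.uniform(size=S)) < logr
        self.theta["t"] = np.where(accept, t_p, t)
        self.theta["v"] = np.where(accept, v_p, v)
        self.ll = np.where(accept, ll_prop, self.ll)
        self.acc["tshift"] += accept

    def update_subject_tskew(self):
        """Joint (t, a, v) move holding the RT mean and variance fixed.

        Walks t along the soft direction of the shifted-Wald likelihood:
        the decision-time mean mu = a(1-z)/v absorbs -delta and the shape
        rescales as lam' = lam (mu'/mu)^3 so the variance mu^3/lam is
        unchanged; only the skewness changes, which is all the data have
        left to say about t. Coordinates are (t, mean, variance) at fixed
        z, whose volume element contributes a log(mu) Jacobian term.
        """
        rng = self.rng
        S = self.data.n_subjects
        a, z, v, t = (self.theta[p] for p in PARAMS)
        mu = a * (1.0 - z) / v
        delta = self.subj_step["tskew"] * rng.standard_normal(S)
        mu_p = mu - delta
        t_p = t + delta
        valid = (mu_p > 0) & (t_p >= 0)
        r = np.where(valid, mu_p / mu, 1.0)
        a_p = a * r**1.5
        v_p = v * np.sqrt(r)
        t_c = np.where(valid, t_p, t)
        ll_prop = self._loglik(a_p, z, v_p, t_c)
        ma, sa = self._mu_of("a"), self.sd["a"]
        mv, sv = self._mu_of("v"), self.sd["v"]
        mt, st_ = self._mu_of("t"), self.sd["t"]

        def kern(av, vv, tv, muv):
            return (
                -0.5 * ((av - ma) / sa) ** 2
                - 0.5 * ((vv - mv) / sv) ** 2
                - 0.5 * ((tv - mt) / st_) ** 2
                + np.log(muv)
            )

        logr = (ll_prop - self.ll) + kern(a_p, v_p, t_c, np.where(valid, mu_p, mu)) - kern(a, v, t, mu)
        logr = np.where(valid, logr, -np.inf)
        accept = np.log(rng.uniform(size=S)) < logr
        self.theta["a"] = np.where(accept, a_p, a)
        self.theta["v"] = np.where(accept, v_p, v)
        self.theta["t"] = np.where(accept, t_c, t)
        self.ll = np.where(accept, ll_prop, self.ll)
        self.acc["tskew"] += accept

    def update_global_tskew(self):
        """Global version of the (t, a, v) skew move: every subject's t
        shifts by the same delta (means and variances all preserved) and
        the t hierarchy translates with them."""
        rng = self.rng
        delta = self.global_tskew_step * rng.standard_normal()
        a, z, v, t = (self.theta[p] for p in PARAMS)
        mu = a * (1.0 - z) / v
        mu_p = mu - delta
        t_p = t + delta
        mu_t_p = self.mu["t"] + delta
        if np.any(mu_p <= 0) or np.any(t_p < 0) or np.any(mu_t_p <= 0):
            return
        r = mu_p / mu
        a_p = a * r**1.5
        v_p = v * np.sqrt(r)
        ll_prop = self._loglik(a_p, z, v_p, t_p)
        if not np.all(np.isfinite(ll_prop)):
            return
        ma, sa = self._mu_of("a"), self.sd["a"]
        mv, sv = self._mu_of("v"), self.sd["v"]
        st_ = self.sd["t"]
        pr_t = self.priors.mean["t"]

        def pieces(av, vv, tv, muv, mt_scalar):
            out = float(
                np.sum(
                    -0.5 * ((av - ma) / sa) ** 2
                    - 0.5 * ((vv - mv) / sv) ** 2
                    - 0.5 * ((tv - mt_scalar) / st_) ** 2
                    + np.log(muv)
                )
            )
            out -= self.data.n_subjects * float(_log_trunc_mass(mt_scalar, st_, 0.0, np.inf))
            out += -0.5 * ((mt_scalar - pr_t.loc) / pr_t.scale) ** 2
            return out

        logr = float(np.sum(ll_prop - self.ll))
        logr += pieces(a_p, v_p, t_p, mu_p, float(mu_t_p[0]))
        logr -= pieces(a, v, t, mu, float(self.mu["t"][0]))
        if np.log(rng.uniform()) < logr:
            self.theta["a"] = a_p
            self.theta["v"] = v_p
            self.theta["t"] = t_p
            self.mu["t"] = mu_t_p
            self.ll = ll_prop
            self.acc_gtskew += 1

    def update_global_tshift(self):
        """Translate every subject's t (and mu_t) together, compensating v.

        The group-level analogue of the per-subject (t, v) move: all
        non-decision times shift by the same delta, each v is rescaled so
        each subject's mean RT stays fixed, and the t hierarchy translates
        with them, so the whole t-v ridge is crossed in one step.
        """
        rng = self.rng
        delta = self.global_tshift_step * rng.standard_normal()
        t, v = self.theta["t"], self.theta["v"]
        az = self.theta["a"] * (1.0 - self.theta["z"])
        mu_dec = az / v
        t_p = t + delta
        mu_p = mu_dec - delta
        mu_t_p = self.mu["t"] + delta
        pr_t = self.priors.mean["t"]
        if np.any(t_p < 0) or np.any(mu_p <= 0) or np.any(mu_t_p <= pr_t.lo):
            return
        v_p = az / mu_p
        ll_prop = self._loglik(self.theta["a"], self.theta["z"], v_p, t_p)
        if not np.all(np.isfinite(ll_prop)):
            return
        mt, st_ = self._mu_of("t"), self.sd["t"]
        mv, sv = self._mu_of("v"), self.sd["v"]

        def pieces(tv, vv, mt_now):
            out = float(
                np.sum(
                    -0.5 * ((tv - mt_now) / st_) ** 2
                    - _log_trunc_mass(mt_now, st_, 0.0, np.inf)
                    - 0.5 * ((vv - mv) / sv) ** 2
                    + 2.0 * np.log(vv)
                )
            )
            m = mt_now[0] if np.ndim(mt_now) else mt_now
            out += -0.5 * ((m - pr_t.loc) / pr_t.scale) ** 2
            return out

        logr = float(np.sum(ll_prop - self.ll))
        logr += pieces(t_p, v_p, np.full_like(mt, mu_t_p[0])) - pieces(t, v, mt)
        if np.log(rng.uniform()) < logr:
            self.theta["t"] = t_p
            self.theta["v"] = v_p
            self.mu["t"] = mu_t_p
            self.ll = ll_prop
            self.acc_gtshift += 1

    def _az_pieces(self, a, z, mu_a, mu_z, sd_a, sd_z, idx):
        """Log-target terms involving only the (a, z) block for subjects in
        ``idx`` plus the given hypers: truncated-normal hierarchy, hyper
        kernels, and the log-scale Jacobians of the ridge coordinates."""
        pr_a, pr_z = self.priors.mean["a"], self.priors.mean["z"]
        if np.any(mu_a <= pr_a.lo) or np.any(mu_a >= pr_a.hi):
            return -np.inf
        if np.any(mu_z <= pr_z.lo) or np.any(mu_z >= pr_z.hi):
            return -np.inf
        gi = self.data.group_idx[idx]
        ma = mu_a[gi] if len(mu_a) > 1 else np.full(idx.sum(), mu_a[0])
        mz = mu_z[gi] if len(mu_z) > 1 else np.full(idx.sum(), mu_z[0])
        out = float(
            np.sum(
                -0.5 * ((a - ma) / sd_a) ** 2
                - _log_trunc_mass(ma, sd_a, 0.0, np.inf)
                - 0.5 * ((z - mz) / sd_z) ** 2
                - _log_trunc_mass(mz, sd_z, 0.0, 1.0)
                + np.log(a)
                + np.log1p(-z)
            )
        )
        out -= idx.sum() * (np.log(sd_a) + np.log(sd_z))
        out += float(
            np.sum(-0.5 * ((mu_a - pr_a.loc) / pr_a.scale) ** 2)
            + np.sum(-0.5 * ((mu_z - pr_z.loc) / pr_z.scale) ** 2)
        )
        return out

    def update_group_ridge(self):
        """Slide one group's subjects (and its z mean, when group-specific)
        along a(1-z): develops the group contrast in z without touching the
        likelihood."""
        rng = self.rng
        for gi in range(self.data.n_groups):
            idx = self.data.group_idx == gi
            if not idx.any():
                continue
            eps = self.group_ridge_step[gi] * rng.standard_normal()
            a, z = self.theta["a"][idx], self.theta["z"][idx]
            a_p = a * np.exp(eps)
            omz = (1.0 - z) * np.exp(-eps)
            if np.any(omz >= 1) or np.any(omz <= 0):
                continue
            z_p = 1.0 - omz
            mu_z = self.mu[p_z := "z"]
            mu_z_p = mu_z.copy()
            jac = 0.0
            if len(mu_z) > 1:
                omz_mu = (1.0 - mu_z[gi]) * np.exp(-eps)
                if not (0 < omz_mu < 1):
                    continue
                mu_z_p[gi] = 1.0 - omz_mu
                jac = np.log1p(-mu_z_p[gi]) - np.log1p(-mu_z[gi])
            cur = self._az_pieces(a, z, self.mu["a"], mu_z, self.sd["a"], self.sd["z"], idx)
            prop = self._az_pieces(a_p, z_p, self.mu["a"], mu_z_p, self.sd["a"], self.sd["z"], idx)
            if np.log(rng.uniform()) < prop - cur + jac:
                self.theta["a"][idx] = a_p
                self.theta["z"][idx] = z_p
                self.mu[p_z] = mu_z_p
                self.acc_gridge[gi] += 1

    def update_global_ridge(self):
        """Slide the whole configuration — every subject, the a and z means
        and their SDs — along the shared a(1-z) ridge."""
        rng = self.rng
        eps = self.global_ridge_step * rng.standard_normal()
        idx = np.ones(self.data.n_subjects, bool)
        a, z = self.theta["a"], self.theta["z"]
        a_p = a * np.exp(eps)
        omz = (1.0 - z) * np.exp(-eps)
        if np.any(omz >= 1) or np.any(omz <= 0):
            return
        z_p = 1.0 - omz
        mu_a_p = self.mu["a"] * np.exp(eps)
        omz_mu = (1.0 - self.mu["z"]) * np.exp(-eps)
        if np.any(omz_mu >= 1) or np.any(omz_mu <= 0):
            return
        mu_z_p = 1.0 - omz_mu
        sd_a_p = self.sd["a"] * np.exp(eps)
        sd_z_p = self.sd["z"] * np.exp(-eps)
        cur = self._az_pieces(a, z, self.mu["a"], self.mu["z"], self.sd["a"], self.sd["z"], idx)
        cur += -0.5 * (self.sd["a"] / self.priors.sd_scale["a"]) ** 2 + np.log(self.sd["a"])
        cur += -0.5 * (self.sd["z"] / self.priors.sd_scale["z"]) ** 2 + np.log(self.sd["z"])
        cur += float(np.sum(np.log(self.mu["a"])) + np.sum(np.log1p(-self.mu["z"])))
        prop = self._az_pieces(a_p, z_p, mu_a_p, mu_z_p, sd_a_p, sd_z_p, idx)
        prop += -0.5 * (sd_a_p / self.priors.sd_scale["a"]) ** 2 + np.log(sd_a_p)
        prop += -0.5 * (sd_z_p / self.priors.sd_scale["z"]) ** 2 + np.log(sd_z_p)
        prop += float(np.sum(np.log(mu_a_p)) + np.sum(np.log1p(-mu_z_p)))
        if np.log(rng.uniform()) < prop - cur:
            self.theta["a"] = a_p
            self.theta["z"] = z_p
            self.mu["a"] = mu_a_p
            self.mu["z"] = mu_z_p
            self.sd["a"] = sd_a_p
            self.sd["z"] = sd_z_p
            self.acc_globalridge += 1

    # -- group-level updates --------------------------------------------
    def _mu_target(self, p, level, m):
        lo, hi = _DOMAINS[p]
        pr = self.priors.mean[p]
        if not (pr.lo < m < pr.hi):
            return -np.inf
        th = self.theta[p]
        if len(self.mu[p]) > 1:
            th = th[self.data.group_idx == level]
        s = self.sd[p]
        like = -0.5 * np.sum(((th - m) / s) ** 2) - th.size * _log_trunc_mass(m, s, lo, hi)
        prior = -0.5 * ((m - pr.loc) / pr.scale) ** 2
        return like + prior

    def update_mu(self, p):
        for level in range(len(self.mu[p])):
            m = self.mu[p][level]
            prop = m + self.mu_step[p][level] * self.rng.standard_normal()
            logr = self._mu_target(p, level, prop) - self._mu_target(p, level, m)
            if np.log(self.rng.uniform()) < logr:
                self.mu[p][level] = prop
                self.acc_mu[p][level] += 1

    def _sd_target(self, p, s):
        if s <= 0:
            return -np.inf
        lo, hi = _DOMAINS[p]
        th = self.theta[p]
        m = self._mu_of(p)
        like = -0.5 * np.sum(((th - m) / s) ** 2) - th.size * np.log(s)
        # truncation normalizer per subject's group mean
        like -= float(np.sum(_log_trunc_mass(m, s, lo, hi)))
        prior = -0.5 * (s / self.priors.sd_scale[p]) ** 2
        return like + prior + np.log(s)  # jacobian of the log-scale walk

    def update_sd(self, p):
        s = self.sd[p]
        prop = s * np.exp(self.sd_step[p] * self.rng.standard_normal())
        logr = self._sd_target(p, prop) - self._sd_target(p, s)
        if np.log(self.rng.uniform()) < logr:
            self.sd[p] = prop
            self.acc_sd[p] += 1

    # -- adaptation ------------------------------------------------------
    def reset_counters(self):
        self.acc = {k: np.zeros_like(v, dtype=float) for k, v in self.subj_step.items()}
        self.acc_mu = {p: np.zeros(len(self.mu[p])) for p in PARAMS}
        self.acc_sd = {p: 0.0 for p in PARAMS}
        self.acc_gridge = np.zeros(self.data.n_groups)
        self.acc_globalridge = 0.0
        self.acc_gtshift = 0.0
        self.acc_gtskew = 0.0

    def adapt_steps(self, window, target=0.3, gain=1.0):
        for k in self.subj_step:
            rate = self.acc[k] / window
            self.subj_step[k] *= np.exp(gain * (rate - target))
        for p in PARAMS:
            rate = self.acc_mu[p] / window
            self.mu_step[p] *= np.exp(gain * (rate - target))
            self.sd_step[p] *= float(np.exp(gain * (self.acc_sd[p] / window - target)))
        self.group_ridge_step *= np.exp(gain * (self.acc_gridge / window - target))
        self.global_ridge_step *= float(
            np.exp(gain * (self.acc_globalridge / window - target))
        )
        self.global_tshift_step *= float(
            np.exp(gain * (self.acc_gtshift / window - target))
        )
        self.global_tskew_step *= float(
            np.exp(gain * (self.acc_gtskew / window - target))
        )
        self.reset_counters()

    def sweep(self):
        for p in PARAMS:
            self.update_subject_param(p)
        self.update_subject_ridge()
        self.update_subject_tshift()
        self.update_subject_tskew()
        self.update_group_ridge()
        self.update_global_ridge()
        self.update_global_tshift()
        self.update_global_tskew()
        for p in PARAMS:
            self.update_mu(p)
            self.update_sd(p)

    def deviance(self):
        return -2.0 * float(np.sum(self.ll))


_MU_STEP0 = {"a": 0.4, "z": 0.04, "v": 0.3, "t": 0.03}


class _FitData:
    """Padded per-subject RT matrix (seconds) plus group bookkeeping."""

    def __init__(self, trials: pd.DataFrame):
        go = trials.loc[(trials["type"] == "go") & trials["responded"]]
        subjects = sorted(go["subject"].unique().tolist())
        if not subjects:
            raise ValueError("no responded go trials in the table")
        groups = sorted(trials["group"].unique().tolist())
        rts, gidx = [], []
        for s in subjects:
            sub = go.loc[go["subject"] == s]
            r = sub["rt_ms"].to_numpy(float) / 1000.0
            if r.size == 0:
                raise ValueError(f"subject {s} has no responded go trials after exclusion")
            if np.min(r) <= 0:
                raise ValueError(
                    f"subject {s}: minimum RT {np.min(r) * 1000:.1f} ms admits no "
                    "non-negative non-decision time"
                )
            rts.append(r)
            gidx.append(groups.index(sub["group"].iloc[0]))
        T = max(r.size for r in rts)
        self.rt_mat = np.full((len(subjects), T), np.nan)
        self.mask = np.zeros((len(subjects), T), bool)
        for i, r in enumerate(rts):
            self.rt_mat[i, : r.size] = r
            self.mask[i, : r.size] = True
        self.rt_mat = np.where(self.mask, self.rt_mat, 1.0)
        self.min_rt = np.array([r.min() for r in rts])
        self.subjects = subjects
        self.groups = groups
        self.group_idx = np.asarray(gidx)
        self.n_subjects = len(subjects)
        self.n_groups = len(groups)
        self.n_trials = int(self.mask.sum())


def _transform(p, x):
    if p in ("a", "v"):
        return np.log(x)
    if p == "z":
        return np.log(x) - np.log1p(-x)
    return x


def _back_transform(p, x):
    if p in ("a", "v"):
        return np.exp(x)
    if p == "z":
        return 1.0 / (1.0 + np.exp(-x))
    return x


# Coordinates for the pD plug-in point. The likelihood identifies, per
# subject, kappa = a(1-z), v and t; averaging raw (log a, logit z) draws
# puts the plug-in point off the curved a-z ridge and makes pD (and hence
# DIC) jump between runs. Averaging in the identified coordinates and
# reconstructing a = kappa/(1-z) keeps the point on the likelihood
# manifold, so the plug-in deviance is reproducible.
def _point_coords(theta):
    return {
        "kappa": np.log(theta["a"] * (1.0 - theta["z"])),
        "z": _transform("z", theta["z"]),
        "v": np.log(theta["v"]),
        "t": theta["t"],
    }


def _point_estimate(sums, n):
    kappa = np.exp(sums["kappa"] / n)
    z = _back_transform("z", sums["z"] / n)
    return {
        "a": kappa / (1.0 - z),
        "z": z,
        "v": np.exp(sums["v"] / n),
        "t": sums["t"] / n,
    }


def fit_hddm(
    trials: pd.DataFrame,
    spec: ModelSpec,
    priors: Priors | None = None,
    config: MCMCConfig | None = None,
    apply_exclusion: bool = True,
) -> FitResult:
    """Fit one hierarchical model variant to a trial table.

    Only responded go trials enter the likelihood; the standard RT
    exclusion window is applied first unless ``apply_exclusion`` is False.
    Returns posterior draws of the group-level means and SDs, the deviance
    trace, DIC/pD, the posterior proportions for every group-varying
    parameter (first group vs second, in sorted label order), and split-R̂
    / effective-sample-size diagnostics. A fit with any group-level
    split-R̂ above 1.1 is flagged ``converged=False`` but still returned.
    """
    priors = priors or Priors()
    config = config or MCMCConfig()
    if apply_exclusion:
        trials, _ = exclusion_filter(trials)
    data = _FitData(trials)
    if spec.free_by_group and data.n_groups < 2:
        raise ValueError("group-varying model requires at least two group labels")

    n_keep = config.n_samples - config.burn_in
    names = []
    for p in PARAMS:
        if p in spec.free_by_group:
            names += [f"mu_{p}[{g}]" for g in data.groups]
        else:
            names.append(f"mu_{p}")
        names.append(f"sigma_{p}")
    posterior = {n: np.empty((config.n_chains, n_keep)) for n in names}
    deviance = np.empty((config.n_chains, n_keep))
    subj_sum = {q: np.zeros(data.n_subjects) for q in ("kappa", "z", "v", "t")}
    subj_draws = (
        {p: np.empty((config.n_chains, n_keep, data.n_subjects)) for p in PARAMS}
        if config.store_subject_draws
        else None
    )
    accept_rates = {}

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    window = 50
    errstate = np.errstate(over="ignore", invalid="ignore", divide="ignore")
    errstate.__enter__()
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        st = _SamplerState(data, spec, priors, rng)
        st.reset_counters()
        for it in range(config.adapt):
            st.sweep()
            if (it + 1) % window == 0:
                st.adapt_steps(window)
        st.reset_counters()
        kept = 0
        for it in range(config.n_samples):
            st.sweep()
            if it < config.burn_in:
                continue
            for p in PARAMS:
                if p in spec.free_by_group:
                    for gi, g in enumerate(data.groups):
                        posterior[f"mu_{p}[{g}]"][c, kept] = st.mu[p][gi]
                else:
                    posterior[f"mu_{p}"][c, kept] = st.mu[p][0]
                posterior[f"sigma_{p}"][c, kept] = st.sd[p]
                if subj_draws is not None:
                    subj_draws[p][c, kept] = st.theta[p]
            for q, val in _point_coords(st.theta).items():
                subj_sum[q] += val
            deviance[c, kept] = st.deviance()
            kept += 1
        denom = config.n_samples
        accept_rates[f"chain{c}"] = {
            k: float(np.mean(st.acc[k]) / denom) for k in st.acc
        }
        accept_rates[f"chain{c}"]["group_ridge"] = float(np.mean(st.acc_gridge) / denom)
        accept_rates[f"chain{c}"]["global_ridge"] = float(st.acc_globalridge / denom)
        accept_rates[f"chain{c}"]["global_tshift"] = float(st.acc_gtshift / denom)
        accept_rates[f"chain{c}"]["global_tskew"] = float(st.acc_gtskew / denom)

    errstate.__exit__(None, None, None)

    # point deviance at the posterior means of the identified coordinates
    n_total = config.n_chains * n_keep
    theta_bar = _point_estimate(subj_sum, n_total)
    tmp = _SamplerState.__new__(_SamplerState)
    tmp.data = data
    point_dev = -2.0 * float(
        np.sum(
            _SamplerState._loglik(
                tmp, theta_bar["a"], theta_bar["z"], theta_bar["v"], theta_bar["t"]
            )
        )
    )
    dic_val, p_d = dic(deviance, point_dev)

    import arviz as az

    # halve each chain so split-R-hat is defined even for a single chain
    half = n_keep // 2
    split = {
        k: v[:, : 2 * half].reshape(config.n_chains * 2, half)
        for k, v in posterior.items()
    }
    ds = az.convert_to_dataset(split)
    rhat_ds = az.rhat(ds)
    ess_ds = az.ess(ds)
    rhat = {k: float(rhat_ds[k].values) for k in posterior}
    ess = {k: float(ess_ds[k].values) for k in posterior}
    finite_rhat = [v for v in rhat.values() if np.isfinite(v)]
    converged = bool(all(v <= 1.1 for v in finite_rhat))

    return FitResult(
        spec=spec,
        groups=data.groups,
        subjects=data.subjects,
        posterior=posterior,
        deviance=deviance,
        point_deviance=point_dev,
        dic=dic_val,
        p_d=p_d,
        rhat=rhat,
        ess=ess,
        converged=converged,
        subject_posterior_mean=theta_bar,
        subject_draws=subj_draws,
        n_retained=n_keep,
        accept_rates=accept_rates,
    )


@dataclass
class ModelComparison:
    """DIC ranking over a set of fitted model variants."""

    table: pd.DataFrame
    winner_id: int
    results: dict  # model_id -> FitResult


def compare_models(
    trials: pd.DataFrame,
    specs: list[ModelSpec] | None = None,
    priors: Priors | None = None,
    config: MCMCConfig | None = None,
) -> ModelComparison:
    """Fit several model variants and rank them by DIC (lower wins).

    Each fit receives an independent seed spawned from ``config.seed``.
    Non-converged fits stay in the ranking but are flagged.
    """
    specs = specs or [ModelSpec.from_id(i) for i in (1, 2, 3, 4)]
    config = config or MCMCConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(len(specs))
    results = {}
    rows = []
    for spec, seed in zip(specs, seeds):
        sub_cfg = replace(config, seed=int(seed.generate_state(1)[0] % (2**31)))
        res = fit_hddm(trials, spec, priors, sub_cfg)
        results[spec.model_id] = res
        rows.append(
            {
                "model": spec.model_id,
                "free_by_group": "+".join(sorted(spec.free_by_group)) or "(none)",
                "dic": res.dic,
                "p_d": res.p_d,
                "converged": res.converged,
            }
        )
    table = pd.DataFrame(rows).sort_values("dic", ignore_index=True)
    return ModelComparison(table=table, winner_id=int(table.loc[0, "model"]), results=results)
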