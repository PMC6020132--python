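"""One-choice drift-diffusion (shifted-Wald) first-passage model.

Evidence accumulates with drift rate ``v`` from starting point ``z * a``
toward a single absorbing threshold ``a`` (unit diffusion coefficient).
The decision time — the first-passage time through the remaining distance
``a * (1 - z)`` — follows a Wald (inverse-Gaussian) distribution with mean
``mu = a * (1 - z) / v`` and shape ``lam = (a * (1 - z))**2``; the observed
response time adds a non-decision shift ``t``.

All times in this module are in seconds. The diffusion coefficient is fixed
at 1, which sets the scale of ``a`` and ``v``; only their ratios and the
products entering ``mu`` and ``lam`` are identified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DDMParams",
    "decision_density",
    "decision_cdf",
    "log_likelihood",
    "sample_rts",
    "mean_rt",
    "var_rt",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class DDMParams:
    """Parameters of the one-choice diffusion process.

    Attributes
    ----------
    a : float
        Decision threshold (evidence units), strictly positive.
    z : float
        Relative starting point, a fraction of ``a`` in the open
        interval (0, 1). Larger ``z`` means less evidence remains to be
        accumulated (a stronger prior bias toward responding).
    v : float
        Drift rate (evidence units per second), strictly positive.
    t : float
        Non-decision time in seconds (encoding and motor latency),
        non-negative.
    """

    a: float
    z: float
    v: float
    t: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and self.a > 0):
            raise ValueError(f"threshold a must be positive, got {self.a}")
        if not (np.isfinite(self.z) and 0 < self.z < 1):
            raise ValueError(f"relative start z must lie in (0, 1), got {self.z}")
        if not (np.isfinite(self.v) and self.v > 0):
            raise ValueError(f"drift rate v must be positive, got {self.v}")
        if not (np.isfinite(self.t) and self.t >= 0):
            raise ValueError(f"non-decision time t must be >= 0, got {self.t}")

    @property
    def mu(self) -> float:
        """Mean decision time ``a (1 - z) / v`` (seconds)."""
        return self.a * (1.0 - self.z) / self.v

    @property
    def lam(self) -> float:
        """Wald shape parameter ``(a (1 - z))**2``."""
        return (self.a * (1.0 - self.z)) ** 2

    def _frozen_wald(self):
        # scipy's invgauss(mu=m, scale=s) has mean m*s and shape s.
        return stats.invgauss(mu=self.mu / self.lam, scale=self.lam)


def wald_logpdf(d, mu, lam):
    """Log-density of the (unshifted) Wald at decision time ``d``.

    Broadcasts over arrays; callers guarantee ``d > 0``. Written out
    explicitly because the MCMC likelihood evaluates it millions of times.
    """
    return (
        0.5 * (np.log(lam) - _LOG_2PI)
        - 1.5 * np.log(d)
        - lam * (d - mu) ** 2 / (2.0 * mu**2 * d)
    )


def decision_density(rt, params: DDMParams):
    """Density (per second) of the observed response time.

    Zero at and below the non-decision time ``params.t``; integrates to 1
    over ``(t, inf)``. Accepts scalars or arrays.
    """
    rt = np.asarray(rt, dtype=float)
    d = rt - params.t
    out = np.zeros_like(d)
    ok = d > 0
    if np.any(ok):
        out[ok] = np.exp(wald_logpdf(d[ok], params.mu, params.lam))
    if out.ndim == 0:
        return float(out)
    return out


def decision_cdf(rt, params: DDMParams):
    """CDF of the observed response time (shifted inverse-Gaussian)."""
    rt = np.asarray(rt, dtype=float)
    d = np.clip(rt - params.t, 0.0, None)
    out = params._frozen_wald().cdf(d)
    if np.ndim(rt) == 0:
        return float(out)
    return out


def log_likelihood(rts, params: DDMParams) -> float:
    """Sum of log decision densities over ``rts``.

    Returns ``-inf`` (not an exception) if any rt falls at or below the
    non-decision time; an empty collection contributes 0 by convention.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        return 0.0
    d = rts - params.t
    if np.any(d <= 0):
        return -np.inf
    return float(np.sum(wald_logpdf(d, params.mu, params.lam)))


def sample_rts(params: DDMParams, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` response times (seconds), exactly, from the shifted Wald.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d = params._frozen_wald().rvs(size=n, random_state=rng)
    return params.t + d


def mean_rt(params: DDMParams) -> float:
    """Closed-form mean response time ``t + a (1 - z) / v`` (seconds)."""
    return params.t + params.mu


def var_rt(params: DDMParams) -> float:
    """Closed-form response-time variance ``mu**3 / lam`` (seconds^2)."""
    return params.mu**3 / params.lam
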