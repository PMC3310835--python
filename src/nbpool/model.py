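"""Core probability model for pooled (group) testing under inverse binomial sampling.

Plants are tested in pools of ``k``; a pool is positive iff at least one of
its members is positive, so a pool of size ``k`` tests positive with
probability ``theta = 1 - (1 - p)**k`` when the plant-level prevalence is
``p``.  Sampling is *inverse* (negative) binomial: pools are drawn and tested
one at a time until the ``r``-th positive pool is found.  The number of pools
tested to reach each positive pool is geometric, so the total number of pools
tested, ``T``, follows a negative binomial distribution with waiting
parameter ``r`` and success probability ``theta``, supported on ``t >= r``
(``T`` counts *all* pools tested, successes included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PoolingDesign",
    "ExperimentOutcome",
    "theta_from_p",
    "p_from_theta",
    "pools_pmf",
    "pools_cdf",
    "pools_quantile",
]


def _validate_pool_size(k: int) -> int:
    if k < 1 or int(k) != k:
        raise ValueError(f"pool size k must be a positive integer, got {k!r}")
    return int(k)


def theta_from_p(p, k: int):
    """Probability that a pool of size ``k`` tests positive.

    theta = 1 - (1 - p)**k.  Accepts scalars or arrays; strictly increasing
    in both ``p`` and ``k`` on (0, 1), and equal to ``p`` when ``k == 1``.
    """
    k = _validate_pool_size(k)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("prevalence p must lie in [0, 1]")
    out = 1.0 - (1.0 - p) ** k
    return out if out.ndim else float(out)


def p_from_theta(theta, k: int):
    """Prevalence implied by a pool-positivity probability: exact inverse of
    :func:`theta_from_p`, p = 1 - (1 - theta)**(1/k)."""
    k = _validate_pool_size(k)
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("theta must lie in [0, 1]")
    out = 1.0 - (1.0 - theta) ** (1.0 / k)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Negative binomial distribution of the total number of pools tested.
# scipy's nbinom counts failures only; T here counts all pools, so t = r + failures.
# ---------------------------------------------------------------------------

def _check_r_theta(r: int, theta: float) -> None:
    if r < 1 or int(r) != r:
        raise ValueError(f"r must be a positive integer, got {r!r}")
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must lie in (0, 1), got {theta!r}")


def pools_pmf(t, r: int, theta: float):
    """P(T = t): probability the r-th positive pool arrives on pool ``t``.

    pmf = C(t-1, r-1) theta^r (1-theta)^(t-r), supported on t >= r.  Values
    of ``t`` below ``r`` get probability 0.
    """
    _check_r_theta(r, theta)
    t = np.asarray(t)
    out = stats.nbinom.pmf(t - r, r, theta)
    return out if out.ndim else float(out)


def pools_cdf(t, r: int, theta: float):
    """P(T <= t) under the total-pools-tested convention."""
    _check_r_theta(r, theta)
    t = np.asarray(t)
    out = stats.nbinom.cdf(t - r, r, theta)
    return out if out.ndim else float(out)


def pools_quantile(q, r: int, theta: float):
    """Smallest t with P(T <= t) >= q; used to truncate infinite sums."""
    _check_r_theta(r, theta)
    q = np.asarray(q, dtype=float)
    out = stats.nbinom.ppf(q, r, theta) + r
    return out.astype(int) if out.ndim else int(out)


@dataclass(frozen=True)
class PoolingDesign:
    """Design parameters of an inverse binomial group-testing study.

    Parameters
    ----------
    p : float
        Assumed (planning) prevalence, in (0, 1).
    k : int
        Pool size (plants per pool), >= 1.
    alpha : float
        CI error rate; the interval has nominal coverage 1 - alpha.
    omega : float
        Desired full CI width, on the prevalence scale.
    gamma : float
        Assurance: the desired probability that the realized width W does
        not exceed ``omega``.  Must lie in [0.5, 1); 0.5 corresponds to the
        expected-width criterion with no assurance adjustment.

    Normal quantiles ``z_alpha`` (at 1 - alpha/2) and ``z_gamma`` (at gamma)
    are computed at full double precision; truncating them (e.g. to 1.96)
    systematically biases the resulting sample sizes upward.
    """

    p: float
    k: int
    alpha: float = 0.05
    omega: float = 0.01
    gamma: float = 0.5
    z_alpha: float = field(init=False)
    z_gamma: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must lie in (0, 1), got {self.p!r}")
        _validate_pool_size(self.k)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if not 0.0 < self.omega < 1.0:
            raise ValueError(f"omega must lie in (0, 1), got {self.omega!r}")
        if not 0.5 <= self.gamma < 1.0:
            raise ValueError(f"gamma must lie in [0.5, 1), got {self.gamma!r}")
        object.__setattr__(self, "z_alpha", float(stats.norm.ppf(1.0 - self.alpha / 2.0)))
        object.__setattr__(self, "z_gamma", float(stats.norm.ppf(self.gamma)))

    @property
    def theta(self) -> float:
        """Pool-positivity probability implied by (p, k)."""
        return float(theta_from_p(self.p, self.k))


@dataclass(frozen=True)
class ExperimentOutcome:
    """Observed data from one inverse binomial group-testing experiment.

    ``r`` positive pools were required; ``y[i]`` is the number of pools
    tested (inclusive) to reach the i-th positive pool, and ``t = sum(y)``
    is the total number of pools tested.  ``y`` is optional — only ``(r, t)``
    is needed for estimation, since T is sufficient.
    """

    r: int
    t: int
    y: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.r < 1 or int(self.r) != self.r:
            raise ValueError(f"r must be a positive integer, got {self.r!r}")
        if self.t < self.r:
            raise ValueError(f"total pools t={self.t} cannot be below r={self.r}")
        if self.y is not None:
            y = tuple(int(v) for v in self.y)
            if len(y) != self.r:
                raise ValueError("y must have exactly r entries")
            if any(v < 1 for v in y):
                raise ValueError("each per-positive count y_i must be >= 1")
            if sum(y) != self.t:
                raise ValueError(f"t={self.t} does not equal sum(y)={sum(y)}")
            object.__setattr__(self, "y", y)

    @classmethod
    def from_counts(cls, y: Sequence[int]) -> "ExperimentOutcome":
        y = tuple(int(v) for v in y)
        return cls(r=len(y), t=sum(y), y=y)
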