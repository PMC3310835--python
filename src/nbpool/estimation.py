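"""Point and interval estimation of prevalence from pooled inverse sampling.

Given ``r`` positive pools observed after testing ``t`` pools of size ``k``,
the MLE of the pool-positivity probability is ``theta_hat = r / t`` and the
prevalence MLE is ``p_hat = 1 - (1 - r/t)**(1/k)``.  Two interval types are
provided:

* Wald: ``p_hat +/- z * sqrt(v(p_hat) / r)`` with the delta-method variance
  ``v(p) = theta(p)**2 (1-p)**(2-k) / k**2``.  At small r the endpoints can
  fall outside [0, 1]; they are reported unclamped by default so that the
  recorded width always equals ``2 z sqrt(v(p_hat)/r)``.
* Clopper-Pearson: exact tail-inversion limits for theta via beta quantiles
  (equivalently F quantiles), transformed to the prevalence scale by the
  monotone map ``p = 1 - (1 - theta)**(1/k)``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .model import ExperimentOutcome, PoolingDesign

__all__ = [
    "PrevalenceEstimate",
    "estimate_prevalence",
    "wald_variance",
    "wald_ci",
    "clopper_pearson_ci",
]


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A prevalence estimate with its confidence interval.

    ``width`` is computed before any clamping (for Wald intervals it is
    exactly ``2 z sqrt(var_hat)``, even when an endpoint is negative);
    ``clamped`` records whether the reported endpoints were truncated
    to [0, 1] for display.
    """

    p_hat: float
    var_hat: float
    lower: float
    upper: float
    width: float
    ci_type: str
    r: int
    t: int
    k: int
    alpha: float
    clamped: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def estimate_prevalence(outcome: ExperimentOutcome, k: int) -> float:
    """Maximum likelihood estimate of prevalence: 1 - (1 - r/t)**(1/k).

    Equals 1 when every pool tested positive (t == r) and r/t when k == 1.
    """
    theta_hat = outcome.r / outcome.t
    return float(1.0 - (1.0 - theta_hat) ** (1.0 / k))


def wald_variance(p_hat: float, k: int, r: int) -> float:
    """Estimated asymptotic variance of the prevalence MLE, v(p_hat) / r.

    v(p) = theta(p)^2 (1-p)^(2-k) / k^2 with theta(p) = 1-(1-p)^k.  For
    k > 2 the variance diverges as p_hat -> 1 (returns +inf at p_hat = 1);
    for k = 1 it reduces to p_hat^2 (1 - p_hat) / r.
    """
    if r < 1:
        raise ValueError(f"r must be >= 1, got {r!r}")
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"p_hat must lie in [0, 1], got {p_hat!r}")
    if p_hat == 1.0:
        if k > 2:
            return float("inf")
        # k <= 2: (1-p)^(2-k) -> 0 (k=1) or 1 (k=2); theta -> 1
        return float((1.0 - p_hat) ** (2.0 - k) / k**2 / r)
    theta = 1.0 - (1.0 - p_hat) ** k
    return float(theta**2 * (1.0 - p_hat) ** (2.0 - k) / k**2 / r)


def _wald_arrays(r: int, t: np.ndarray, k: int, z: float):
    """Vectorized MLE, endpoints and width of the Wald interval over totals t.

    Used by the attainment-probability sum and the Monte Carlo engine.
    Degenerate replicates (t == r, p_hat = 1) get infinite width for k > 2.
    """
    t = np.asarray(t, dtype=float)
    theta_hat = r / t
    p_hat = 1.0 - (1.0 - theta_hat) ** (1.0 / k)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = theta_hat**2 * (1.0 - p_hat) ** (2.0 - k) / k**2 / r
    if k > 2:
        v = np.where(p_hat >= 1.0, np.inf, v)
    half = z * np.sqrt(v)
    return p_hat, p_hat - half, p_hat + half, 2.0 * half


def _cp_theta_limits(r: int, t: np.ndarray, alpha: float, form: str = "beta"):
    """Exact limits for theta inverting the negative binomial tails.

    Lower: Beta(alpha/2; r, t-r+1).  Upper: Beta(1-alpha/2; r, t-r), with
    the degenerate upper limit 1 when t == r.  ``form='f'`` computes the
    same quantiles through the F distribution via
    Beta_q(a, b) = a F_q(2a, 2b) / (b + a F_q(2a, 2b)).
    """
    t = np.asarray(t, dtype=float)
    b_lo = t - r + 1.0
    b_hi = t - r
    if form == "beta":
        th_lo = stats.beta.ppf(alpha / 2.0, r, b_lo)
        th_hi = np.where(
            b_hi > 0, stats.beta.ppf(1.0 - alpha / 2.0, r, np.where(b_hi > 0, b_hi, 1.0)), 1.0
        )
    elif form == "f":

        def beta_via_f(q, a, b):
            fq = stats.f.ppf(q, 2.0 * a, 2.0 * b)
            return a * fq / (b + a * fq)

        th_lo = beta_via_f(alpha / 2.0, r, b_lo)
        th_hi = np.where(
            b_hi > 0, beta_via_f(1.0 - alpha / 2.0, r, np.where(b_hi > 0, b_hi, 1.0)), 1.0
        )
    else:
        raise ValueError(f"form must be 'beta' or 'f', got {form!r}")
    return th_lo, th_hi


def _cp_arrays(r: int, t: np.ndarray, k: int, alpha: float, form: str = "beta"):
    """Vectorized Clopper-Pearson prevalence limits and width over totals t."""
    th_lo, th_hi = _cp_theta_limits(r, t, alpha, form)
    p_lo = 1.0 - (1.0 - th_lo) ** (1.0 / k)
    p_hi = 1.0 - (1.0 - th_hi) ** (1.0 / k)
    return p_lo, p_hi, p_hi - p_lo


def wald_ci(
    outcome: ExperimentOutcome, design: PoolingDesign, clamp: bool = False
) -> PrevalenceEstimate:
    """Wald confidence interval for prevalence (may exceed [0, 1] unclamped).

    The width is always the nominal ``2 z_alpha sqrt(var_hat)``; clamping
    (opt-in) truncates the *reported* endpoints only.
    """
    p_hat = estimate_prevalence(outcome, design.k)
    var_hat = wald_variance(p_hat, design.k, outcome.r)
    half = design.z_alpha * np.sqrt(var_hat)
    lower, upper = p_hat - half, p_hat + half
    clamped = False
    if clamp:
        clipped = (max(lower, 0.0), min(upper, 1.0))
        clamped = clipped != (lower, upper)
        lower, upper = clipped
    return PrevalenceEstimate(
        p_hat=p_hat,
        var_hat=var_hat,
        lower=float(lower),
        upper=float(upper),
        width=float(2.0 * half),
        ci_type="wald",
        r=outcome.r,
        t=outcome.t,
        k=design.k,
        alpha=design.alpha,
        clamped=clamped,
    )


def clopper_pearson_ci(
    outcome: ExperimentOutcome, design: PoolingDesign, form: str = "beta"
) -> PrevalenceEstimate:
    """Exact Clopper-Pearson interval on the prevalence scale.

    ``form`` selects the beta-quantile or F-quantile computation; the two
    agree to ~1e-12.  The upper limit is 1 when every pool was positive.
    """
    t = np.asarray([outcome.t])
    p_lo, p_hi, width = _cp_arrays(outcome.r, t, design.k, design.alpha, form)
    p_hat = estimate_prevalence(outcome, design.k)
    var_hat = wald_variance(p_hat, design.k, outcome.r)
    return PrevalenceEstimate(
        p_hat=p_hat,
        var_hat=var_hat,
        lower=float(p_lo[0]),
        upper=float(p_hi[0]),
        width=float(width[0]),
        ci_type=f"clopper_pearson_{form}",
        r=outcome.r,
        t=outcome.t,
        k=design.k,
        alpha=design.alpha,
    )
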