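"""Seeded Monte Carlo engine for validating the sample-size procedures.

Replicates the validation study design: for a chosen sample size ``r`` and
design, draw many sequential pooled experiments, form the CI each time, and
summarize coverage (fraction of intervals containing the true prevalence),
assurance (fraction with realized width <= omega), the overestimation
proportion of the MLE, and its mean squared error.

Experiments can be drawn at two levels that agree in distribution:

* ``theta_level`` — each waiting count Y_i ~ Geometric(theta) directly;
* ``plant_level`` — pools of k Bernoulli(p) plants, a pool positive iff at
  least one plant is positive, drawn sequentially until the r-th positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .estimation import _cp_arrays, _wald_arrays
from .model import ExperimentOutcome, PoolingDesign, pools_quantile, theta_from_p

__all__ = [
    "SimulationSummary",
    "draw_experiment",
    "draw_totals",
    "run_coverage_assurance",
    "run_bias_mse",
]

logger = logging.getLogger(__name__)

DEFAULT_N_REP = 40_000


@dataclass(frozen=True)
class SimulationSummary:
    """Monte Carlo summary for one (design, r, ci_type) cell."""

    coverage: float
    assurance: float
    prop_overestimate: float
    mse: float
    n_rep: int
    seed: int
    ci_type: str
    r: int
    p: float
    k: int
    omega: float
    n_degenerate: int = 0  # replicates with t == r (infinite Wald width for k > 2)

    def to_dict(self) -> dict:
        return asdict(self)


def draw_experiment(
    design: PoolingDesign,
    r: int,
    mode: str = "theta_level",
    seed: int | np.random.Generator = 0,
) -> ExperimentOutcome:
    """Draw one sequential pooled experiment, recording the waiting counts.

    ``theta_level`` draws each geometric waiting count directly;
    ``plant_level`` simulates every plant in every pool.  Both stop at the
    r-th positive pool.
    """
    if r < 1:
        raise ValueError(f"r must be >= 1, got {r!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "theta_level":
        y = rng.geometric(design.theta, size=r)
    elif mode == "plant_level":
        y = np.empty(r, dtype=int)
        for i in range(r):
            count = 0
            while True:
                count += 1
                if (rng.random(design.k) < design.p).any():
                    break
            y[i] = count
    else:
        raise ValueError(f"mode must be 'theta_level' or 'plant_level', got {mode!r}")
    return ExperimentOutcome.from_counts(y.tolist())


def draw_totals(
    design: PoolingDesign,
    r: int,
    n_rep: int,
    mode: str = "theta_level",
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Vectorized totals T for ``n_rep`` independent experiments.

    The plant-level path draws a (n_rep, m, k) block of plant statuses with
    m large enough that the r-th positive pool falls inside it except with
    probability < 1e-12 (the rare overflow replicates are re-drawn
    sequentially).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = design.theta
    if mode == "theta_level":
        return rng.negative_binomial(r, theta, size=n_rep) + r
    if mode != "plant_level":
        raise ValueError(f"mode must be 'theta_level' or 'plant_level', got {mode!r}")
    m = int(pools_quantile(1.0 - 1e-12, r, theta))
    pool_pos = (rng.random((n_rep, m, design.k)) < design.p).any(axis=2)
    cum = np.cumsum(pool_pos, axis=1)
    reached = cum >= r
    t = np.argmax(reached, axis=1) + 1
    overflow = ~reached[:, -1]
    for i in np.flatnonzero(overflow):
        t[i] = draw_experiment(design, r, mode="plant_level", seed=rng).t
    return t


def run_coverage_assurance(
    design: PoolingDesign,
    r: int,
    ci_type: str = "wald",
    n_rep: int = DEFAULT_N_REP,
    seed: int = 0,
) -> SimulationSummary:
    """Coverage / assurance / bias summary at sample size r.

    Draws ``n_rep`` totals T, computes the CI of ``ci_type`` for each, and
    counts coverage of the true p and attainment of the target width.
    Degenerate replicates (every pool positive) have infinite Wald width for
    k > 2 and count as non-attainment.
    """
    rng = np.random.default_rng(seed)
    t = draw_totals(design, r, n_rep, mode="theta_level", seed=rng)
    t_unique, inverse = np.unique(t, return_inverse=True)
    p_hat_u, _, _, _ = _wald_arrays(r, t_unique, design.k, design.z_alpha)
    if ci_type == "wald":
        _, lo_u, hi_u, w_u = _wald_arrays(r, t_unique, design.k, design.z_alpha)
    elif ci_type == "clopper_pearson":
        lo_u, hi_u, w_u = _cp_arrays(r, t_unique, design.k, design.alpha)
    else:
        raise ValueError(f"ci_type must be 'wald' or 'clopper_pearson', got {ci_type!r}")
    lo, hi, w, p_hat = lo_u[inverse], hi_u[inverse], w_u[inverse], p_hat_u[inverse]
    n_degenerate = int(np.sum(t == r))
    if n_degenerate:
        logger.info("%d of %d replicates were degenerate (t == r)", n_degenerate, n_rep)
    summary = SimulationSummary(
        coverage=float(np.mean((lo <= design.p) & (design.p <= hi))),
        assurance=float(np.mean(w <= design.omega)),
        prop_overestimate=float(np.mean(p_hat > design.p)),
        mse=float(np.mean((p_hat - design.p) ** 2)),
        n_rep=n_rep,
        seed=seed,
        ci_type=ci_type,
        r=r,
        p=design.p,
        k=design.k,
        omega=design.omega,
        n_degenerate=n_degenerate,
    )
    logger.info(
        "p=%g k=%d r=%d %s: coverage=%.4f assurance=%.4f",
        design.p, design.k, r, ci_type, summary.coverage, summary.assurance,
    )
    return summary


def run_bias_mse(
    p: float,
    grid: list[tuple[int, int]],
    alpha: float = 0.05,
    omega: float = 0.01,
    n_rep: int = DEFAULT_N_REP,
    seed: int = 0,
) -> list[SimulationSummary]:
    """Overestimation proportion and MSE of the MLE over a (k, r) grid.

    The prevalence MLE is right-biased under pooled inverse sampling; both
    the overestimation proportion and the MSE shrink as r grows.  Output is
    ordered by (k, r).
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    out = []
    for i, (k, r) in enumerate(sorted(grid)):
        design = PoolingDesign(p=p, k=k, alpha=alpha, omega=omega)
        out.append(
            run_coverage_assurance(design, r, ci_type="wald", n_rep=n_rep, seed=seed + i)
        )
    return out
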