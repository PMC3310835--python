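"""Regenerate the reference sample-size and simulation tables.

The package carries the printed values of the five reference tables as CSV
fixtures (``nbpool/data/table{1..5}.csv``):

1. preliminary sizes r0 and attainment probabilities P(W <= omega) on a
   k=25, omega=0.007, 95% CI grid;
2. the 324-cell sample-size grid (three methods x gamma in {0.5, 0.8, 0.9}
   x nine prevalences x four target widths, k=40, 95% CI);
3.-5. Monte Carlo coverage/assurance at the method-3 / method-2 / method-1
   sample sizes (40,000 replicates per cell; the study computed Wald CIs
   for all three tables — the tables differ only in which procedure chose r).

Each ``regenerate_*`` function recomputes the grid from scratch;
``diff_table`` merges the result against the printed fixture.
"""

from __future__ import annotations

import importlib.resources as resources
import logging

import numpy as np
import pandas as pd

from .model import PoolingDesign
from .sample_size import (
    analytic_pool_count,
    attainment_probability,
    preliminary_pool_count,
    search_pool_count,
)
from .simulation import run_coverage_assurance

__all__ = [
    "printed_table",
    "regenerate_table1",
    "regenerate_table2",
    "regenerate_simulation_table",
    "diff_table",
    "TABLE1_DESIGN",
    "TABLE2_GRID",
]

logger = logging.getLogger(__name__)

#: recovered design of the preliminary-size table: k=25, omega=0.007, 95% CI
TABLE1_DESIGN = {"k": 25, "omega": 0.007, "alpha": 0.05}
TABLE1_PS = [0.005, 0.0075, 0.01, 0.0125, 0.015, 0.0175, 0.02, 0.0225, 0.025]
TABLE1_INCREMENTS = (0, 10, 20, 40)

#: the 108-design sample-size grid (k=40, 95% CI)
TABLE2_GRID = {
    "k": 40,
    "alpha": 0.05,
    "gammas": [0.5, 0.8, 0.9],
    "ps": TABLE1_PS,
    "omegas": [0.007, 0.008, 0.009, 0.010],
}

#: which sample-size procedure chose r in each simulation table
SIMULATION_TABLE_METHOD = {3: "analytic", 4: "wald", 5: "clopper_pearson"}


def printed_table(n: int) -> pd.DataFrame:
    """Load the packaged printed values of reference table ``n`` (1-5)."""
    if n not in (1, 2, 3, 4, 5):
        raise ValueError(f"table id must be 1..5, got {n!r}")
    ref = resources.files("nbpool").joinpath(f"data/table{n}.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def regenerate_table1(tail: float = 1e-10) -> pd.DataFrame:
    """Preliminary sizes and Wald attainment probabilities (k=25, omega=0.007)."""
    rows = []
    for p in TABLE1_PS:
        design = PoolingDesign(p=p, **TABLE1_DESIGN)
        r0 = preliminary_pool_count(design).r_star
        for inc in TABLE1_INCREMENTS:
            r = r0 + inc
            prob = attainment_probability(r, design, ci_type="wald", tail=tail)
            rows.append({"p": p, "r": r, "prob": prob})
    return pd.DataFrame(rows)


def _r_for(method: str, design: PoolingDesign) -> tuple[int, float | None]:
    if method == "analytic":
        return analytic_pool_count(design).r_star, None
    ci_type = {"clopper_pearson": "clopper_pearson", "wald": "wald"}[method]
    res = search_pool_count(design, ci_type=ci_type, warm_start=True)
    return res.r_star, res.attained_prob


def regenerate_table2() -> pd.DataFrame:
    """The full 324-cell sample-size grid for the three procedures (k=40)."""
    g = TABLE2_GRID
    rows = []
    for gamma in g["gammas"]:
        for p in g["ps"]:
            for omega in g["omegas"]:
                design = PoolingDesign(
                    p=p, k=g["k"], alpha=g["alpha"], omega=omega, gamma=gamma
                )
                for method in ("analytic", "clopper_pearson", "wald"):
                    r, prob = _r_for(method, design)
                    rows.append(
                        {
                            "method": method,
                            "gamma": gamma,
                            "p": p,
                            "omega": omega,
                            "r": r,
                            "attained_prob": prob,
                        }
                    )
            logger.info("table 2: gamma=%s p=%s done", gamma, p)
    return pd.DataFrame(rows)


def regenerate_simulation_table(
    n: int, n_rep: int = 40_000, seed: int = 0, cells: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Monte Carlo coverage/assurance at one procedure's sample sizes.

    ``n`` selects the procedure (3: analytic, 4: Wald search, 5:
    Clopper-Pearson search).  ``cells`` restricts the grid (columns gamma, p,
    omega); by default the full printed grid for that table is rerun.  Each
    cell gets its own deterministic substream derived from ``seed``.
    Intervals are Wald for every table, matching the reference study.
    """
    method = SIMULATION_TABLE_METHOD[n]
    if cells is None:
        cells = printed_table(n)[["gamma", "p", "omega"]].drop_duplicates()
    rows = []
    for i, cell in enumerate(cells.itertuples(index=False)):
        design = PoolingDesign(
            p=cell.p,
            k=TABLE2_GRID["k"],
            alpha=TABLE2_GRID["alpha"],
            omega=cell.omega,
            gamma=cell.gamma,
        )
        r, _ = _r_for(method, design)
        cell_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)
        s = run_coverage_assurance(design, r, ci_type="wald", n_rep=n_rep, seed=cell_seed)
        rows.append(
            {
                "method": method,
                "gamma": cell.gamma,
                "p": cell.p,
                "omega": cell.omega,
                "r": r,
                "coverage": s.coverage,
                "assurance": s.assurance,
            }
        )
    return pd.DataFrame(rows)


def _width_boundary_margin(r: int, design: PoolingDesign, ci_type: str) -> float:
    """Smallest |W - omega| over the totals adjacent to the indicator boundary.

    When this margin is below ~1e-5 the inclusion of that total's probability
    mass in P(W <= omega) depends on arithmetic details, so the search result
    at this design is numerically fragile.
    """
    from .estimation import _cp_arrays, _wald_arrays
    from .model import pools_quantile

    t_max = pools_quantile(1.0 - 1e-10, r, design.theta)
    t = np.arange(r, t_max + 1, dtype=float)
    if ci_type == "wald":
        _, _, _, w = _wald_arrays(r, t, design.k, design.z_alpha)
    else:
        _, _, w = _cp_arrays(r, t, design.k, design.alpha)
    ok = (w <= design.omega).astype(int)
    idx = np.flatnonzero(np.diff(ok))
    if idx.size == 0:
        return float("inf")
    near = np.unique(np.concatenate([idx, idx + 1]))
    return float(np.min(np.abs(w[near] - design.omega)))


def diff_table(regenerated: pd.DataFrame, printed: pd.DataFrame) -> pd.DataFrame:
    """Merge a regenerated table against its printed fixture.

    Joins on the shared key columns; numeric result columns get ``*_regen``
    / ``*_printed`` pairs plus a ``diff_<col>``.  For sample-size tables a
    ``near_boundary`` flag marks cells where sub-1e-5 numerical differences
    can legitimately move the integer: analytic cells with the raw value's
    fractional part within 0.02 of 0.5; search cells where the attainment
    probability at r-1 is within 1e-3 of gamma, or where some total t has a
    CI width within 1e-5 of omega (so the probability mass of that single t
    — a lump of order 1e-2 — is not reproducible across arithmetics and the
    first crossing of gamma can shift across a local dip).
    """
    value_cols = [c for c in ("prob", "coverage", "assurance") if c in printed.columns]
    if not value_cols and "r" in printed.columns:
        value_cols = ["r"]
    keys = [c for c in ("method", "gamma", "p", "omega", "r") if c in printed.columns]
    keys = [k for k in keys if k not in value_cols]
    merged = regenerated.merge(
        printed, on=keys, how="outer", suffixes=("_regen", "_printed"), indicator=True
    ).rename(columns={"_merge": "presence"})
    for c in value_cols:
        merged[f"diff_{c}"] = merged[f"{c}_regen"] - merged[f"{c}_printed"]
    if "r" in value_cols and "method" in merged.columns:
        flags = []
        for row in merged.itertuples(index=False):
            flag = False
            if row.presence == "both" and row.method == "analytic":
                design = PoolingDesign(
                    p=row.p,
                    k=TABLE2_GRID["k"],
                    alpha=TABLE2_GRID["alpha"],
                    omega=row.omega,
                    gamma=row.gamma,
                )
                from .sample_size import _v_and_vprime  # raw, unrounded value

                v, v_prime = _v_and_vprime(design.p, design.k)
                z_a, z_g = design.z_alpha, design.z_gamma
                if z_g == 0.0:
                    raw = 4.0 * z_a**2 * v / design.omega**2
                else:
                    u = (
                        -z_a * np.sqrt(v)
                        + np.sqrt(z_a**2 * v + z_g * z_a * v_prime * design.omega)
                    ) / (z_g * z_a * v_prime)
                    raw = 1.0 / u**2
                flag = abs(raw - np.floor(raw) - 0.5) < 0.02
            elif row.presence == "both":
                design = PoolingDesign(
                    p=row.p,
                    k=TABLE2_GRID["k"],
                    alpha=TABLE2_GRID["alpha"],
                    omega=row.omega,
                    gamma=row.gamma,
                )
                ci = "wald" if row.method == "wald" else "clopper_pearson"
                r_printed = int(row.r_printed)
                if r_printed > 1:
                    prob_below = attainment_probability(r_printed - 1, design, ci_type=ci)
                    flag = abs(prob_below - design.gamma) < 1e-3
                if not flag:
                    lo = min(r_printed, int(row.r_regen))
                    hi = max(r_printed, int(row.r_regen))
                    flag = any(
                        _width_boundary_margin(r, design, ci) < 1e-5
                        for r in range(lo, hi + 1)
                    )
            flags.append(flag)
        merged["near_boundary"] = flags
    return merged
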