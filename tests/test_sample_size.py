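import numpy as np
import pytest

from nbpool.model import PoolingDesign
from nbpool.sample_size import (
    analytic_pool_count,
    attainment_probability,
    individual_pool_count,
    preliminary_pool_count,
    required_pools,
    search_pool_count,
    width_distribution,
)
from nbpool.simulation import draw_totals
from nbpool.estimation import _wald_arrays


def design(p, k, omega, gamma=0.5, alpha=0.05):
    return PoolingDesign(p=p, k=k, alpha=alpha, omega=omega, gamma=gamma)


# ---------------------------------------------------------------- preliminary

@pytest.mark.parametrize(
    "p, k, omega, expected",
    [
        (0.02, 40, 0.008, 99),
        (0.01, 40, 0.007, 31),
        (0.0125, 25, 0.007, 49),
    ],
)
def test_preliminary_size(p, k, omega, expected):
    assert preliminary_pool_count(design(p, k, omega)).r_star == expected


def test_width_distribution_is_positive():
    wd = width_distribution(design(0.01, 40, 0.008), r=36)
    assert wd.mean_w > 0 and wd.sd_w >= 0 and wd.v > 0


# ----------------------------------------------------------------- attainment

@pytest.mark.parametrize(
    "r, expected",
    [(49, 0.4825564), (89, 0.9962656)],
)
def test_attainment_probability_reference_values(r, expected):
    d = design(0.0125, 25, 0.007)
    assert attainment_probability(r, d, ci_type="wald") == pytest.approx(
        expected, abs=1e-4
    )


def test_attainment_probability_matches_monte_carlo(mc_seed):
    """The truncated sum equals a brute-force simulated estimate."""
    d = design(0.0125, 25, 0.007)
    r, n = 59, 40_000
    exact = attainment_probability(r, d, ci_type="wald")
    totals = draw_totals(d, r, n, seed=mc_seed)
    _, _, _, widths = _wald_arrays(r, np.asarray(totals, float), d.k, d.z_alpha)
    mc = np.mean(widths <= d.omega)
    se = np.sqrt(exact * (1 - exact) / n)
    assert abs(mc - exact) <= 4 * se
    assert 0.0 <= exact <= 1.0


def test_attainment_nondecreasing_in_r():
    d = design(0.015, 40, 0.008, gamma=0.9)
    probs = [attainment_probability(r, d, ci_type="wald") for r in range(5, 120, 5)]
    assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))


def test_attainment_near_half_at_preliminary_size():
    """The expected-width size attains the target only about half the time,
    and usually slightly less."""
    ps = [0.005, 0.0075, 0.01, 0.0125, 0.015, 0.0175, 0.02, 0.0225, 0.025]
    below = 0
    for p in ps:
        d = design(p, 25, 0.007)
        r0 = preliminary_pool_count(d).r_star
        prob = attainment_probability(r0, d, ci_type="wald")
        assert 0.40 < prob < 0.55
        below += prob < 0.5
    assert below == 8  # all but one of the nine designs fall short of 0.5


# --------------------------------------------------------------------- search

@pytest.mark.parametrize(
    "p, omega, gamma, ci_type, expected",
    [
        (0.01, 0.008, 0.9, "clopper_pearson", 39),
        (0.01, 0.008, 0.9, "wald", 38),
        (0.005, 0.007, 0.5, "clopper_pearson", 9),
        (0.005, 0.007, 0.5, "wald", 9),
    ],
)
def test_search_reference_values(p, omega, gamma, ci_type, expected):
    res = search_pool_count(design(p, 40, omega, gamma), ci_type=ci_type)
    assert res.r_star == expected
    assert res.attained_prob >= gamma
    prob_below = attainment_probability(res.r_star - 1, res.design, ci_type=ci_type)
    assert prob_below < gamma


@pytest.mark.parametrize("ci_type", ["wald", "clopper_pearson"])
@pytest.mark.parametrize("p, omega, gamma", [(0.01, 0.008, 0.9), (0.02, 0.009, 0.8)])
def test_warm_start_matches_unit_step_search(p, omega, gamma, ci_type):
    d = design(p, 40, omega, gamma)
    plain = search_pool_count(d, ci_type=ci_type, warm_start=False)
    warm = search_pool_count(d, ci_type=ci_type, warm_start=True)
    assert warm.r_star == plain.r_star


def test_search_reports_nonconvergence():
    with pytest.raises(RuntimeError, match="no r <="):
        search_pool_count(design(0.01, 40, 0.008, 0.9), r_max=5)


# ------------------------------------------------------------------- analytic

@pytest.mark.parametrize(
    "p, omega, gamma, expected",
    [
        (0.01, 0.008, 0.9, 36),
        (0.02, 0.008, 0.8, 116),
    ],
)
def test_analytic_size_reference_values(p, omega, gamma, expected):
    assert analytic_pool_count(design(p, 40, omega, gamma)).r_star == expected


@pytest.mark.parametrize("p, k, omega", [(0.01, 40, 0.008), (0.02, 25, 0.01)])
def test_analytic_reduces_to_preliminary_without_assurance(p, k, omega):
    d = design(p, k, omega, gamma=0.5)
    assert analytic_pool_count(d).r_star == preliminary_pool_count(d).r_star


def test_method_ordering_spot_checks():
    for p, omega, gamma in [(0.01, 0.008, 0.9), (0.025, 0.007, 0.8)]:
        d = design(p, 40, omega, gamma)
        r_a = analytic_pool_count(d).r_star
        r_w = search_pool_count(d, ci_type="wald", warm_start=True).r_star
        r_cp = search_pool_count(d, ci_type="clopper_pearson", warm_start=True).r_star
        assert r_cp >= r_w >= r_a
        assert r_w - r_a <= 5


# ----------------------------------------------------------------- individual

def test_individual_size_no_assurance():
    # 4 z^2 p^2 (1-p) / omega^2 = 55.3 -> 55
    d = design(0.1, 1, 0.05, gamma=0.5)
    assert individual_pool_count(d).r_star == 55


@pytest.mark.parametrize("p, omega, gamma", [(0.05, 0.02, 0.8), (0.1, 0.05, 0.9)])
def test_individual_equals_analytic_at_unpooled(p, omega, gamma):
    d = design(p, 1, omega, gamma)
    assert individual_pool_count(d).r_star == analytic_pool_count(d).r_star


def test_individual_requires_unpooled_design():
    with pytest.raises(ValueError):
        individual_pool_count(design(0.1, 5, 0.05))


def test_size_monotone_in_width_and_assurance():
    for method in ("analytic", "wald"):
        sizes_w = [
            required_pools(design(0.01, 40, om, 0.8), method).r_star
            for om in (0.007, 0.008, 0.009, 0.010)
        ]
        assert all(b <= a for a, b in zip(sizes_w, sizes_w[1:]))
        sizes_g = [
            required_pools(design(0.01, 40, 0.008, g), method).r_star
            for g in (0.5, 0.8, 0.9)
        ]
        assert all(b >= a for a, b in zip(sizes_g, sizes_g[1:]))


def test_required_pools_rejects_unknown_method():
    with pytest.raises(ValueError):
        required_pools(design(0.01, 40, 0.008), "bayes")
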