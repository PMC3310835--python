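# Methods

## Model

Individuals carry a rare binary trait with prevalence `p`. They are tested
in pools of fixed size `k` with a perfect assay (sensitivity = specificity
= 1); a pool is positive iff it contains at least one positive individual,
so pool positivity is `θ(p) = 1 − (1−p)^k`. Pools are drawn by simple random
sampling and tested sequentially until the r-th positive pool (inverse /
negative binomial sampling). The number of pools tested to reach each
positive pool is Geometric(θ) on {1, 2, …}; their sum `T`, the total number
of pools tested, is sufficient for `θ` and follows a negative binomial
distribution with waiting parameter `r`, parameterized here on the
total-count support `t ≥ r`:

    P(T = t) = C(t−1, r−1) θ^r (1−θ)^(t−r).

All negative binomial, beta, F and normal quantile computations are
delegated to `scipy.stats` (scipy's `nbinom` counts failures, so the wrapper
shifts by `r`). Normal quantiles are kept at full double precision; a
truncated `z = 1.96` visibly inflates the larger sample sizes.

## Estimation

MLE: `θ̂ = r/t`, `p̂ = 1 − (1 − r/t)^(1/k)`. Asymptotic variance (delta
method): `Var(p̂) ≈ v(p)/r` with

    v(p)  = θ² (1−p)^(2−k) / k²,
    v′(p) = [2kθ(1−p) + (k−2) θ² (1−p)^(1−k)] / k².

Wald interval: `p̂ ± z_{1−α/2} √(v(p̂)/r)`, full width
`W = 2 z √(v(p̂)/r)`. At small `r` the endpoints can leave [0, 1]; they are
reported unclamped by default so that the recorded width is always the
nominal one, with clamping available as a reporting flag that never alters
the stored width.

Exact (Clopper–Pearson) interval for `θ`, by inverting the negative binomial
tails through the beta distribution:

    θ_L = Beta^{-1}(α/2; r, t−r+1),   θ_U = Beta^{-1}(1−α/2; r, t−r),

with `θ_U = 1` when `t = r`. The F-distribution form uses
`Beta^{-1}(q; a, b) = a F_q(2a,2b) / (b + a F_q(2a,2b))` and agrees with the
beta form to well below 1e-9 (tested). Prevalence-scale limits follow from
the monotone transform `p = 1 − (1−θ)^{1/k}`, which preserves
`p_L ≤ p̂ ≤ p_U`. The shape parameterization was selected by validating the
searched sample sizes against the packaged reference grid (it reproduces
the exact-method column throughout); the (r+1, t−r) variant does not.

### Degenerate outcomes

At `t = r` (every pool positive) `p̂ = 1`; for `k > 2` the variance formula
diverges, so the Wald width is reported as `+inf` and such replicates count
as non-attainment in all width events. For `k ≤ 2` the formula is evaluated
as written. The exact upper limit is 1. The probability of `t = r` is
negligible in the design region (θ well below 1, r ≥ 2) but the code paths
are exercised by tests.

## Sample-size procedures

Target: the smallest number of positive pools `r` such that
`P(W ≤ ω) ≥ γ`, with assurance `γ ∈ [0.5, 1)`.

* **Expected-width (preliminary) size.** `r₀ = round(4 z² v(p) / ω²)`.
  Attains the target roughly — usually slightly less than — half the time.
* **Attainment probability.** `P(W ≤ ω | r) = Σ_t P(T=t) 1{W(r,t) ≤ ω}`,
  truncated at the `1 − tail` quantile of `T` with `tail = 1e-10` by default
  (exposed as a parameter). The truncation error is bounded by `tail`, far
  below the 1e-4 precision at which the reference probabilities are
  reproduced. Widths are Wald (plug-in `p̂(r,t)`) or exact, per `ci_type`.
* **Incremental search (exact and Wald variants).** Start at `r_start = 2`
  (at `r = 1` the exact upper limit is degenerate at `t = r`) and increase
  by one until `P(W ≤ ω) ≥ γ`, returning the first crossing. A warm-start
  variant starts at `r₀` and scans down/up; it returns the same minimum and
  is used for bulk grid regeneration.
* **Analytic size.** `W` is asymptotically normal with mean `2z√(v/r)` and
  SD `z|v′|/r`, so requiring the γ-quantile of `W` to equal `ω` gives
  `2 z_α √v /√r + z_γ z_α v′ / r = ω`, a quadratic in `u = 1/√r`:

      u = [−z_α√v + √(z_α²v + z_γ z_α v′ ω)] / (z_γ z_α v′),  r* = round(1/u²).

  At `γ = 0.5` (`z_γ = 0`) the limit is the expected-width formula, taken
  as an explicit branch. At `k = 1` it specializes to individual testing
  (`θ = p`), where the no-assurance case is the classical inverse-sampling
  size `4 z² p² (1−p)/ω²`.

Rounding of the closed forms is to the **nearest** integer (half away from
zero), not the ceiling: the reference grids are reproduced under nearest
(e.g. raw values 49.42 → 49, 31.47 → 31, 99.35 → 99, 35.67 → 36) and fail
under ceiling.

### Non-monotonicity of the attainment probability

`P(W ≤ ω | r)` increases in `r` in the large but not cell by cell: the set
of totals `t` whose width meets `ω` changes discretely with `r`, and when a
single `t` with non-trivial probability mass (lumps of order 1e-2) exits the
set, the probability dips briefly just after first crossing `γ` (e.g. Wald,
k=40, p=0.025, ω=0.008, γ=0.8: 0.8005 at r=183, 0.7898 at 184, 0.8024 at
185). The search therefore documents its stopping rule explicitly: the
default is the strict first crossing; `lookahead = n` instead requires the
criterion to hold for `n` further sizes, returning the smallest `r` from
which the assurance holds onward. In two grid cells out of 324 the boundary
total's width sits within ~3e-6 of `ω`, so whether its mass counts is not
reproducible across arithmetics and the first crossing can shift by the
width of the dip (two pools); the table diff report flags such cells
(`near_boundary`).

## Monte Carlo validation

For a design and sample size `r`, the engine draws `n_rep` totals
`T = r + NegativeBinomial(r, θ)` (default `n_rep = 40,000`, matching the
reference study), computes the chosen interval per replicate, and reports:
coverage (fraction of intervals containing the true `p`), assurance
(fraction with `W ≤ ω`), the proportion of replicates with `p̂ > p` (the
MLE's right bias), and the MSE of `p̂`. One `numpy` PCG64 generator is
seeded per run; grid drivers derive an independent substream per cell from
the base seed via `SeedSequence`, so every summary is exactly reproducible
from (seed, parameters). Degenerate replicates are counted and logged.

The simulation reference tables were all computed with **Wald** intervals;
the three tables differ only in which procedure chose `r` (analytic, Wald
search, exact search). This is established empirically: the printed
assurances match the exact Wald attainment probability at the corresponding
sample sizes across spot checks of all three tables (including the
exact-search table, where exact-interval assurance would be ~0.03 lower),
and the exact-search table's coverage is ~0.95 rather than conservative.
`run_coverage_assurance` nevertheless supports exact intervals for general
use.

A plant-level generator (every individual Bernoulli(p), pools of `k`,
sequential testing) is provided alongside the geometric waiting-time
generator; the two agree in distribution (tested via the mean `r/θ` at
40,000 replicates) and the waiting-time form is used for bulk simulation.

### What the simulations do and do not show

The generator emulates the model's own assumptions: equal pool sizes, a
perfect diagnostic assay, independent individuals, constant prevalence.
Passing validation therefore demonstrates internal consistency of the
sample-size procedures (nominal coverage, assurance within Monte Carlo
error), not robustness to imperfect assays, clustered sampling, or
heterogeneous prevalence — all outside the model. Dilution effects in large
pools are likewise not modelled; `k` should be chosen so the assay remains
reliable.

## Problem sizes and runtimes

Everything here is cheap: closed forms are O(1); one attainment evaluation
sums over ~10³ totals (vectorized, with two beta quantile calls per total in
the exact variant); a full 324-cell grid regeneration takes a few seconds
using warm-started searches; a 40,000-replicate simulation cell takes well
under a second because intervals are computed once per unique total. The
test suite and the acceptance script each run end to end in under a minute
on one core.

## Known limitations

* Perfect-assay assumption; no sensitivity/specificity adjustment.
* The analytic size relies on the delta-method normal approximation of `W`
  and can sit a few pools below the Wald search (bounded at 5 pools across
  the reference grid); the exact-interval search is conservative.
* The attainment probability's local dips mean "smallest r with
  P(W ≤ ω) ≥ γ" is ambiguous at razor-thin boundary cells; see the
  stopping-rule discussion above.
* Wald intervals can have negative lower endpoints at small `r`; they are
  reported unclamped by default.
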