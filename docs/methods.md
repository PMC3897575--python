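# Methods

## Sampling model

The unit of inference is one allele at one locus in a closed population of
`M` diploid individuals. Two parameters describe it: the allele frequency
`p` (so the population holds exactly `2Mp` copies — an integer) and the
homozygote frequency `P` (exactly `MP` homozygous individuals). Any pair
must satisfy `max(0, 2p − 1) ≤ P ≤ p`: an allele's copies can all sit in
heterozygotes only while copies do not outnumber individuals. The package
stores both parameters as the integer counts `2Mp` and `MP`; all grid
construction, feasibility checks and equality tests happen on integers,
never on floats.

Sampling `N ≤ M` individuals uniformly without replacement partitions the
draw across the three genotype classes (homozygote, heterozygous carrier,
non-carrier), giving a multivariate hypergeometric law for the class
counts. The observed copy count `K = 2x₂ + x₁` has pmf equal to a sum over
the feasible number of sampled homozygotes `x₂`, with integer bounds
derived from the six class-count constraints:

    L(k) = max(0, k − N, ⌈(k − m₁)/2⌉),   U(k) = min(m₂, ⌊k/2⌋, m₀ − N + k).

An empty range (`L > U`) means `Pr(K = k) = 0`; this is a legitimate
outcome, not an error. The bounds were transcribed and then verified by
exhaustive enumeration of every feasible `(p, P)` pair and every `N` for
all `M ≤ 12`, in exact rational arithmetic (`tests/test_distribution.py`,
`tests/test_acceptance.py`).

Moments used throughout: `E[p̂] = p` (sampling is unbiased) and
`Var(p̂) = ((M − N)/(M − 1)) · (p(1 − p) + (P − p²)) / (2N)`. The closed
form is asserted against the pmf-derived variance to 1e−12 across all
scenario grids at `M = 50`; the degenerate `M = 1` census is defined to
have zero variance. As `M → ∞` at HWE the pmf converges to
`Binomial(2N, p)` (total-variation distance < 1e−3 at `M = 10⁵, N = 20`).

## Numerics

Binomial coefficients are evaluated through a cached log-factorial table
(`scipy.special.gammaln`), and pmf terms are accumulated on the
probability scale — every term is a probability, so overflow is
impossible and underflow only zeroes terms below ~1e−308, far outside any
tail that matters at usable α. Acceptance-region decisions compare tail
sums against `α/2 + 1e−12`; the epsilon implements the non-strict tie rule
(a tail exactly equal to `α/2` keeps its boundary point inside the
region, favouring wider regions and preserving the coverage guarantee).
An exact `fractions.Fraction` mode exists solely for oracle comparisons on
tiny instances.

## Confidence sets by test inversion

For a hypothesised `(p, P)` the equal-tail acceptance region is
`[k_lo, k_hi]` with `k_lo` the largest integer keeping `Pr(K < k_lo) ≤ α/2`
and `k_hi` the smallest keeping `Pr(K > k_hi) ≤ α/2`. Membership of an
observation reduces to two tail statistics — `k ∈ [k_lo, k_hi]` iff
`Pr(K ≤ k) > α/2` and `Pr(K ≥ k) > α/2` — which is how the sweeps evaluate
thousands of candidates at once.

The confidence set for `p` under a known homozygosity rule collects every
feasible lattice `p` (the population must contain at least the observed
copies of the allele and of its complement) whose region contains the
observation. The reported interval is the hull `[min, max]` of that set;
the raw accepted set is retained on the result object because the set can
in principle have interior gaps, making the hull conservative. When the
accepted set is empty, α is halved until it is not ("α-relaxation"); the
final level is reported as `effective_alpha`. Halving is one deterministic
choice among many; any decreasing schedule terminates because as α → 0
each region grows to the candidate's full attainable range `[k_min,
k_max]`. Observations outside every feasible candidate's attainable range
raise `ImpossibleObservationError` — they indicate corrupt input. One
subtlety: because regions are interval-valued, an interior copy count with
zero probability under a candidate (e.g. an odd count under the
no-heterozygote rule `P = p`) is still *accepted* by that candidate; such
observations get valid, if conservative, intervals.

This construction makes the coverage guarantee structural: the true
`(p, P)` accepts at least `1 − α` of the observations it can generate, so
`Σ_k Pr(K = k | truth) · 1[p ∈ CI(k)] ≥ 1 − α` identically. The test suite
verifies this exactly for every grid truth of all three scenarios at
`(M = 50, N = 10)` and `(M = 100, N = 30)`, and for the joint
unknown-homozygosity region at `(M = 30, N = 10)`.

### Tail convention and the one irreproducible design value

A tail rule that guarantees coverage must keep strictly more than `α/2`
probability at-or-beyond the observation on both sides. Five of the six
published minimum sample sizes for `M = 1000` (22, 26, 94, 94, 285)
reproduce exactly under this rule, several through margins of less than
0.002 in worst-case length, which pins the convention. The sixth (HWE,
target 0.1) computes to `N = 50` here rather than the published 49: at
`N = 49`, observing `k = 49` gives `Pr(K ≥ 49 | p = 0.4, P = 0.16) =
0.0254356` (exact), which exceeds `α/2 = 0.025`, so `p = 0.4` cannot be
rejected by any coverage-preserving equal-tail test and the worst-case CI
length stays 0.2. Alternative conventions (strict-exclusive tails, CDF
windows, one-sided survival comparisons, mid-p) were each tested: every
one that rejects this case also breaks four or more of the other five
values. The package keeps the coverage-guaranteed rule and reports the
value it computes.

## Scenario grids

- **HWE** (`P = p²`): feasible `p` are those with both `2Mp` and `Mp²`
  integral. For `M = 1000` this is the 11 frequencies `0, 0.1, …, 1`; for
  general `M` the grid can be irregular, and it is always computed by
  integer scan rather than assumed uniform.
- **Minimum homozygosity** (`P = max(0, 2p − 1)`): all `2M + 1` lattice
  frequencies are feasible.
- **Maximum homozygosity** (`P = p`): `p` must sit on the `1/M` lattice
  (`M + 1` values). This is the conservative choice when homozygosity is
  unknown — it maximises `Var(p̂)` at every `p` — and the unknown-`P`
  joint region's `p`-projection tracks it closely (asserted within 0.05 at
  `M = 200, N = 20`).
- **Unknown**: every feasible `(p, P)` pair; `Σ_k (⌊k/2⌋ − max(0, k − M)
  + 1)` pairs in total, quadratic in `M`, which is why the scenario rules
  exist.

A user-supplied rule `p → P` defines a custom grid: lattice `p` values
whose image lands on the `1/M` lattice within bounds. The HWE grid is
exactly the rule grid of `p → p²`.

## Sample-size design

`min_sample_size` scans `N` upward in steps of 10 from `N = 10` (both
configurable) until the worst-case CI length over all observations meets
the target, then walks down in steps of 1 while the target still holds.
The coarse scan start and step cannot affect the result because the
downward walk re-verifies every step; no monotonicity of worst-case length
in `N` is assumed. Within one `N`, acceptance tails for each grid pair are
computed once and reused across all `2N + 1` observations. The returned
record carries the worst-case length at `N_min` and at `N_min − 1` so the
minimality claim is self-verifying. The population sweep `m_sweep`
defaults to the paper-style grid `{100, 250, 500, 750, 1000, 2500, 5000,
7500, 10000}`; its sample size is a required, logged parameter (`N = 30`
is used in the examples and tests as the benchmark sample size the method
interrogates).

## Jost's D and its interval

For two demes with full frequency vectors `u, v` (equal weights):
`H_S = 1 − (Σu² + Σv²)/2`, `H_T = 1 − Σ((u+v)/2)²`,
`D = 2(H_T − H_S)/(1 − H_S)`. Per-population uncertainty enters as a
Bonferroni box: per-allele CIs at level `1 − α/n` for the first `n` listed
alleles (the final allele is implied by the simplex constraint and gets no
interval of its own), giving joint coverage `≥ 1 − α`. The CI for `D` is
the constrained minimum/maximum of `D` over the two boxes, with the listed
frequencies free inside their intervals subject to `Σ ≤ 1` per population
and the remainder assigned to the implied allele.

`D` is non-convex in the frequencies, so the SLSQP optimiser is restarted
from 32 scrambled-Sobol points of the joint box (fixed seed, reproducible)
plus all box corners (up to 256). Any optimiser reaching the grid oracle's
value qualifies; the tests compare against exhaustive 0.001-step lattice
scans. Those scans are exact only when tractable, so the 3-allele oracle
cases use boxes of width ≤ 0.04 (a full 0.001 grid over wider 3-allele
boxes has ~10⁹ points); the 2-allele cases use full-width boxes.

## Synthetic populations

`build_population` materialises an explicit genotype list realising
requested per-allele marginals: forced homozygote classes first, then
leftover single copies paired into heterozygotes greedily
(largest-remaining first), which succeeds exactly when the marginals are
jointly feasible. The seed only shuffles row order; the derived marginals
are seed-invariant, and the focal-allele sampling distribution depends
only on the three focal genotype classes (asserted by test). These urns
are static: no drift, mutation, migration or selfing dynamics — they
exist to validate the sampling pmf (200,000 seeded draws match the
analytic pmf to TV < 0.01) and interval coverage, not to emulate real
demography. Consequently, passing tests demonstrate correctness of the
finite-sampling mathematics, not robustness to model misspecification
(relatedness structure, genotyping error, null alleles) present in real
surveys.

## Problem sizes and defaults

Defaults follow the study conditions the package models: `α = 0.05`
everywhere; design sweeps at `M = 1000` (a large population on the scale
of published census estimates) with targets 0.2 and 0.1; `M`-sweeps at
`N = 30`. Oracle-backed tests run at `M ≤ 12` (exhaustive), coverage
checks at `M ≤ 100, N ≤ 30` (exact summation), Monte-Carlo checks with
10,000–200,000 seeded replicates. The full test suite and the acceptance
script each run in minutes on one CPU.

## Known limitations

- Intervals are conservative: coverage is `≥ 1 − α`, sometimes well above
  (discreteness); no attempt is made to shorten them toward exact-level
  sets.
- The reported interval is the hull of the accepted set; interior gaps,
  when they occur, are visible only through `accepted_p`.
- Multi-allele inference is per-allele marginal (plus Bonferroni
  combination); there is no joint multi-allele sampling distribution, so
  the Bonferroni boxes are not the tightest possible joint regions.
- The two-population `D` interval propagates box uncertainty only; it
  conditions on the assumed population sizes and the conservative
  maximum-homozygosity rule used for the per-allele CIs.
- Populations are treated as fixed urns; temporal change between sampling
  and inference is out of scope.
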