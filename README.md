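# finpopfreq

Exact confidence intervals for **population allele frequencies** when a
sample of `N` diploid individuals is drawn **without replacement** from a
**finite** diploid population of `M` individuals, with **any** degree of
departure from Hardy–Weinberg equilibrium (HWE). On top of the intervals
the package provides minimum-sample-size design sweeps and a confidence
interval for **Jost's D** between two populations.

Most allele-frequency uncertainty tools assume an effectively infinite
population at HWE, where the sampled copy count is binomial and
Clopper–Pearson or Wald intervals apply. Field studies of conservation and
population genetics routinely violate both assumptions: populations are
small relative to the sample and genotype frequencies deviate from HWE.
`finpopfreq` is for researchers planning or analysing such surveys —
microsatellite or SNP summaries of wild populations, forensic or museum
samples from small demes — who need uncertainty statements with a
*guaranteed* coverage level rather than an asymptotic one.

## Model

A focal allele in a population of `M` diploids is described by its
frequency `p` (a multiple of `1/(2M)`) and the frequency `P` of homozygotes
for it (a multiple of `1/M`), with `max(0, 2p − 1) ≤ P ≤ p`. Partition the
population into `m₂ = MP` homozygotes, `m₁ = 2M(p − P)` heterozygous
carriers and `m₀ = M − m₂ − m₁` non-carriers. Sampling `N` individuals
without replacement makes the sampled class counts `(x₂, x₁, x₀)`
multivariate hypergeometric, and the allele copy count `K = 2x₂ + x₁` has

    Pr(K = k) = Σ_{x₂ = L(k)}^{U(k)} C(m₂, x₂) C(m₁, k − 2x₂) C(m₀, N − k + x₂) / C(M, N)

with integer bounds `L(k) = max(0, k − N, ⌈(k − m₁)/2⌉)` and
`U(k) = min(m₂, ⌊k/2⌋, m₀ − N + k)`. The sample frequency `p̂ = K/(2N)` is
unbiased, `E[p̂] = p`, with

    Var(p̂) = (M − N)/(M − 1) · [p(1 − p) + (P − p²)] / (2N),

the classic Weir variance times a finite-population correction.

A **confidence interval** for `p` is built by test inversion: for each
feasible lattice value of `p` (with `P` tied to `p` by a scenario rule —
HWE `P = p²`, minimum homozygosity `P = max(0, 2p − 1)`, maximum
homozygosity `P = p`, or a user rule), the equal-tail level-α acceptance
region for `K` keeps at most `α/2` probability in each tail; the CI is the
hull of all `p` whose region contains the observed count. Coverage is
guaranteed `≥ 1 − α` for every true `(p, P)` consistent with the rule. If
no candidate accepts the observation, α is halved until one does and the
relaxed level is reported. When nothing is known about `P`, the same
inversion over all feasible `(p, P)` pairs yields a joint confidence
region whose projections bound `p` and `P`.

## A worked example

```python
from finpopfreq import ci_known_homozygosity, min_sample_size

# 30 of 60 sampled gene copies carry the allele; the population has M=1000
for scenario in ("hwe", "minhom", "maxhom"):
    ci = ci_known_homozygosity(M=1000, N=30, k_obs=30, alpha=0.05,
                               scenario=scenario)
    print(scenario, round(ci.lower, 3), round(ci.upper, 3))
```

prints

```
hwe 0.4 0.6
minhom 0.443 0.557
maxhom 0.316 0.684
```

— the 95% interval for the population frequency is `[0.40, 0.60]` if the
population is at HWE, `[0.32, 0.68]` under the conservative
maximum-homozygosity assumption (the one to use when homozygosity is
unknown). Sample-size design inverts the question:

```python
min_sample_size(M=1000, scenario="maxhom", alpha=0.05, target_length=0.2).N_min
# -> 94
```

i.e. 94 individuals are needed before the *worst-case* 95% CI length over
all possible observations drops to 0.2 (an estimate within ±0.1). Under
HWE the same target needs only 22. The `examples/` directory holds short
narrative scripts for each capability (exact pmf and intervals,
sample-size design, Jost's D with uncertainty, coverage checks), and the
`finpopfreq` command exposes the same operations as CLI subcommands
(`pmf`, `ci`, `cr`, `samplesize`, `sweep`, `jostd`, `simulate`,
`coverage`).

## Data

`data/cinx1_synthetic.csv` is a **synthetic** example table (invented
frequencies in the shape of a published microsatellite survey) used by the
examples. The checkerspot-butterfly application requires the original
survey table (Palo et al. 1995, Table 1), which is not redistributed here;
place a transcription at `data/external/palo1995_cinx1.csv` to run that
check.
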