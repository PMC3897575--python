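"""Does the interval really cover at 95%?  Exact and simulated coverage.

For a small population we compute the exact coverage probability of the
test-inversion CI at a known truth (summing the sampling pmf over the
observations whose CI contains the true p) and compare it with a seeded
Monte-Carlo estimate from an explicit genotype urn.
"""

from finpopfreq import (
    ci_known_homozygosity,
    copy_count_pmf,
    empirical_coverage,
)

M, N, alpha = 30, 10, 0.05
p, P = 0.5, 0.5  # truth on the maximum-homozygosity grid

pmf = copy_count_pmf(M, N, p, P).pmf
exact = sum(
    pmf[k]
    for k in range(2 * N + 1)
    if pmf[k] > 0
    and any(abs(p - q) < 1e-12 for q in
            ci_known_homozygosity(M, N, k, alpha, scenario="maxhom").accepted_p)
)
est = empirical_coverage(M, N, p, P, alpha, replicates=20_000, seed=7,
                         scenario="maxhom")
print(f"exact coverage      = {exact:.4f}  (guaranteed >= {1 - alpha})")
print(f"Monte-Carlo (20k)   = {est:.4f}")

# The exact value sits at or above the nominal 0.95 -- usually strictly
# above, because the copy count is discrete -- and the simulation agrees
# within Monte-Carlo error.
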