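"""Exact confidence intervals for one observed sample, three assumptions.

A sample of N = 30 diploid individuals from a population of M = 1000 shows
30 copies of the focal allele (sample frequency 0.5).  We compute the exact
sampling pmf of the copy count under one hypothesis and the 95% test-
inversion CI for the population frequency under each homozygosity rule.
"""

from finpopfreq import ci_known_homozygosity, copy_count_pmf, cr_unknown_homozygosity

M, N, k_obs = 1000, 30, 30

dist = copy_count_pmf(M, N, p=0.5, P=0.25)
print(f"pmf of K under (p=0.5, P=0.25): mean p_hat = {dist.mean_freq():.3f}, "
      f"sd = {dist.var_freq() ** 0.5:.4f}")

for scenario, label in [("hwe", "Hardy-Weinberg equilibrium"),
                        ("minhom", "minimum homozygosity"),
                        ("maxhom", "maximum homozygosity")]:
    ci = ci_known_homozygosity(M, N, k_obs, 0.05, scenario=scenario)
    print(f"{label:30s}: 95% CI [{ci.lower:.3f}, {ci.upper:.3f}] "
          f"(length {ci.length:.3f})")

cr = cr_unknown_homozygosity(200, 20, 20, 0.05)
lo, hi = cr.p_interval
print(f"unknown homozygosity (M=200, N=20, k=20): p in [{lo:.3f}, {hi:.3f}], "
      f"{len(cr)} accepted (p, P) pairs")

# The three CI lengths are nested: assuming HWE gives the shortest interval,
# assuming nothing (~ maximum homozygosity) the longest; all guarantee >= 95%
# coverage of the true population frequency.
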