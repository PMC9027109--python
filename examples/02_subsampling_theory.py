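"""Unbiasedness and variance of the subsampled pair-rate estimators.

On a tiny series every subset can be enumerated, so the exact mean
and variance of the subsample pair rate A~/(N0(N0-1)) are computable
by brute force.  This script checks them against the closed forms:
the mean equals the full-population rate A/(N(N-1)) (unbiasedness)
and the variance equals C_N0 / N0 with C_N0 below the theoretical
ceiling 1 + 1/(2(N0-1)).
"""

from mcsampen import enumerated_moments, expectation_formula, match_counts, variance_formula
from mcsampen.signals import fixtures

toy = fixtures()["toy"]  # (0,0,1,0,0,1,0)
counts = match_counts(toy, m=1, r=0.5)
N = counts.n_templates
print(f"toy series: A={counts.a}, B={counts.b}, N={N}")

n0 = 3
em = enumerated_moments(toy, m=1, r=0.5, N0=n0)
print(f"enumerated over C({N},{n0}) subsets: "
      f"mean={em.a_mean:.6f}, var={em.a_var:.6f}")

mean = expectation_formula(counts.a, N, n0)
vr = variance_formula(counts.per_template_a, N, n0)
print(f"closed forms:                mean={mean:.6f}, var={vr.variance:.6f}")
print(f"variance constant C_N0 = {vr.c_n0:.4f} "
      f"(ceiling {vr.bound:.4f}); terms: "
      + ", ".join(f"{t:+.4f}" for t in vr.terms))
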