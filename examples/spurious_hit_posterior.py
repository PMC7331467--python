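"""Classifying a candidate hit as spurious after alignment.

Against a random genomic location three quarters of the aligned
nucleotides mismatch; against the true location only a fraction p does.
With 33 nucleotides to align after the seed the two regimes are separated
by ~27 orders of magnitude, so the posterior saturates regardless of the
prior.
"""

from seedprob import RandomHitQuery, likelihood_ratio_factor, \
    random_hit_posterior

for m in (15, 4):
    q = RandomHitQuery(L=33, m=m, p=0.01)
    print(f"L=33 aligned, {m:2d} mismatches: "
          f"factor 4^L (p/3)^m q^(L-m) = {likelihood_ratio_factor(q):.2e}, "
          f"P(random) = {random_hit_posterior(q):.3g}")
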