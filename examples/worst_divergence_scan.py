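"""The worst-case duplicate divergence rate.

Off-target seeding vanishes both when duplicates are identical to the
target (any duplicate seed is accompanied by a target seed) and when they
are very diverged (duplicates are never seeded), so there is a worst
divergence mu* in between.  The worst case differs between seed types,
which is what makes strategy comparisons worthwhile.
"""

from seedprob import SeedingParams, worst_mu_scan

for seed_type, gamma, n in [("exact", 19, 0), ("skip", 19, 9), ("mem", 19, 0)]:
    params = SeedingParams(k=50, gamma=gamma, p=0.01, n=n, N=1)
    mu_star, p_off = worst_mu_scan(params, seed_type, mu_range=(0.005, 0.2),
                                   step=0.005, epsilon=1e-6)
    label = seed_type if n == 0 else f"{seed_type}-{n}"
    print(f"{label:8s} gamma={gamma}: worst mu = {mu_star:.3f} "
          f"with p_off = {p_off:.2e}")
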