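"""MEM seeds: duplicate masking, and the matrix/Monte Carlo agreement.

MEM (maximal exact match) seeds are variable-length seeds used by BWA-MEM.
Duplicates can *mask* the target: if a duplicate's match run extends
strictly past the target's, the target stretch is not maximal and yields no
seed.  Masking makes MEM seeding markedly more error-prone than exact
seeding with the same minimum size, and creates oddities such as a read
that gains an on-target seed when it is shortened.
"""

import numpy as np

from seedprob import SeedingParams, off_target_exact, off_target_mem, \
    mem_monte_carlo, prob_no_on_target_mem
from seedprob.oracle import SimulatedInstance, detect_mem_on_target

params = SeedingParams(k=50, gamma=19, p=0.01, N=5, mu=0.06)
mem = off_target_mem(params, epsilon=1e-8)
exact = off_target_exact(params, epsilon=1e-8)
print(f"k=50, gamma=19, p=0.01, N=5, mu=0.06:")
print(f"  MEM   p_off = {mem.p_off:.2e}")
print(f"  exact p_off = {exact.p_off:.2e}  "
      f"(MEM is ~{mem.p_off / exact.p_off:.0f}x worse: masking)")

a = prob_no_on_target_mem(params, epsilon=1e-10)
est = mem_monte_carlo(params, 1_000_000, rng_seed=1)
print(f"\nP(no on-target MEM seed): matrix {a:.6f} vs "
      f"Monte Carlo {1 - est.p_hat:.6f} (+/- {est.stderr:.6f})")

# a read that gains a seed when shortened: the duplicate matches the whole
# read including the target's two trailing errors, hard-masking the target
tmatch = np.array([True] * 8 + [False, False])
dup = np.ones((1, 10), dtype=bool)
full = SimulatedInstance(tmatch, dup)
trimmed = SimulatedInstance(tmatch[:8], dup[:, :8])
print(f"\n10-mer with trailing hard mask: on-target seed? "
      f"{detect_mem_on_target(full, 4)}")
print(f"same read trimmed to 8-mer:      on-target seed? "
      f"{detect_mem_on_target(trimmed, 4)}")
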