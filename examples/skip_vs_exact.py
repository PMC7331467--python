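"""Skip seeds versus exact seeds, and the staircase in read length.

Skip-n seeds may start only every n+1 positions (Bowtie2 uses skip-9 seeds
of size 16).  At a high error rate skipping can even reduce the off-target
probability: fewer duplicate seeds survive than target seeds are lost.  The
no-seed probability also becomes a staircase in the read length, dropping
only when the read grows past the next allowed seed start.
"""

import numpy as np

from seedprob import SeedingParams, off_target_exact, off_target_skip, \
    prob_no_on_target_skip

setting = dict(k=50, gamma=19, p=0.1, N=10, mu=0.1)
exact = off_target_exact(SeedingParams(**setting), epsilon=1e-8)
skip9 = off_target_skip(SeedingParams(**setting, n=9), epsilon=1e-8)
print(f"k=50, gamma=19, p=0.1, mu=0.1, N=10:")
print(f"  exact seeds : p_off = {exact.p_off:.4f}")
print(f"  skip-9 seeds: p_off = {skip9.p_off:.4f}  (skipping helps here)")

series = prob_no_on_target_skip(
    SeedingParams(k=48, gamma=16, p=1e-3, n=9), epsilon=1e-10)
print("\nP(no on-target skip-9 seed of size 16), small p: a staircase")
for k in range(15, 48, 4):
    bar = "#" * int(60 * series[k])
    print(f"  k={k:2d}  {series[k]:.6f}  {bar}")
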