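"""On/off-target/null seeding probabilities for exact seeds.

A read of 50 nucleotides is sequenced with a 1% substitution rate from a
target that has 5 duplicates diverging at 6% per position; the mapper uses
exact seeds of size 19.  The three numbers printed are the probabilities
that the candidate set contains the target (the read can be mapped
correctly), contains only duplicates (the read will be mapped to the wrong
place), or is empty of homologous locations (the read is unmappable).
"""

from seedprob import SeedingParams, off_target_exact

params = SeedingParams(k=50, gamma=19, p=0.01, N=5, mu=0.06)
out = off_target_exact(params, epsilon=1e-6)

print(f"read length k={params.k}, seed size gamma={params.gamma}, "
      f"error rate p={params.p}, N={params.N} duplicates at mu={params.mu}")
print(f"P(on-target)  = {out.p_on:.6f}   target is in the candidate set")
print(f"P(off-target) = {out.p_off:.6f}   only duplicates are: mapping error")
print(f"P(null)       = {out.p_null:.6f}   no seed at all: read unmapped")
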