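"""Grid-snapped memoized lookups, as a mapper would use them at run time.

Inside a mapper only N and mu vary per read; snapping them to a grid turns
almost every probability query into a dictionary read.  Entries are
computed on first use and can be persisted as JSON-lines.
"""

import tempfile

from seedprob import GridSpec, ProbabilityStore, SeedingParams, snapped_lookup

grid = GridSpec()   # mu on a 0.01 grid, N geometrically spaced
store = ProbabilityStore()

for N, mu in [(4, 0.058), (3, 0.062), (1_000_000, 0.06)]:
    params = SeedingParams(k=50, gamma=19, p=0.01, N=N, mu=mu)
    out = snapped_lookup(params, "mem", grid, store, n_samples=200_000)
    n_s, mu_s = grid.snap(N, mu)
    print(f"request (N={N}, mu={mu:.3f}) -> grid (N={n_s}, mu={mu_s:.2f}): "
          f"p_off = {out.p_off:.3e}  [{out.method}]")

print(f"\ncomputations: {store.computations}, cache hits: {store.hits}")
with tempfile.NamedTemporaryFile(suffix=".jsonl") as fh:
    store.save(fh.name)
    reloaded = ProbabilityStore.load(fh.name)
    print(f"persisted and reloaded {len(reloaded.records)} grid cells")
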