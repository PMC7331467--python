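# Methods

## Generative model

All probabilities refer to the following model of sequencing and
duplication.  A target sequence is read with a constant per-nucleotide
substitution rate p; insertions and deletions never occur, and an erroneous
nucleotide is uniform over the three alternative bases (an Illumina-like
error spectrum).  The target has N ≥ 0 duplicates; at each position,
independently across positions and duplicates, a duplicate carries the
target base with probability 1 − μ and otherwise one of the other three
bases uniformly.  Consequently a read error matches any given duplicate
with probability μ/3 and a correct nucleotide matches it with probability
1 − μ.  Seeds are evaluated at homologous positions only; matches
elsewhere in a genome are handled separately by the spurious-hit posterior
(below).

Parameters, with the package defaults used in examples and tests:

| symbol | meaning | typical |
|---|---|---|
| k | read length (nt) | 50–100 |
| γ | minimum seed size (nt) | 16–34 (19 = BWA-MEM default) |
| p | substitution rate | 0.01 (Illumina); 0.1 as stress case |
| n | skipped positions between seed starts | 0–9 (9 = Bowtie2) |
| N | number of duplicates | 0–10⁶ |
| μ | per-position duplicate divergence | 0–0.2 |
| ε | relative truncation accuracy of a_k | 0.01 |

## Transfer matrices and the truncated power sum

Reads are recoded as segments over problem-specific alphabets, and the
weighted generating function of the no-seed reads is the (start, tail)
entry of M + M² + …, evaluated on polynomials truncated at order k.  The
matrices implemented are:

- **exact on-target** (2 states): segments of fewer than γ matches ending
  in an error; equivalently the recurrence
  a_k = a_{k−1} − p q^γ a_{k−γ−1} with a_k = 1 below γ and
  a_γ = 1 − q^γ, which is the route actually used (O(k) time).
- **skip-n on-target** (n+2 states): error symbols carry their phase
  (distance to the next allowed seed start); segment lengths are
  constrained modulo n+1.
- **exact dual** (2(γ−1)+2 states): per-nucleotide outcomes are classed as
  double match (a = (1−p)(1−μ)), mismatch against the duplicate only
  (b = (1−p)μ), against the target only (c = pμ/3), or both
  (d = p(1−μ/3)); states track the live match length of the non-mismatched
  sequence.  Yields P(S̄₀∩S̄₁).
- **skip dual** (n+1+2(γ−1)+1 states): the dual construction with
  phase-carrying reset states; errors landing inside one inter-skip
  interval reset both counters ("fast-forward" projections of weight z^i).
  Match lengths in the v-states are counted from the latest allowed seed
  start covered by the run, which is what makes a run seed-relevant.
- **MEM** (N+γ+1 states): states are the number m of *hard masks*
  (duplicates whose match run strictly exceeds the target's) at the last
  error, plus "first unmasked nucleotide" states; the entries are built
  from ω_m = C(N,m)(μ/3)^m(1−μ/3)^{N−m}, ξ_j = 1−(1−μ)^j,
  η_j = 1−(1−μ)^j μ/3 and the terminator-splitting probabilities
  ζ_{j,m,n}.  With N = 0 there are no masks and the construction
  degenerates to the exact-seed matrix, which the code special-cases.
- **spaced on-target** (≤ 2^m+1 states for m don't-care positions): a
  state is the set of suffix lengths (ending at the last error) compatible
  with a proper model prefix, materialized by breadth-first closure from
  the start state.  The construction is validated against a brute-force
  pattern detector for every model used in the tests.

Two printed-formula ambiguities in the dual constructions (whether tail
segments weigh matches by a or by q = a+b, and which of b/c enters the
same-interval correction terms) were resolved from first principles —
unique segment decomposition forbids q-tails, and the correction mismatch
is against the sequence whose counter was live — and the resulting
matrices reproduce exhaustive joint enumeration to machine precision for
k ≤ 10 across assorted (γ, n, p, μ).

## Stopping rule

After accumulating s powers, every neglected read has at least e(s)
mismatches: e(s) = s for the on-target and exact dual matrices, and
e(s) = ⌊s/2⌋ for the skip dual and MEM matrices (mask-vanishing and
fast-forward segments carry no mismatch, but cannot occur twice in a row).
The neglected weight is bounded by the binomial tail Pr(X ≥ e(s)) with
X ~ B(k, r), bounded in turn by the Chernoff-type expression

    Pr(X ≥ e) ≤ exp((e−k) log[(k−e)/(k(1−r))] − e log[e/(kr)]),

taken as 1 below the mean (the bound is a large-deviation inequality and
certifies nothing there).  The rate r is p for on-target and MEM matrices
and b+c+d = p + qμ for the dual matrices — the probability that a
nucleotide mismatches at least one sequence; a per-kind maximum such as
max{b,c,d} would not bound the any-mismatch count and is not used.
Iteration stops when the bound falls below ε·a_k.  Because every non-tail
segment consumes at least one nucleotide, k+1 powers are always exact;
the engine therefore never needs more than k+1 iterations, and a
user-supplied lower cap raises an error naming the bound achieved.

Note that ε certifies the *coefficient* a_k.  The off-target combination
amplifies its error roughly N-fold through the ratio power, so scans and
worked comparisons in this package use ε between 10⁻⁶ and 10⁻⁸ (the extra
iterations are cheap at these matrix sizes).

## Combining single- and pair-events over N duplicates

Given P(S̄₀) and P(S̄₀∩S̄₁),

    P(null) = P(S̄₀)·(P(S̄₀∩S̄₁)/P(S̄₀))^N,   P(off) = P(S̄₀) − P(null),

and for MEM seeds P(off) = P(M̄₀) − P(null) with the same null term (there
is some MEM seed iff some sequence has a γ-match).  The step treating the
duplicate events as i.i.d. conditionally on S̄₀ is exact for N = 1 but an
approximation for N ≥ 2: the duplicates are i.i.d. given the read's error
pattern, and Jensen's inequality makes the formula overstate p_off
slightly (≈0.4% relative at k=7, γ=3, N=2 by exhaustive enumeration;
smaller at realistic parameters).  The package follows the formula; the
oracle tests quantify the gap.

## Monte Carlo sampler for MEM seeds

For N beyond a configurable switch (default 20, where the matrix becomes
slow), P(on-target MEM seed) is estimated by sampling reads at the segment
level: the gap to the next error is geometric(p) truncated at the read
end, and mask survival across the stretch is tracked only through counts —
hard masks survive j clean nucleotides with probability (1−μ)^j, soft
masks span stretch-plus-error with (1−μ)^j μ/3, and dead masks rejoin the
hard count at the next error with μ/3 (or μ/3·ξ_j/η_j when conditioned to
die inside the segment).  A stretch of j ≥ γ clean nucleotides yields a
seed iff no hard mask survives it and, when an error terminates it, no
soft mask spans it including the error.  Per-cycle cost is a handful of
binomial draws regardless of N; the sampler is vectorized across reads and
bit-reproducible for a fixed seed.  Its contract is agreement with the
transfer-matrix method, enforced at 10⁷ samples over N ∈ {1,5,10,20} and
μ ∈ {0.02,0.06,0.10} in the acceptance tests.

## Spurious-hit posterior

After alignment, a candidate location that is not homologous to the read
mismatches at rate 3/4 instead of p.  With L aligned nucleotides and m
mismatches, P(random hit) = 1/(1 + 4^L (p/3)^m (1−p)^{L−m} (1−β)/β),
evaluated in log space with saturation at |log-odds| > 745 (beyond which
the double rounds to 0 or 1 anyway).  The default prior β = 1/2 cancels
the prior term; the classification is insensitive to β except within
~10⁻¹⁷ of 0 (random regime) or ~10⁻⁹ of 1 (true-hit regime).

## Simulation oracle

`seedprob.oracle` samples instances nucleotide-by-nucleotide from the
generative model and decides every event by direct string logic: windowed
matching for fixed and spaced seeds, and for MEMs the run/flank rule — a
maximal error-free stretch of length ≥ γ is an on-target MEM seed unless
some duplicate matches the whole stretch plus a flanking error (which is
exactly the hard-mask criterion).  Exhaustive mode enumerates per-position
outcome classes (2^{N+1} per position) for exact references at small k;
Monte Carlo mode is vectorized across instances.  The oracle emulates the
model faithfully but *only* the model: uniform errors (no quality decay
along the read), no indels, no duplicate genealogy, and no background
genome.  Green oracle tests therefore validate the mathematics, not the
fidelity of the model to any particular sequencing run.

## Caching interface

`GridSpec` snaps a requested (N, μ) to a predefined grid — μ on a 0.01
grid over [0, 0.2], N geometrically spaced up to 10⁶, ties resolved
toward larger N and toward the worst-case μ (both push p_off up,
i.e. conservative for mapping-quality use) — and `ProbabilityStore`
memoizes results, persisting them as JSON-lines with a schema-version
header; JSON float round-trips are lossless at double precision.  The grid
values are a package default, not a reproduction of any published grid.

## Problem sizes and determinism

The test suite and the acceptance script run at the printed parameter
scales (k = 50–100, γ = 19–34): transfer matrices stay below ~70 states
and power sums below ~50 iterations, so everything is desk-scale;
exhaustive enumerations are kept at k ≤ 10 (≤ 4^k patterns for one
duplicate), Monte Carlo checks use 10⁶ instances at nucleotide level and
10⁷ at segment level, and the worst-μ scans use a 0.001–0.005 grid step
over (0, 0.2].  All random draws go through seeded NumPy generators;
every stochastic check is reproducible from its stated seed.

## Known limitations

- Substitution-only errors: inappropriate for indel-prone platforms.
- Duplicates evolve i.i.d. from the target; real paralog families have
  shared ancestry that the exchangeable model ignores.
- Off-target probabilities for spaced seeds are not computed (the dual
  construction would need ~4^m states).
- The N-duplicate combination is exact only at N = 1 (see above).
- For N slightly above the Monte Carlo switch, rare events (p_off below
  ~10⁻⁵) need large sample counts for tight relative error; the matrix
  method should be preferred whenever it is affordable.
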