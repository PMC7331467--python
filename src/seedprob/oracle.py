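"""Nucleotide-level generative model and direct seed detectors.

This module is the independent test surface for every analytic computation
in the package: it samples target/duplicate/read instances position by
position from the generative model (uniform substitution errors at rate p,
i.i.d. per-position duplicate divergence at rate mu, no indels) and decides
seeding events by direct string logic rather than generating functions.

Two regimes are supported: Monte Carlo sampling (vectorized across
instances) and exhaustive enumeration over per-position outcome classes,
which yields exact reference probabilities for small k and N.

Conventions: positions are 0-based internally and 1-based in user-facing
text; intervals are half-open.  Events are evaluated at homologous
(aligned) positions only — random matches elsewhere in a genome are outside
the model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exact_seeds import SeedingParams
from .mem_seeds import MonteCarloEstimate
from .spaced_seeds import SpacedSeedModel

__all__ = [
    "SimulatedInstance",
    "simulate_instance",
    "simulate_batch",
    "detect_fixed_seed",
    "detect_spaced_seed",
    "detect_mem_on_target",
    "best_location",
    "estimate_event_probability",
    "exhaustive_event_probability",
    "write_instance_fasta",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulatedInstance:
    """One target + N duplicates + read, as position-aligned match patterns.

    ``target_matches[t]`` is True unless the read has a sequencing error at
    t; ``dup_matches[j, t]`` is True when the read agrees with duplicate j
    at t.  When nucleotides are materialized the boolean vectors are exactly
    their agreement patterns.
    """

    target_matches: np.ndarray
    dup_matches: np.ndarray
    read: str | None = None
    target: str | None = None
    duplicates: tuple[str, ...] | None = None

    @property
    def k(self) -> int:
        return self.target_matches.size

    @property
    def N(self) -> int:
        return self.dup_matches.shape[0]


def simulate_instance(params: SeedingParams, rng_seed: int,
                      materialize: bool = True) -> SimulatedInstance:
    """Sample one instance at the nucleotide level.

    The target is uniform over the four bases; each duplicate position
    equals the target base with probability 1 - mu, else is uniform over
    the other three; the read equals the target base with probability
    1 - p, else uniform over the other three.
    """
    rng = np.random.default_rng(rng_seed)
    k, N, p, mu = params.k, params.N, params.p, params.mu
    target = rng.integers(0, 4, size=k)

    def mutate(seq: np.ndarray, rate: float) -> np.ndarray:
        flip = rng.random(k) < rate
        # uniform over the three other bases
        shift = rng.integers(1, 4, size=k)
        return np.where(flip, (seq + shift) % 4, seq)

    dups = np.stack([mutate(target, mu) for _ in range(N)]) if N else \
        np.zeros((0, k), dtype=int)
    read = mutate(target, p)
    inst = SimulatedInstance(
        target_matches=read == target,
        dup_matches=(dups == read[None, :]) if N else np.zeros((0, k), bool),
    )
    if materialize:
        inst.read = "".join(_BASES[read])
        inst.target = "".join(_BASES[target])
        inst.duplicates = tuple("".join(_BASES[d]) for d in dups)
    return inst


def simulate_batch(params: SeedingParams, n_samples: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized agreement patterns: (errors, dup_matches) with shapes
    (n_samples, k) and (n_samples, N, k)."""
    k, N, p, mu = params.k, params.N, params.p, params.mu
    err = rng.random((n_samples, k)) < p
    u = rng.random((n_samples, N, k))
    dup = np.where(err[:, None, :], u < mu / 3.0, u < 1.0 - mu)
    return err, dup


def _seq_matches(instance: SimulatedInstance, seq_index: int) -> np.ndarray:
    if seq_index == 0:
        return instance.target_matches
    return instance.dup_matches[seq_index - 1]


def detect_fixed_seed(instance: SimulatedInstance, seq_index: int,
                      gamma: int, n: int = 0) -> bool:
    """True iff some window of gamma matches starts at an allowed position.

    Allowed starts are 1, n+2, 2n+3, ... (1-based); n = 0 gives exact seeds.
    """
    m = _seq_matches(instance, seq_index)
    return bool(_fixed_seed_batch(m[None, :], gamma, n)[0])


def _fixed_seed_batch(m: np.ndarray, gamma: int, n: int) -> np.ndarray:
    k = m.shape[-1]
    out = np.zeros(m.shape[0], dtype=bool)
    for s in range(0, k - gamma + 1, n + 1):
        out |= m[:, s: s + gamma].all(axis=1)
    return out


def detect_spaced_seed(instance: SimulatedInstance, seq_index: int,
                       model: SpacedSeedModel) -> bool:
    """True iff some offset aligns all '1' positions of the model to matches."""
    m = _seq_matches(instance, seq_index)
    ones = np.array([u for u, ch in enumerate(model.pattern) if ch == "1"])
    k = m.size
    for s in range(k - model.length + 1):
        if m[s + ones].all():
            return True
    return False


def _run_lengths(m: np.ndarray) -> np.ndarray:
    """Per-position leftward match-run lengths, vectorized over rows."""
    L = np.zeros(m.shape, dtype=np.int32)
    run = np.zeros(m.shape[0], dtype=np.int32)
    for t in range(m.shape[1]):
        run = np.where(m[:, t], run + 1, 0)
        L[:, t] = run
    return L


def _mem_on_target_batch(err: np.ndarray, dup: np.ndarray,
                         gamma: int) -> np.ndarray:
    """Vectorized on-target MEM seed detector.

    A maximal error-free stretch R of the read (length L >= gamma) is an
    on-target MEM seed unless some duplicate matches all of R plus the
    flanking error on either side (which would extend the match and exclude
    the target).  This is the hard/soft-mask recoding: a blocking duplicate
    is precisely a hard mask covering the stretch boundary.
    """
    reps, k = err.shape
    tmatch = ~err
    L0 = _run_lengths(tmatch)
    Ld = _run_lengths(dup.reshape(-1, k)).reshape(dup.shape)
    run_end = tmatch.copy()
    run_end[:, :-1] &= err[:, 1:]
    seed = np.zeros(reps, dtype=bool)
    for t in range(k):
        sel = run_end[:, t] & (L0[:, t] >= gamma)
        rows = np.flatnonzero(sel)
        if rows.size == 0:
            continue
        Lv = L0[rows, t]
        block = (Ld[rows, :, t] >= (Lv + 1)[:, None]).any(axis=1)
        if t < k - 1:
            block |= (Ld[rows, :, t + 1] >= (Lv + 1)[:, None]).any(axis=1)
        seed[rows[~block]] = True
    return seed


def detect_mem_on_target(instance: SimulatedInstance, gamma: int) -> bool:
    """True iff the read contains an on-target MEM seed of size >= gamma."""
    err = ~instance.target_matches[None, :]
    dup = instance.dup_matches[None, :, :]
    if instance.N == 0:
        return bool(_fixed_seed_batch(~err, gamma, 0)[0])
    return bool(_mem_on_target_batch(err, dup, gamma)[0])


def best_location(instance: SimulatedInstance) -> int:
    """Index of the sequence with the fewest mismatches against the read.

    0 is the target, j >= 1 the j-th duplicate; ties are broken in favor of
    the target, then the lowest duplicate index.
    """
    d0 = int((~instance.target_matches).sum())
    dists = [d0] + [int((~m).sum()) for m in instance.dup_matches]
    return int(np.argmin(dists))


# ---------------------------------------------------------------------------
# Event evaluation: Monte Carlo and exhaustive.

def _event_batch(event: str, params: SeedingParams, err: np.ndarray,
                 dup: np.ndarray) -> np.ndarray:
    gamma, n = params.gamma, params.n
    tmatch = ~err
    if event == "no_target_seed":
        return ~_fixed_seed_batch(tmatch, gamma, n)
    if event == "no_seed_pair":
        return (~_fixed_seed_batch(tmatch, gamma, n)
                & ~_fixed_seed_batch(dup[:, 0, :], gamma, n))
    if event in ("off_target", "null"):
        s0 = _fixed_seed_batch(tmatch, gamma, n)
        anydup = np.zeros(err.shape[0], dtype=bool)
        for j in range(params.N):
            anydup |= _fixed_seed_batch(dup[:, j, :], gamma, n)
        return (~s0 & anydup) if event == "off_target" else (~s0 & ~anydup)
    if event == "no_mem_on_target":
        return ~_mem_on_target_batch(err, dup, gamma)
    if event == "mem_off_target":
        no_mem = ~_mem_on_target_batch(err, dup, gamma)
        anyseq = _fixed_seed_batch(tmatch, gamma, 0)
        for j in range(params.N):
            anyseq |= _fixed_seed_batch(dup[:, j, :], gamma, 0)
        return no_mem & anyseq
    raise ValueError(f"unknown event {event!r}")


def estimate_event_probability(event: str | Callable[[SimulatedInstance], bool],
                               params: SeedingParams, n_samples: int,
                               rng_seed: int) -> MonteCarloEstimate:
    """Monte Carlo frequency of a seeding event with binomial stderr.

    ``event`` is one of the named detectors ('no_target_seed',
    'no_seed_pair', 'off_target', 'null', 'no_mem_on_target',
    'mem_off_target'), evaluated vectorized, or an arbitrary callable on
    :class:`SimulatedInstance` (slower).  Reproducible under a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng_seed)
    if callable(event):
        hits = 0
        for i in range(n_samples):
            inst = simulate_instance(params, rng_seed=int(rng.integers(2 ** 31)),
                                     materialize=False)
            hits += bool(event(inst))
        return MonteCarloEstimate.from_counts(hits, n_samples, rng_seed)
    chunk = 200_000
    hits = 0
    remaining = n_samples
    while remaining > 0:
        size = min(chunk, remaining)
        err, dup = simulate_batch(params, size, rng)
        hits += int(_event_batch(event, params, err, dup).sum())
        remaining -= size
    return MonteCarloEstimate.from_counts(hits, n_samples, rng_seed)


def exhaustive_event_probability(event: str, params: SeedingParams) -> float:
    """Exact event probability by enumerating per-position outcome classes.

    Each position falls in one of 2^(N+1) classes (error bit plus one match
    bit per duplicate) whose probabilities follow from the model; summing
    the detector over all class patterns gives an exact reference.  Only
    practical for small k and N.
    """
    k, N, p, mu = params.k, params.N, params.p, params.mu
    n_classes = 2 ** (N + 1)
    if n_classes ** k > 20_000_000:
        raise ValueError("instance too large for exhaustive enumeration")
    class_ids = np.arange(n_classes)
    err_bit = (class_ids & 1).astype(bool)
    dup_bits = np.stack([(class_ids >> (1 + j)) & 1 for j in range(N)],
                        axis=0).astype(bool) if N else np.zeros((0, n_classes), bool)
    logw = np.where(err_bit, np.log(p), np.log(1 - p))
    for j in range(N):
        pm = np.where(err_bit, mu / 3.0, 1.0 - mu)
        pr = np.where(dup_bits[j], pm, 1.0 - pm)
        with np.errstate(divide="ignore"):
            logw = logw + np.log(pr)
    total = 0.0
    chunk = 100_000
    patterns = itertools.product(range(n_classes), repeat=k)
    while True:
        block = np.array(list(itertools.islice(patterns, chunk)), dtype=np.int64)
        if block.size == 0:
            break
        w = np.exp(logw[block].sum(axis=1))
        keep = w > 0.0
        block, w = block[keep], w[keep]
        err = err_bit[block]
        dup = dup_bits.T[block].transpose(0, 2, 1) if N else \
            np.zeros((block.shape[0], 0, k), bool)
        total += float(w[_event_batch(event, params, err, dup)].sum())
    return total


def write_instance_fasta(instance: SimulatedInstance, path: str) -> None:
    """Write the materialized target, duplicates and read as FASTA records,
    so fixtures can feed external mappers."""
    if instance.read is None:
        raise ValueError("instance has no materialized nucleotides")
    with open(path, "w") as fh:
        fh.write(f">target\n{instance.target}\n")
        for j, d in enumerate(instance.duplicates or (), start=1):
            fh.write(f">duplicate_{j}\n{d}\n")
        fh.write(f">read\n{instance.read}\n")
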