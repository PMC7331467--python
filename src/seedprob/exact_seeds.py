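"""Exact (contiguous, fixed-size) seeds: on-target, off-target and null.

The generative model: a read of k nucleotides is sequenced from a target
with a constant substitution rate p (no indels); the target has N duplicate
(paralogous) sequences, each identical to the target at any position with
probability 1 - mu, independently across positions and duplicates.  A
genomic location enters the candidate set iff the read contains a perfect
match of length >= gamma for it.  Seeding is on-target if the candidate set
contains the target, off-target if it contains a duplicate but not the
target, null if neither.

P(no on-target seed) follows a short recurrence; P(no seed for the target
nor for one fixed duplicate) comes from the dual transfer matrix over the
alphabet {double match, mismatch-minus-only, mismatch-plus-only, double
mismatch}; the N-duplicate probabilities follow because the duplicate
events are i.i.d. conditionally on the target having no seed:

    P(off-target) = P(S0bar) - P(S0bar) * (P(S0bar & S1bar)/P(S0bar))^N
    P(null)       =            P(S0bar) * (P(S0bar & S1bar)/P(S0bar))^N
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gfcore import (
    ConvergenceConfig,
    TransferMatrix,
    TruncatedPolynomial,
    accumulate_power_sum,
)

__all__ = [
    "SeedingParams",
    "DualMatchProbs",
    "SeedingOutcome",
    "prob_no_on_target_exact",
    "dual_match_probs",
    "build_dual_transfer_exact",
    "prob_no_seed_either_exact",
    "combine_outcomes",
    "off_target_exact",
]


@dataclass(frozen=True)
class SeedingParams:
    """One problem instance.

    k: read length (nucleotides); gamma: minimum seed size; p: sequencing
    substitution rate; n: skipped positions between seed starts (0 for exact
    seeds); N: number of duplicates; mu: per-position divergence rate of each
    duplicate from the target.
    """

    k: int
    gamma: int
    p: float
    n: int = 0
    N: int = 0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("read length k must be >= 1")
        if self.gamma < 1:
            raise ValueError("minimum seed size gamma must be >= 1")
        if not 0.0 < self.p < 1.0:
            raise ValueError("substitution rate p must lie in (0, 1)")
        if self.n < 0:
            raise ValueError("skipped positions n must be >= 0")
        if self.N < 0:
            raise ValueError("number of duplicates N must be >= 0")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("divergence rate mu must lie in [0, 1]")

    @property
    def q(self) -> float:
        return 1.0 - self.p


@dataclass(frozen=True)
class DualMatchProbs:
    """Per-nucleotide joint outcome probabilities for (target, duplicate).

    a: double match; b: mismatch against the duplicate (minus sequence)
    only; c: mismatch against the target (plus sequence) only; d: double
    mismatch.  Under the generative model a = (1-p)(1-mu), b = (1-p)mu,
    c = p*mu/3, d = p(1 - mu/3).
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(self.a + self.b + self.c + self.d - 1.0) > 1e-9:
            raise ValueError("a + b + c + d must equal 1")

    @property
    def mismatch_rate(self) -> float:
        """Per-nucleotide probability that a nucleotide mismatches at least
        one of the two sequences (b + c + d = p + q*mu), the binomial rate
        that bounds the weight of reads neglected by the truncated power
        sum.  (Note: the per-kind maximum max{b, c, d} does not bound the
        any-mismatch count and would certify nothing.)"""
        return min(1.0 - 1e-12, self.b + self.c + self.d)


@dataclass(frozen=True)
class SeedingOutcome:
    """The (on-target, off-target, null) probability triple for one instance."""

    p_on: float
    p_off: float
    p_null: float
    p_no_target_seed: float
    p_no_seed_pair: float
    method: str = "matrix"
    n_samples: int | None = None
    stderr: float | None = None

    def __post_init__(self) -> None:
        if abs(self.p_on + self.p_off + self.p_null - 1.0) > 1e-6:
            raise ValueError("p_on + p_off + p_null must equal 1")

    def as_dict(self) -> dict:
        out = {
            "p_on": self.p_on,
            "p_off": self.p_off,
            "p_null": self.p_null,
            "method": self.method,
        }
        if self.n_samples is not None:
            out["n_samples"] = self.n_samples
        if self.stderr is not None:
            out["stderr"] = self.stderr
        return out


def prob_no_on_target_exact(params: SeedingParams) -> np.ndarray:
    """Series a_0..a_k where a_j = P(no error-free stretch of length gamma).

    Order-(gamma+1) recurrence:

        a_j = 1                                   for j < gamma
        a_gamma = 1 - q^gamma
        a_j = a_{j-1} - p q^gamma a_{j-gamma-1}   otherwise
    """
    k, gamma, p, q = params.k, params.gamma, params.p, params.q
    a = np.ones(k + 1)
    if gamma > k:
        return a
    qg = q ** gamma
    a[gamma] = 1.0 - qg
    for j in range(gamma + 1, k + 1):
        a[j] = a[j - 1] - p * qg * a[j - gamma - 1]
    return a


def dual_match_probs(p: float, mu: float) -> DualMatchProbs:
    """Joint per-nucleotide probabilities under the error/divergence model.

    A read error (rate p) mismatches the target and matches the duplicate
    with probability mu/3; a correct nucleotide matches the target and
    matches the duplicate with probability 1 - mu.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    q = 1.0 - p
    return DualMatchProbs(a=q * (1.0 - mu), b=q * mu, c=p * mu / 3.0,
                          d=p * (1.0 - mu / 3.0))


def dual_state_labels(gamma: int) -> list[str]:
    """Fixed state ordering of the exact dual matrix (documented contract)."""
    minus = [f"v/{i}-" for i in range(1, gamma)]
    plus = [f"v/{i}+" for i in range(1, gamma)]
    return ["V", *minus, *plus, "|"]


def build_dual_transfer_exact(gamma: int, probs: DualMatchProbs,
                              order: int | None = None) -> TransferMatrix:
    """Transfer matrix of reads with no seed for either of two sequences.

    States: "V" (double mismatch, both match counters reset), "v/i-"
    (mismatch against the duplicate only, target match length i), "v/i+"
    (mismatch against the target only, duplicate match length i), and the
    tail "|".  Entries follow the segment rules: after V up to gamma-1
    double matches may precede any terminator; after v/i+ a v/j- needs
    1 <= j <= gamma-i and a v/j+ needs i < j <= gamma-1 with weight
    (az)^{j-i-1} c z, symmetrically for v/i-.
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    if order is None:
        order = 2 * gamma
    a, b, c, d = probs.a, probs.b, probs.c, probs.d
    M = TransferMatrix(dual_state_labels(gamma), order, initial_state="V")
    geo = TruncatedPolynomial.geometric

    def R(i: int) -> TruncatedPolynomial:  # (1 + az + ... + (az)^i) dz
        return geo(a, i + 1, order, shift=1, scale=d)

    def F(i: int) -> TruncatedPolynomial:  # 1 + az + ... + (az)^i
        return geo(a, i + 1, order)

    mono = TruncatedPolynomial.monomial
    M.set_entry("V", "V", R(gamma - 1))
    M.set_entry("V", "|", F(gamma - 1))
    for j in range(1, gamma):
        M.set_entry("V", f"v/{j}-", mono(a ** (j - 1) * b, j, order))
        M.set_entry("V", f"v/{j}+", mono(a ** (j - 1) * c, j, order))
    for i in range(1, gamma):
        M.set_entry(f"v/{i}-", "V", R(gamma - i - 1))
        M.set_entry(f"v/{i}-", "|", F(gamma - i - 1))
        M.set_entry(f"v/{i}+", "V", R(gamma - i - 1))
        M.set_entry(f"v/{i}+", "|", F(gamma - i - 1))
        for j in range(i + 1, gamma):
            M.set_entry(f"v/{i}-", f"v/{j}-", mono(a ** (j - i - 1) * b, j - i, order))
            M.set_entry(f"v/{i}+", f"v/{j}+", mono(a ** (j - i - 1) * c, j - i, order))
        for j in range(1, gamma - i + 1):
            if j <= gamma - 1:
                M.set_entry(f"v/{i}-", f"v/{j}+", mono(a ** (j - 1) * c, j, order))
                M.set_entry(f"v/{i}+", f"v/{j}-", mono(a ** (j - 1) * b, j, order))
    M.validate()
    return M


def prob_no_seed_either_exact(params: SeedingParams, epsilon: float = 0.01,
                              series: bool = False):
    """P(no seed for the target nor for one fixed duplicate) at length k.

    Computed as the (V, |) entry series of the dual matrix power sum,
    certified to relative epsilon with the mismatch rate max{b, c, d}.
    With ``series=True`` the whole coefficient series a_0..a_k is returned.
    """
    probs = dual_match_probs(params.p, params.mu)
    gamma = min(params.gamma, params.k + 1)
    if gamma > params.k:
        out = np.ones(params.k + 1)
        return out if series else 1.0
    M = build_dual_transfer_exact(gamma, probs, order=params.k)
    conv = ConvergenceConfig(epsilon=epsilon, errors_per_power=lambda s: s,
                             mismatch_rate=probs.mismatch_rate)
    a = accumulate_power_sum(M, conv, params.k)
    return a if series else float(a[params.k])


def combine_outcomes(p_s0bar: float, p_pair: float, N: int,
                     p_no_target_seed: float | None = None,
                     method: str = "matrix",
                     rel_tol: float = 1e-9) -> SeedingOutcome:
    """Combine P(S0bar) and P(S0bar & S1bar) into the outcome triple.

    p_off = P(S0bar) - P(S0bar) (p_pair / P(S0bar))^N and
    p_null = P(S0bar) (p_pair / P(S0bar))^N; with N = 0 the read is null
    whenever the target is unseeded.  ``p_no_target_seed`` allows the
    no-seed event used for p_on to differ from the one entering the ratio
    (MEM seeds pass P(no on-target MEM seed) there).
    """
    if p_no_target_seed is None:
        p_no_target_seed = p_s0bar
    # both inputs carry independent truncation error up to rel_tol
    if p_pair > p_s0bar * (1.0 + rel_tol) + 1e-12:
        raise ValueError("P(S0bar & S1bar) cannot exceed P(S0bar)")
    p_pair = min(p_pair, p_s0bar)
    if N < 0:
        raise ValueError("N must be >= 0")
    if p_s0bar <= 0.0:
        p_null = 0.0
    elif N == 0:
        p_null = p_s0bar
    else:
        p_null = p_s0bar * (p_pair / p_s0bar) ** N
    p_off = max(0.0, p_no_target_seed - p_null)
    p_on = 1.0 - p_no_target_seed
    return SeedingOutcome(p_on=p_on, p_off=p_off, p_null=p_null,
                          p_no_target_seed=p_no_target_seed,
                          p_no_seed_pair=p_pair, method=method)


def off_target_exact(params: SeedingParams,
                     epsilon: float = 0.01) -> SeedingOutcome:
    """Full exact-seed pipeline: recurrence, dual matrix, combination."""
    if params.gamma > params.k:
        return SeedingOutcome(p_on=0.0, p_off=0.0, p_null=1.0,
                              p_no_target_seed=1.0, p_no_seed_pair=1.0)
    p_s0bar = float(prob_no_on_target_exact(params)[params.k])
    p_pair = prob_no_seed_either_exact(params, epsilon=epsilon)
    return combine_outcomes(p_s0bar, p_pair, params.N, rel_tol=epsilon)
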