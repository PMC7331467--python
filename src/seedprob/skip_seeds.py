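"""Skip-n seeds: fixed-size seeds that may start only every n+1 positions.

Skip seeds (Bowtie2-style) reduce the clutter of overlapping hits at the
price of sensitivity: a seed of size gamma may start only at read positions
1, n+2, 2n+3, ... (1-based).  The on-target construction recodes reads in
the skip alphabet whose error symbols carry their phase (the distance to the
next non-skipped position); the off-target construction extends the dual
alphabet with phase-carrying double-reset symbols and "fast-forward"
projections for errors that land mid-interval.

All index arithmetic (the x, y, m offsets of the segment generating
functions) lives in the small helpers below; they are the dominant
off-by-one risk and are unit-tested exhaustively.
"""

from __future__ import annotations

import numpy as np

from .exact_seeds import (
    DualMatchProbs,
    SeedingOutcome,
    SeedingParams,
    combine_outcomes,
    dual_match_probs,
    prob_no_on_target_exact,
)
from .gfcore import (
    ConvergenceConfig,
    TransferMatrix,
    TruncatedPolynomial,
    accumulate_power_sum,
)

__all__ = [
    "build_skip_transfer",
    "prob_no_on_target_skip",
    "build_skip_dual_transfer",
    "prob_no_seed_either_skip",
    "off_target_skip",
    "skip_offset_x",
    "skip_phase_y",
    "skip_num_extra",
]


def skip_offset_x(i: int, j: int, n: int) -> int:
    """Number of matches in the shortest segment from phase i to phase j.

    For on-target segments this is (i - j - 1) mod (n + 1); the dual rows
    use it with i replaced by -i (phase counted from the seed-relevant run
    start), i.e. callers pass the appropriate signed first argument.
    """
    return (i - j - 1) % (n + 1)


def skip_phase_y(i: int, n: int) -> int:
    """Distance from a v/i terminator to the last skipped position before
    the next non-skipped one: y = -i mod (n+1)."""
    return (-i) % (n + 1)


def skip_num_extra(budget: int, x: int, n: int) -> int:
    """Largest m with x + m(n+1) <= budget; -1 when even x exceeds it."""
    if x > budget:
        return -1
    return (budget - x) // (n + 1)


def _effective_n(n: int, k: int, gamma: int) -> int:
    # Seed starts beyond the read never matter; capping n keeps the state
    # space bounded without changing any coefficient up to degree k.
    return min(n, max(k, gamma))


def skip_state_labels(gamma: int, n: int, dual: bool) -> list[str]:
    down = [f"S{i}" for i in range(n + 1)]
    if not dual:
        return [*down, "|"]
    minus = [f"v/{i}-" for i in range(1, gamma)]
    plus = [f"v/{i}+" for i in range(1, gamma)]
    return [*down, *minus, *plus, "|"]


def build_skip_transfer(gamma: int, n: int, p: float,
                        order: int | None = None) -> TransferMatrix:
    """On-target skip-n transfer matrix M_n(z).

    States S_i are error symbols with i nucleotides to the next non-skipped
    position; the (S_i, S_j) entry is
    H_{i,j}(z) = (qz)^x (1 + (qz)^{n+1} + ... + (qz)^{m(n+1)}) pz with
    x = (i-j-1) mod (n+1) and m = floor((gamma+i-1-x)/(n+1)); the tail entry
    is J_i(z) = 1 + qz + ... + (qz)^{gamma+i-1}.  With n = 0 this is exactly
    the two-state exact-seed matrix.
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    if order is None:
        order = 2 * (gamma + n)
    n = _effective_n(n, order, gamma)
    q = 1.0 - p
    M = TransferMatrix(skip_state_labels(gamma, n, dual=False), order,
                       initial_state="S0")
    geo = TruncatedPolynomial.geometric
    for i in range(n + 1):
        for j in range(n + 1):
            x = skip_offset_x(i, j, n)
            m = skip_num_extra(gamma + i - 1, x, n)
            if m < 0:
                continue
            M.set_entry(f"S{i}", f"S{j}",
                        geo(q ** (n + 1), m + 1, order, step=n + 1,
                            shift=x + 1, scale=q ** x * p))
        M.set_entry(f"S{i}", "|", geo(q, gamma + i, order))
    M.validate()
    return M


def prob_no_on_target_skip(params: SeedingParams,
                           epsilon: float = 0.01) -> np.ndarray:
    """Series a_0..a_k of P(read of size j has no on-target skip-n seed)."""
    if params.n == 0:
        return prob_no_on_target_exact(params)
    M = build_skip_transfer(params.gamma, params.n, params.p, order=params.k)
    conv = ConvergenceConfig(epsilon=epsilon, errors_per_power=lambda s: s,
                             mismatch_rate=params.p)
    return accumulate_power_sum(M, conv, params.k)


def build_skip_dual_transfer(gamma: int, n: int, probs: DualMatchProbs,
                             order: int | None = None) -> TransferMatrix:
    """Skip-n dual transfer matrix for P(no seed for either sequence).

    States: S_0..S_n (both match counters effectively zero, phase-indexed),
    v/i- (mismatch against the duplicate, target run i counted from a
    non-skipped position), v/i+ (the mirror image), and the tail.  The S_i
    rows (i >= 1) only "fast forward": they project to S_0 with weight z^i
    (the skipped interval carries no constraint) or end the read with weight
    1 + z + ... + z^{i-1}.  The v rows include the correction terms for a
    single mismatch of the opposite sign landing inside the same inter-skip
    interval, which re-enters an S_j state rather than a v state.
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    if order is None:
        order = 2 * (gamma + n)
    n = _effective_n(n, order, gamma)
    a, b, c, d = probs.a, probs.b, probs.c, probs.d
    M = TransferMatrix(skip_state_labels(gamma, n, dual=True), order,
                       initial_state="S0")
    geo = TruncatedPolynomial.geometric
    mono = TruncatedPolynomial.monomial
    zero = TruncatedPolynomial.zero(order)

    def reset_entry(run: int, j: int, delta_weight: float) -> TruncatedPolynomial:
        """Segments from a state with ongoing target-or-duplicate run ``run``
        to S_j: double-mismatch terminators at phase-compatible positions,
        plus the same-interval single-mismatch correction."""
        y = skip_phase_y(run, n)
        x = skip_offset_x(-run, j, n)
        m = skip_num_extra(gamma - 1 - run, x, n)
        poly = zero
        if m >= 0:
            poly = poly + geo(a ** (n + 1), m + 1, order, step=n + 1,
                              shift=x + 1, scale=a ** x * d)
        if j < y and run + x <= gamma - 1 and delta_weight > 0.0:
            poly = poly + mono(a ** x * delta_weight, x + 1, order)
        return poly

    # Rows S_i, i >= 1: fast-forward projections.
    for i in range(1, n + 1):
        M.set_entry(f"S{i}", "S0", mono(1.0, i, order))
        M.set_entry(f"S{i}", "|", geo(1.0, i, order))

    # Row S_0: all counters reset, next position non-skipped.
    for j in range(n + 1):
        x = skip_offset_x(0, j, n)
        m = skip_num_extra(gamma - 1, x, n)
        if m >= 0:
            M.set_entry("S0", f"S{j}",
                        geo(a ** (n + 1), m + 1, order, step=n + 1,
                            shift=x + 1, scale=a ** x * d))
    for j in range(1, gamma):
        M.set_entry("S0", f"v/{j}-", mono(a ** (j - 1) * b, j, order))
        M.set_entry("S0", f"v/{j}+", mono(a ** (j - 1) * c, j, order))
    M.set_entry("S0", "|", geo(a, gamma, order))

    # Rows v/i- and v/i+.
    for i in range(1, gamma):
        y = skip_phase_y(i, n)
        M.set_entry(f"v/{i}-", "|", geo(a, gamma - i, order))
        M.set_entry(f"v/{i}+", "|", geo(a, gamma - i, order))
        for j in range(i + 1, gamma):
            M.set_entry(f"v/{i}-", f"v/{j}-", mono(a ** (j - i - 1) * b, j - i, order))
            M.set_entry(f"v/{i}+", f"v/{j}+", mono(a ** (j - i - 1) * c, j - i, order))
        for j in range(1, gamma):
            if i + j + y <= gamma:
                M.set_entry(f"v/{i}-", f"v/{j}+", mono(a ** (y + j - 1) * c, y + j, order))
                M.set_entry(f"v/{i}+", f"v/{j}-", mono(a ** (y + j - 1) * b, y + j, order))
        for j in range(n + 1):
            M.set_entry(f"v/{i}-", f"S{j}", reset_entry(i, j, c))
            M.set_entry(f"v/{i}+", f"S{j}", reset_entry(i, j, b))
    M.validate()
    return M


def prob_no_seed_either_skip(params: SeedingParams, epsilon: float = 0.01,
                             series: bool = False):
    """P(no skip-n seed for the target nor for one fixed duplicate)."""
    probs = dual_match_probs(params.p, params.mu)
    if params.gamma > params.k:
        out = np.ones(params.k + 1)
        return out if series else 1.0
    M = build_skip_dual_transfer(params.gamma, params.n, probs, order=params.k)
    # Fast-forward projections carry no mismatch, but each one follows a
    # mismatch segment, so s accumulated powers still certify floor(s/2)
    # mismatches in every neglected read.
    conv = ConvergenceConfig(epsilon=epsilon, errors_per_power=lambda s: s // 2,
                             mismatch_rate=probs.mismatch_rate)
    arr = accumulate_power_sum(M, conv, params.k)
    return arr if series else float(arr[params.k])


def off_target_skip(params: SeedingParams,
                    epsilon: float = 0.01) -> SeedingOutcome:
    """Skip-seed outcome triple via the on-target and dual skip matrices."""
    if params.gamma > params.k:
        return SeedingOutcome(p_on=0.0, p_off=0.0, p_null=1.0,
                              p_no_target_seed=1.0, p_no_seed_pair=1.0)
    p_s0bar = float(prob_no_on_target_skip(params, epsilon=epsilon)[params.k])
    p_pair = prob_no_seed_either_skip(params, epsilon=epsilon)
    return combine_outcomes(p_s0bar, p_pair, params.N, rel_tol=epsilon)
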