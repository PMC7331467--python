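"""MEM seeds: maximal exact matches of minimum size gamma.

A MEM is a read subsequence with a genomic match that cannot be extended on
either side; MEM seeds (BWA-MEM style) are MEMs of size >= gamma.  Unlike
fixed-size seeds, duplicates can *mask* the target: at a read position, a
duplicate whose leftward match run is strictly longer than the target's is
a hard mask, one with an equal run is a soft mask.  A read has no on-target
MEM seed when every long error-free stretch is covered by a hard mask, or
by a soft mask extending through the flanking errors.

P(no on-target MEM seed) is computed from the transfer matrix over the MEM
alphabet (states d/m = sequencing error with m hard masks, u/i = first
unmasked nucleotide i positions after the last error), built from the mask
survival probabilities

    omega_m = C(N, m) (mu/3)^m (1 - mu/3)^{N-m}   (hard masks at an error)
    xi_j    = 1 - (1-mu)^j                        (mask dies within j matches)
    eta_j   = 1 - (1-mu)^j mu/3                   (dies within j matches + error)

and the terminator-splitting probabilities zeta_{j,m,n}.  For large N the
matrix is impractical and a segment-level Monte Carlo sampler with per-cycle
cost independent of N estimates the same probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import comb
from scipy.stats import binom

from .exact_seeds import (
    SeedingOutcome,
    SeedingParams,
    combine_outcomes,
    prob_no_on_target_exact,
    prob_no_seed_either_exact,
)
from .gfcore import (
    ConvergenceConfig,
    TransferMatrix,
    TruncatedPolynomial,
    accumulate_power_sum,
)

__all__ = [
    "MEMQuantities",
    "MonteCarloEstimate",
    "mem_quantities",
    "build_mem_transfer",
    "prob_no_on_target_mem",
    "mem_monte_carlo",
    "off_target_mem",
]

#: Above this number of duplicates the transfer matrix is considered too
#: large and the Monte Carlo route is used (configurable per call).
DEFAULT_N_SWITCH = 20


@dataclass(frozen=True)
class MonteCarloEstimate:
    """Frequency estimate of an event probability with binomial stderr."""

    p_hat: float
    n_samples: int
    stderr: float
    rng_seed: int

    @classmethod
    def from_counts(cls, hits: int, n_samples: int,
                    rng_seed: int) -> "MonteCarloEstimate":
        p_hat = hits / n_samples
        return cls(p_hat=p_hat, n_samples=n_samples,
                   stderr=float(np.sqrt(p_hat * (1.0 - p_hat) / n_samples)),
                   rng_seed=rng_seed)


class MEMQuantities:
    """The omega / xi / eta / zeta machinery for N duplicates at rate mu."""

    def __init__(self, N: int, mu: float, K: int):
        if N < 0:
            raise ValueError("N must be >= 0")
        if not 0.0 <= mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        self.N, self.mu, self.K = N, mu, K
        j = np.arange(K + 1)
        self.omega = binom.pmf(np.arange(N + 1), N, mu / 3.0)
        self.xi = 1.0 - (1.0 - mu) ** j
        self.eta = 1.0 - (1.0 - mu) ** j * (mu / 3.0)

    @lru_cache(maxsize=None)
    def _psi_zeta_row(self, m: int, n: int) -> np.ndarray:
        """zeta_{j,m,n} for all j = 0..K (meaningful for j >= gamma)."""
        N, mu = self.N, self.mu
        j = np.arange(self.K + 1)
        out = np.zeros(self.K + 1)
        denom = comb(N, n)
        if denom == 0:
            return out
        for r in range(1, min(N - m, n) + 1):
            psi = np.zeros(self.K + 1)
            for q in range(0, min(m, n - r) + 1):
                c2 = comb(N - m - r, n - r - q)
                if c2 == 0:
                    continue
                psi += comb(m, q) * c2 * self.xi ** (n - r - q)
            out += comb(N - m, r) * (1.0 - mu) ** (r * j) * psi
        return out / denom

    def zeta(self, j: int, m: int, n: int) -> float:
        """P(terminator is d/n AND >= 1 soft mask spans segment+terminator |
        segment of j error-free nucleotides after d/m, all m hard masks
        vanish within the segment), divided by omega_n."""
        return float(self._psi_zeta_row(m, n)[j])


def mem_quantities(N: int, mu: float, K: int) -> MEMQuantities:
    """Compute the omega/xi/eta arrays and the zeta function up to order K."""
    return MEMQuantities(N, mu, K)


def mem_state_labels(gamma: int, N: int) -> list[str]:
    return [f"d/{m}" for m in range(N + 1)] + \
           [f"u/{i}" for i in range(1, gamma)] + ["|"]


def build_mem_transfer(gamma: int, p: float, N: int, mu: float,
                       K: int) -> TransferMatrix:
    """Transfer matrix of reads with no on-target MEM seed.

    Dimension (N + gamma + 1); rows d/m hold the A (error-to-error), B
    (masks vanish at an unmasked nucleotide, restricted to j < gamma) and C
    (tail) entries; rows u/i hold the D and E entries bounding the strict
    MEM below gamma.  Infinite tail sums are truncated at degree K.  With
    N = 0 there are no masks and the matrix reduces to the exact-seed one.
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    if K < gamma:
        raise ValueError("truncation order K must be >= gamma")
    q = 1.0 - p
    M = TransferMatrix(mem_state_labels(gamma, N), K, initial_state="d/0")
    jj = np.arange(K + 1)
    qpow = q ** jj

    if N == 0:
        # No duplicates: no masks, MEM seeds behave exactly like exact seeds.
        coeffs = np.zeros(K + 1)
        coeffs[1: gamma + 1] = p * qpow[:gamma]
        M.set_entry("d/0", "d/0", TruncatedPolynomial(coeffs, K))
        M.set_entry("d/0", "|",
                    TruncatedPolynomial.geometric(q, gamma, K))
        M.validate()
        return M

    quant = mem_quantities(N, mu, K)
    xi, omega = quant.xi, quant.omega
    xiN = xi ** N
    no_unmask = 1.0 - xiN            # some mask survives j clean nucleotides

    for m in range(N + 1):
        row = f"d/{m}"
        xim = xi ** m if m > 0 else np.ones(K + 1)
        hard_survives = 1.0 - xim
        # A entries: next terminator is another error.
        for n in range(N + 1):
            zrow = quant._psi_zeta_row(m, n)
            body = np.where(jj < gamma, no_unmask, hard_survives + xim * zrow)
            coeffs = np.zeros(K + 1)
            coeffs[1:] = omega[n] * p * (qpow * body)[:K]
            M.set_entry(row, f"d/{n}", TruncatedPolynomial(coeffs, K))
        # B entries: all masks vanish at the j-th clean nucleotide (j < gamma).
        for j in range(1, gamma):
            w = (xiN[j] - xiN[j - 1]) * qpow[j]
            M.set_entry(row, f"u/{j}",
                        TruncatedPolynomial.monomial(w, j, K))
        # C entry: the tail.
        tail = np.where(jj < gamma, no_unmask, hard_survives) * qpow
        M.set_entry(row, "|", TruncatedPolynomial(tail, K))

    for i in range(1, gamma):
        row = f"u/{i}"
        # D entries: the strict MEM must stay below gamma nucleotides.
        for m in range(N + 1):
            coeffs = np.zeros(K + 1)
            top = min(gamma - i - 1, K - 1)
            coeffs[1: top + 2] = omega[m] * p * qpow[: top + 1]
            M.set_entry(row, f"d/{m}", TruncatedPolynomial(coeffs, K))
        M.set_entry(row, "|",
                    TruncatedPolynomial.geometric(q, gamma - i, K))
    M.validate()
    return M


def prob_no_on_target_mem(params: SeedingParams, epsilon: float = 0.01,
                          series: bool = False):
    """P(no on-target MEM seed) at read length k via the transfer matrix.

    A read of s + 1 segments holds at least floor(s/2) sequencing errors
    (u and d terminators must alternate), which drives the stopping bound.
    """
    if params.gamma > params.k:
        out = np.ones(params.k + 1)
        return out if series else 1.0
    M = build_mem_transfer(params.gamma, params.p, params.N, params.mu,
                           K=params.k)
    conv = ConvergenceConfig(epsilon=epsilon, errors_per_power=lambda s: s // 2,
                             mismatch_rate=params.p)
    arr = accumulate_power_sum(M, conv, params.k)
    return arr if series else float(arr[params.k])


def mem_monte_carlo(params: SeedingParams, n_samples: int,
                    rng_seed: int) -> MonteCarloEstimate:
    """Estimate P(read has an on-target MEM seed) by segment-level sampling.

    Reads are generated as alternating error-free stretches and errors; only
    the counts of hard masks are tracked, so each cycle costs a handful of
    binomial draws regardless of N.  Per cycle: (i) the gap to the next
    error is geometric(p), truncated at the read end; (ii) mask survival
    across the stretch (rate (1-mu)^j) and across the error nucleotide
    (rate mu/3, or mu/3 * xi_j/eta_j for masks known to die within the
    segment) decides whether the stretch is an unblocked target MEM of size
    >= gamma.  The estimate is reproducible for a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    k, gamma, p, N, mu = params.k, params.gamma, params.p, params.N, params.mu
    rng = np.random.default_rng(rng_seed)
    t = np.zeros(n_samples, dtype=np.int64)       # nucleotides consumed
    m = np.zeros(n_samples, dtype=np.int64)       # hard masks at last error
    hit = np.zeros(n_samples, dtype=bool)
    alive = np.ones(n_samples, dtype=bool)
    third = mu / 3.0
    while True:
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        rem = k - t[idx]
        gap = rng.geometric(p, idx.size) - 1      # clean nucleotides drawn
        is_tail = gap >= rem
        j = np.where(is_tail, rem, gap)
        surv = (1.0 - mu) ** j
        long = j >= gamma
        hard_left = np.zeros(idx.size, dtype=np.int64)
        if long.any():
            hard_left[long] = rng.binomial(m[idx[long]], surv[long])

        # Tail stretches: seed iff the stretch is long and no hard mask
        # survives it (a surviving soft mask yields a shared on-target MEM).
        tail_sel = is_tail
        seed_tail = tail_sel & long & (hard_left == 0)
        hit[idx[seed_tail]] = True
        alive[idx[tail_sel]] = False

        # Internal stretches ending in an error.
        inner = ~is_tail
        if not inner.any():
            continue
        new_m = np.empty(idx.size, dtype=np.int64)
        # Short stretch: nothing can seed; the error's hard masks are the
        # duplicates matching the error nucleotide, Binomial(N, mu/3).
        short_inner = inner & ~long
        new_m[short_inner] = rng.binomial(N, third, int(short_inner.sum()))
        # Long stretch with a hard survivor: blocked, same refresh.
        blocked = inner & long & (hard_left > 0)
        new_m[blocked] = rng.binomial(N, third, int(blocked.sum()))
        # Long stretch, hard masks gone: soft masks spanning the stretch
        # *and* the error block the seed; otherwise the MEM is on-target.
        open_ = inner & long & (hard_left == 0)
        if open_.any():
            oi = np.flatnonzero(open_)
            r = rng.binomial((N - m[idx[oi]]), surv[oi] * third)
            seeded = r == 0
            hit[idx[oi[seeded]]] = True
            alive[idx[oi[seeded]]] = False
            bi = oi[~seeded]
            if bi.size:
                jv = j[bi].astype(float)
                xi_j = 1.0 - (1.0 - mu) ** jv
                eta_j = 1.0 - (1.0 - mu) ** jv * third
                p_dead_soft = np.where(eta_j > 0.0, third * xi_j / eta_j, 0.0)
                new_m[bi] = (r[~seeded]
                             + rng.binomial(m[idx[bi]], third)
                             + rng.binomial(N - m[idx[bi]] - r[~seeded],
                                            p_dead_soft))
        adv = inner & alive[idx]
        ai = np.flatnonzero(adv)
        t[idx[ai]] += j[ai] + 1
        m[idx[ai]] = new_m[ai]

    return MonteCarloEstimate.from_counts(int(hit.sum()), n_samples, rng_seed)


def off_target_mem(params: SeedingParams, epsilon: float = 0.01,
                   n_switch: int = DEFAULT_N_SWITCH,
                   n_samples: int = 1_000_000,
                   rng_seed: int = 0) -> SeedingOutcome:
    """MEM-seed outcome triple.

        p_off = P(no on-target MEM seed) - P(S0bar) (P(S0bar&S1bar)/P(S0bar))^N

    The second term reuses the exact-seed quantities: there is *some* MEM
    seed iff some sequence has a match of size >= gamma, so the null event
    coincides with the all-sequences-unseeded event of exact seeds.
    P(no on-target MEM seed) uses the transfer matrix for N <= n_switch and
    the Monte Carlo sampler beyond.
    """
    if params.gamma > params.k:
        return SeedingOutcome(p_on=0.0, p_off=0.0, p_null=1.0,
                              p_no_target_seed=1.0, p_no_seed_pair=1.0)
    if params.N <= n_switch:
        p_m0bar = prob_no_on_target_mem(params, epsilon=epsilon)
        method, ns, se = "matrix", None, None
    else:
        est = mem_monte_carlo(params, n_samples, rng_seed)
        p_m0bar, method, ns, se = 1.0 - est.p_hat, "monte_carlo", est.n_samples, est.stderr
    p_s0bar = float(prob_no_on_target_exact(params)[params.k])
    p_pair = prob_no_seed_either_exact(params, epsilon=epsilon)
    out = combine_outcomes(p_s0bar, p_pair, params.N,
                           p_no_target_seed=p_m0bar, method=method,
                           rel_tol=epsilon)
    if ns is not None:
        out = SeedingOutcome(p_on=out.p_on, p_off=out.p_off, p_null=out.p_null,
                             p_no_target_seed=out.p_no_target_seed,
                             p_no_seed_pair=out.p_no_seed_pair,
                             method=method, n_samples=ns, stderr=se)
    return out
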