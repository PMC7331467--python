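"""Truncated-polynomial arithmetic and the transfer-matrix power-sum engine.

Seeding probabilities are coefficients of weighted generating functions
A(z) = sum_a w(a) z^|a| over recoded reads, where the weight of a read is its
probability and the size is its length in nucleotides.  Because only the
coefficients up to the read length k are ever needed, every polynomial is
truncated at a fixed order K, and the generating function of interest is
extracted from partial sums M + M^2 + ... of a transfer matrix M(z) whose
(i, j) entry is the generating function of segments of type j that can be
appended to segments of type i.

The partial sum is stopped early with a certified error bound: reads omitted
after accumulating s powers must contain at least e(s) sequencing errors
(the mapping s -> e depends on the seed type), and the binomial tail
Pr(X >= e), X ~ B(k, p), is bounded by a Chernoff-type inequality.  Since
every non-tail segment has size >= 1, accumulating K + 1 powers is always
exact, so the bound only ever shortens the computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom


__all__ = [
    "TruncatedPolynomial",
    "TransferMatrix",
    "ConvergenceConfig",
    "ConvergenceError",
    "poly_combine",
    "accumulate_power_sum",
    "chernoff_bound",
    "binomial_tail_exact",
]


class ConvergenceError(RuntimeError):
    """Raised when the power sum cannot be certified within ``max_powers``."""


@dataclass(frozen=True)
class TruncatedPolynomial:
    """A polynomial kept to finite order K; the computational currency.

    ``coeffs[j]`` is the total weight of objects of size j.  Operations that
    would produce terms of degree > K discard them.
    """

    coeffs: np.ndarray
    order: int

    def __init__(self, coeffs: Sequence[float], order: int | None = None):
        arr = np.asarray(coeffs, dtype=float)
        if arr.ndim != 1:
            raise ValueError("coefficients must be a 1-D sequence")
        if order is None:
            order = arr.size - 1
        if order < 0:
            raise ValueError("order must be non-negative")
        if arr.size > order + 1:
            raise ValueError("more coefficients than order + 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("coefficients must be finite")
        if np.any(arr < 0):
            raise ValueError("coefficients are weights and must be >= 0")
        full = np.zeros(order + 1)
        full[: arr.size] = arr
        object.__setattr__(self, "coeffs", full)
        object.__setattr__(self, "order", order)

    @classmethod
    def zero(cls, order: int) -> "TruncatedPolynomial":
        return cls(np.zeros(order + 1), order)

    @classmethod
    def one(cls, order: int) -> "TruncatedPolynomial":
        c = np.zeros(order + 1)
        c[0] = 1.0
        return cls(c, order)

    @classmethod
    def monomial(cls, weight: float, degree: int, order: int) -> "TruncatedPolynomial":
        c = np.zeros(order + 1)
        if degree <= order:
            c[degree] = weight
        return cls(c, order)

    @classmethod
    def geometric(cls, ratio: float, n_terms: int, order: int,
                  step: int = 1, shift: int = 0,
                  scale: float = 1.0) -> "TruncatedPolynomial":
        """scale * z^shift * (1 + (ratio z^step) + ... + (ratio z^step)^{n-1})."""
        c = np.zeros(order + 1)
        for t in range(n_terms):
            d = shift + t * step
            if d > order:
                break
            c[d] += scale * ratio ** t
        return cls(c, order)

    def __add__(self, other: "TruncatedPolynomial") -> "TruncatedPolynomial":
        return poly_combine(self, other, "add")

    def __mul__(self, other: "TruncatedPolynomial") -> "TruncatedPolynomial":
        return poly_combine(self, other, "mul")

    def __call__(self, z: float) -> float:
        return float(np.polynomial.polynomial.polyval(z, self.coeffs))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TruncatedPolynomial):
            return NotImplemented
        return self.order == other.order and bool(
            np.array_equal(self.coeffs, other.coeffs)
        )


def poly_combine(f: TruncatedPolynomial, g: TruncatedPolynomial,
                 op: str) -> TruncatedPolynomial:
    """Combine two truncated polynomials: sizes add, weights multiply.

    ``add`` merges two disjoint families of objects (coefficient-wise sum);
    ``mul`` concatenates them (convolution truncated at the shared order).
    """
    if f.order != g.order:
        raise ValueError(f"order mismatch: {f.order} != {g.order}")
    if op == "add":
        return TruncatedPolynomial(f.coeffs + g.coeffs, f.order)
    if op == "mul":
        full = np.convolve(f.coeffs, g.coeffs)
        return TruncatedPolynomial(full[: f.order + 1], f.order)
    raise ValueError(f"unknown op {op!r}")


class TransferMatrix:
    """Square matrix of truncated polynomials indexed by terminator labels.

    The (i, j) entry is the generating function of segments of type j that
    can be appended to segments of type i.  The tail state (end-of-read
    terminator "|") has an identically zero row: a tail cannot be followed
    by anything.  The series of interest is read from the
    (initial_state, tail_state) entry of M + M^2 + ...
    """

    def __init__(self, states: Sequence[str], order: int,
                 initial_state: str, tail_state: str = "|"):
        self.states = list(states)
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state labels")
        self.order = int(order)
        self.initial_state = initial_state
        self.tail_state = tail_state
        self._index = {s: i for i, s in enumerate(self.states)}
        for s in (initial_state, tail_state):
            if s not in self._index:
                raise ValueError(f"state {s!r} not in state list")
        dim = len(self.states)
        self.array = np.zeros((dim, dim, self.order + 1))

    @property
    def dim(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self._index[state]

    def set_entry(self, row: str, col: str, poly: TruncatedPolynomial) -> None:
        if poly.order != self.order:
            raise ValueError("entry order does not match matrix order")
        self.array[self._index[row], self._index[col], :] = poly.coeffs

    def entry(self, row: str, col: str) -> TruncatedPolynomial:
        return TruncatedPolynomial(
            self.array[self._index[row], self._index[col]].copy(), self.order
        )

    def validate(self) -> None:
        if np.any(self.array < 0):
            raise ValueError("transfer matrix entries must be non-negative")
        if np.any(self.array[self._index[self.tail_state]] != 0.0):
            raise ValueError("tail row must be identically zero")


@dataclass
class ConvergenceConfig:
    """Stopping rule for the truncated power sum.

    ``epsilon`` is the relative accuracy target on the coefficient of
    interest; ``errors_per_power`` maps the number s of accumulated powers to
    the minimum number of mismatches e carried by any neglected read (e.g.
    s -> s for on-target fixed-size seeds, s -> floor(s/2) for the skip dual
    and MEM constructions); ``mismatch_rate`` is the per-nucleotide rate fed
    to the Chernoff bound (p for on-target matrices, max{b, c, d} for duals).
    """

    epsilon: float = 0.01
    max_powers: int | None = None
    errors_per_power: Callable[[int], int] = field(default=lambda s: s)
    mismatch_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")


def chernoff_bound(k: int, p: float, s: int) -> float:
    """Chernoff-type upper bound on Pr(X >= s) for X ~ Binomial(k, p).

        Pr(X >= s) <= exp((s-k) log[(k-s)/(k(1-p))] - s log[s/(kp)])

    with the conventions 0*log(0) = 0 (both at s = 0 and s = k).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    if s < 0 or s > k:
        raise ValueError("s must satisfy 0 <= s <= k")
    if s <= k * p:
        return 1.0  # the large-deviation bound only holds above the mean
    log_term1 = 0.0 if s == k else (s - k) * np.log((k - s) / (k * (1.0 - p)))
    log_term2 = 0.0 if s == 0 else -s * np.log(s / (k * p))
    return float(min(1.0, np.exp(log_term1 + log_term2)))


def binomial_tail_exact(k: int, p: float, s: int, side: str = "ge") -> float:
    """Exact binomial tail by log-space summation of the pmf.

    ``side='ge'`` returns P(X >= s); ``side='le'`` returns P(X <= s),
    for X ~ Binomial(k, p).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if s < 0 or s > k:
        raise ValueError("s must satisfy 0 <= s <= k")
    if side == "ge":
        support = np.arange(s, k + 1)
    elif side == "le":
        support = np.arange(0, s + 1)
    else:
        raise ValueError("side must be 'ge' or 'le'")
    if p in (0.0, 1.0):
        return float(np.sum(binom.pmf(support, k, p)))
    return float(np.exp(logsumexp(binom.logpmf(support, k, p))))


def _row_times_matrix(v: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Truncated product of a polynomial row vector with a polynomial matrix.

    v has shape (dim, K+1), m has shape (dim, dim, K+1); the result r
    satisfies r[j, d] = sum_l sum_{d1+d2=d} v[l, d1] m[l, j, d2].
    """
    dim, k1 = v.shape
    out = np.zeros((m.shape[1], k1))
    for d1 in range(k1):
        col = v[:, d1]
        if not np.any(col):
            continue
        out[:, d1:] += np.tensordot(col, m[:, :, : k1 - d1], axes=(0, 0))
    return out


def accumulate_power_sum(M: TransferMatrix, conv: ConvergenceConfig,
                         k_of_interest: int) -> np.ndarray:
    """Coefficient series of the (initial, tail) entry of M + M^2 + ...

    Powers are accumulated until the Chernoff bound on neglected reads drops
    below ``conv.epsilon`` times the running coefficient at ``k_of_interest``,
    or until K + 1 powers make the truncated sum exact (every non-tail
    segment has size >= 1, so M^t only contributes to degrees >= t - 1).
    Raises :class:`ConvergenceError` if ``max_powers`` is hit first.
    """
    if k_of_interest > M.order:
        raise ValueError("k_of_interest exceeds the truncation order")
    M.validate()
    exact_cap = M.order + 1
    cap = exact_cap if conv.max_powers is None else min(conv.max_powers, exact_cap)
    if cap < 1:
        raise ValueError("max_powers must allow at least one power")

    i0 = M.index(M.initial_state)
    itail = M.index(M.tail_state)
    v = M.array[i0].copy()          # row of M^1
    series = v[itail].copy()
    s = 1
    bound = np.inf
    while True:
        if s >= exact_cap:
            return series           # truncated sum is exact at this point
        e = conv.errors_per_power(s)
        if e > k_of_interest:
            return series           # neglected reads need more errors than fit
        if e > 0 and 0.0 < conv.mismatch_rate < 1.0:
            bound = chernoff_bound(k_of_interest, conv.mismatch_rate, e)
            if bound <= conv.epsilon * series[k_of_interest]:
                return series
        if s >= cap:
            raise ConvergenceError(
                f"power sum not certified after {s} powers; "
                f"achieved bound {bound:.3g} vs target "
                f"{conv.epsilon * series[k_of_interest]:.3g}"
            )
        v = _row_times_matrix(v, M.array)
        series += v[itail]
        s += 1
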