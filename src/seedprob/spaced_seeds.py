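"""Spaced seeds: match patterns with don't-care positions (on-target only).

A spaced-seed model such as "11*1*1" matches at a read offset when every
position labeled '1' is a correct nucleotide; '*' positions are ignored.
The probability that a read of size k has no match anywhere is again a
transfer-matrix computation over segments (runs of correct nucleotides
ending in an error): the state records which suffixes of the read, ending
at the last error, are still compatible with a proper prefix of the model
(errors may only sit on '*' positions).  States are materialized by
breadth-first closure from the start state, which yields at most 2^m states
for m don't-care positions plus one tail state.

Off-target probabilities for spaced seeds are out of scope: the dual
construction would need ~4^m states, which is prohibitive for real models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gfcore import (
    ConvergenceConfig,
    TransferMatrix,
    TruncatedPolynomial,
    accumulate_power_sum,
)

__all__ = [
    "SpacedSeedModel",
    "build_spaced_transfer",
    "prob_no_on_target_spaced",
]


@dataclass(frozen=True)
class SpacedSeedModel:
    """A pattern over {1, *}, e.g. "11*1*1"; must start and end with '1'."""

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("pattern must be non-empty")
        if set(self.pattern) - {"1", "*"}:
            raise ValueError("pattern may only contain '1' and '*'")
        if self.pattern[0] != "1" or self.pattern[-1] != "1":
            raise ValueError("pattern must begin and end with '1'")

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def weight(self) -> int:
        return self.pattern.count("1")

    @property
    def m(self) -> int:
        return self.pattern.count("*")

    def wildcard_at(self, pos: int) -> bool:
        """1-based position check for a don't-care slot."""
        return self.pattern[pos - 1] == "*"


def _state_label(fit: frozenset[int]) -> str:
    inner = ",".join(str(v) for v in sorted(fit - {0}))
    return "{" + inner + "}"


def _transition(fit: frozenset[int], i: int, model: SpacedSeedModel) -> frozenset[int]:
    """State reached by appending a segment of i correct nucleotides and an
    error.  Fresh suffixes start inside the segment; inherited fits extend
    through the i matches and land the error on position fit+i+1."""
    G = model.length
    new = {0}
    for s in range(1, min(i + 1, G - 1) + 1):        # fresh: last s symbols
        if model.wildcard_at(s):
            new.add(s)
    for f in fit:
        if f == 0:
            continue
        s = f + i + 1
        if s <= G - 1 and model.wildcard_at(s):
            new.add(s)
    return frozenset(new)


def build_spaced_transfer(model: SpacedSeedModel, p: float,
                          order: int | None = None) -> TransferMatrix:
    """Transfer matrix of reads with no match for the spaced-seed model.

    Each non-tail state is the set of active partial-match lengths (suffix
    lengths of the read, ending at the last error, compatible with a model
    prefix).  From a state, a segment of i correct nucleotides is allowed
    while no active fit can run to a complete match, i.e.
    i <= length - 1 - max(fit); the tail allows the same range of i.
    For "11*1*1" this reproduces the four abstract states of the printed
    matrix plus the tail.
    """
    G = model.length
    if order is None:
        order = 2 * G
    q = 1.0 - p
    start = frozenset({0})
    # BFS closure over reachable states.
    states = [start]
    seen = {start}
    trans: dict[frozenset, list[tuple[int, frozenset]]] = {}
    queue = [start]
    while queue:
        fit = queue.pop()
        moves = []
        for i in range(0, G - max(fit)):
            nxt = _transition(fit, i, model)
            moves.append((i, nxt))
            if nxt not in seen:
                seen.add(nxt)
                states.append(nxt)
                queue.append(nxt)
        trans[fit] = moves
    labels = [_state_label(s) for s in states] + ["|"]
    M = TransferMatrix(labels, order, initial_state=_state_label(start))
    for fit in states:
        row = _state_label(fit)
        agg: dict[str, np.ndarray] = {}
        for i, nxt in trans[fit]:
            col = _state_label(nxt)
            coeffs = agg.setdefault(col, np.zeros(order + 1))
            if i + 1 <= order:
                coeffs[i + 1] += q ** i * p
        for col, coeffs in agg.items():
            M.set_entry(row, col, TruncatedPolynomial(coeffs, order))
        M.set_entry(row, "|",
                    TruncatedPolynomial.geometric(q, G - max(fit), order))
    M.validate()
    return M


def prob_no_on_target_spaced(k: int, model: SpacedSeedModel, p: float,
                             epsilon: float = 0.01) -> np.ndarray:
    """Series a_0..a_k of P(read of size j has no spaced-seed match)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    M = build_spaced_transfer(model, p, order=k)
    conv = ConvergenceConfig(epsilon=epsilon, errors_per_power=lambda s: s,
                             mismatch_rate=p)
    return accumulate_power_sum(M, conv, k)
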