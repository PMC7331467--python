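"""Posterior probability that an aligned candidate hit is spurious.

Even when seeding is null, the candidate set usually contains random hits
from elsewhere in the genome.  Against a random location, mismatches occur
with probability 3/4 per nucleotide; against the true location they occur
with the sequencer error rate p.  With L nucleotides aligned after the seed
and m of them mismatching, Bayes' formula gives

    P(random | m of L mismatch) = 1 / (1 + 4^L (p/3)^m q^{L-m} (1-beta)/beta)

where q = 1 - p and beta is the prior probability that the hit is spurious.
The likelihood-ratio factor is astronomically far from 1 in both regimes,
so the choice of beta is immaterial for small p; the default beta = 1/2
removes the prior term altogether.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["RandomHitQuery", "random_hit_posterior", "likelihood_ratio_factor"]

#: log-odds saturation: |log LR + log prior-odds| beyond this returns exactly
#: 0.0 or 1.0 (the double-precision result would round there anyway).
_LOG_ODDS_CLAMP = 745.0


@dataclass(frozen=True)
class RandomHitQuery:
    """L aligned nucleotides, m observed mismatches, error rate p, prior beta."""

    L: int
    m: int
    p: float
    beta: float = 0.5

    def __post_init__(self) -> None:
        if self.L < 0 or not 0 <= self.m <= self.L:
            raise ValueError("need 0 <= m <= L")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie in (0, 1)")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")


def likelihood_ratio_factor(q: RandomHitQuery) -> float:
    """The factor 4^L (p/3)^m (1-p)^{L-m} (true-location vs random odds)."""
    return math.exp(_log_factor(q))


def _log_factor(q: RandomHitQuery) -> float:
    return (q.L * math.log(4.0) + q.m * math.log(q.p / 3.0)
            + (q.L - q.m) * math.log(1.0 - q.p))


def random_hit_posterior(q: RandomHitQuery) -> float:
    """P(candidate location is random | m mismatches out of L aligned).

    Evaluated in log space; the log-odds are clamped at +/-745 (the
    saturation threshold of double precision) before exponentiation.
    """
    log_odds = _log_factor(q) + math.log((1.0 - q.beta) / q.beta)
    if log_odds > _LOG_ODDS_CLAMP:
        return 0.0
    if log_odds < -_LOG_ODDS_CLAMP:
        return 1.0
    return 1.0 / (1.0 + math.exp(log_odds))
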