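"""Shared brute-force helpers: tiny, direct implementations used as oracles.

These deliberately re-derive seeding events from definitions (windows of
matches, spaced-pattern alignment, interval extension for MEMs) with no
generating functions, so they stay independent of the code paths they
check.
"""

import itertools

import numpy as np
import pytest


def enumerate_error_patterns(k: int, p: float):
    """Yield (error_tuple, probability) over all 2^k error patterns."""
    for bits in itertools.product([0, 1], repeat=k):
        e = sum(bits)
        yield bits, p ** e * (1.0 - p) ** (k - e)


def has_fixed_seed(matches, gamma: int, n: int = 0) -> bool:
    k = len(matches)
    return any(all(matches[s + t] for t in range(gamma))
               for s in range(0, k - gamma + 1, n + 1))


def has_spaced_match(matches, pattern: str) -> bool:
    G = len(pattern)
    return any(all(matches[s + u] for u in range(G) if pattern[u] == "1")
               for s in range(len(matches) - G + 1))


def enum_no_target_seed(k, gamma, p, n=0):
    """Exact P(no on-target fixed seed) by 2^k enumeration."""
    return sum(w for bits, w in enumerate_error_patterns(k, p)
               if not has_fixed_seed([b == 0 for b in bits], gamma, n))


def enum_no_seed_pair(k, gamma, probs, n=0):
    """Exact P(no seed for target nor duplicate) over 4^k joint classes.

    Classes per position: 0 = double match, 1 = mismatch duplicate only,
    2 = mismatch target only, 3 = double mismatch.
    """
    pr = (probs.a, probs.b, probs.c, probs.d)
    total = 0.0
    for pat in itertools.product(range(4), repeat=k):
        w = 1.0
        for c in pat:
            w *= pr[c]
        tm = [c in (0, 1) for c in pat]
        dm = [c in (0, 2) for c in pat]
        if not has_fixed_seed(tm, gamma, n) and not has_fixed_seed(dm, gamma, n):
            total += w
    return total


def enum_no_spaced_match(k, pattern, p):
    return sum(w for bits, w in enumerate_error_patterns(k, p)
               if not has_spaced_match([b == 0 for b in bits], pattern))


def series_from_rational(num, den, k):
    """Taylor coefficients of num(z)/den(z) by the division recurrence —
    an independent route to expand a closed-form generating function."""
    num = list(num) + [0.0] * (k + 1 - len(num))
    den = list(den) + [0.0] * (k + 1 - len(den))
    a = np.zeros(k + 1)
    for j in range(k + 1):
        acc = num[j] - sum(den[i] * a[j - i] for i in range(1, j + 1))
        a[j] = acc / den[0]
    return a


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
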