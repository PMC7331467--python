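"""MEM seeds: mask machinery, transfer matrix, Monte Carlo sampler."""

import numpy as np
import pytest

from seedprob.exact_seeds import SeedingParams, prob_no_on_target_exact
from seedprob.mem_seeds import (
    build_mem_transfer,
    mem_monte_carlo,
    mem_quantities,
    off_target_mem,
    prob_no_on_target_mem,
)
from seedprob.oracle import exhaustive_event_probability


def zeta_conditional_oracle(j, m, n, N, mu, reps, rng):
    """Direct conditional simulation of the zeta split: given a segment of
    j clean nucleotides ending in an error after a d/m terminator, with all
    m hard masks failing inside the segment, measure P(terminator carries n
    matches AND >= 1 soft mask spans segment + terminator)."""
    third = mu / 3.0
    # rejection-sample the conditioning event: all m hard masks mismatch
    # somewhere within the j clean nucleotides
    accepted = 0
    hits = 0
    while accepted < reps:
        batch = min(200_000, 4 * (reps - accepted))
        ok = (rng.random((batch, m, j)) < mu).any(axis=2).all(axis=1)
        nb = int(ok.sum())
        if nb == 0:
            continue
        nb = min(nb, reps - accepted)
        hard_match = (rng.random((nb, m)) < third).sum(axis=1)
        soft_clean = ~(rng.random((nb, N - m, j)) < mu).any(axis=2)
        soft_match = rng.random((nb, N - m)) < third
        spans = (soft_clean & soft_match).any(axis=1)
        n_matches = hard_match + soft_match.sum(axis=1)
        hits += int((spans & (n_matches == n)).sum())
        accepted += nb
    return hits / reps


class TestQuantities:
    def test_omega_is_binomial_pmf(self):
        q = mem_quantities(N=7, mu=0.13, K=10)
        assert q.omega.sum() == pytest.approx(1.0, abs=1e-12)
        assert q.omega[0] == pytest.approx((1 - 0.13 / 3) ** 7)

    def test_xi_eta_boundary_values(self):
        q = mem_quantities(N=3, mu=0.2, K=10)
        assert q.xi[0] == 0.0
        assert q.xi[1] == pytest.approx(0.2)
        assert q.eta[0] == pytest.approx(1 - 0.2 / 3)
        assert np.all(np.diff(q.xi) >= 0)
        assert np.all(q.eta >= q.xi)

    def test_zeta_against_conditional_simulation(self, rng):
        N, mu, j, m, n = 3, 0.1, 5, 1, 1
        q = mem_quantities(N, mu, K=8)
        expect = q.omega[n] * q.zeta(j, m, n)
        reps = 400_000
        got = zeta_conditional_oracle(j, m, n, N, mu, reps, rng)
        se = np.sqrt(got * (1 - got) / reps)
        assert abs(got - expect) < 4 * se

    def test_zeta_normalization(self, rng):
        """Summing the terminator split over n recovers the total
        soft-mask-spans-segment mass measured by the conditional oracle."""
        N, mu, j, m = 3, 0.15, 6, 1
        q = mem_quantities(N, mu, K=8)
        total = sum(q.omega[n] * q.zeta(j, m, n) for n in range(N + 1))
        # closed form: >= 1 of the N-m soft masks survives j clean
        # nucleotides and matches the error
        p_span = 1 - (1 - (1 - mu) ** j * mu / 3) ** (N - m)
        assert total == pytest.approx(p_span, abs=1e-12)


class TestTransferMatrix:
    def test_no_duplicates_reduces_to_exact_seeds(self):
        params = SeedingParams(k=80, gamma=12, p=0.08, N=0)
        series = prob_no_on_target_mem(params, epsilon=1e-12, series=True)
        assert np.allclose(series, prob_no_on_target_exact(params), atol=1e-12)

    def test_short_read_probability_one(self):
        params = SeedingParams(k=30, gamma=12, p=0.05, N=3, mu=0.1)
        series = prob_no_on_target_mem(params, epsilon=1e-12, series=True)
        assert np.allclose(series[:12], 1.0, atol=1e-12)

    def test_segment_weights_substochastic(self):
        M = build_mem_transfer(gamma=5, p=0.1, N=3, mu=0.2, K=20)
        # row sums at z=1 over non-tail entries cannot exceed 1
        totals = M.array.sum(axis=(1, 2))
        for s, label in zip(totals, M.states):
            if label != "|":
                # tail column included; subtract it to test segment mass only
                tail_mass = M.array[M.index(label), M.index("|")].sum()
                assert s - tail_mass <= 1.0 + 1e-9

    @pytest.mark.parametrize("k,gamma,p,mu,N", [
        (8, 3, 0.1, 0.2, 1),
        (8, 3, 0.2, 0.3, 2),
        (7, 2, 0.25, 0.4, 2),
        (9, 4, 0.15, 0.1, 1),
    ])
    def test_against_exhaustive_enumeration(self, k, gamma, p, mu, N):
        params = SeedingParams(k=k, gamma=gamma, p=p, mu=mu, N=N)
        expect = exhaustive_event_probability("no_mem_on_target", params)
        got = prob_no_on_target_mem(params, epsilon=1e-12)
        assert got == pytest.approx(expect, abs=1e-11)

    def test_truncation_order_below_gamma_rejected(self):
        with pytest.raises(ValueError):
            build_mem_transfer(gamma=10, p=0.1, N=1, mu=0.1, K=5)

    def test_masking_only_hides_the_target(self):
        """P(no on-target MEM seed) >= P(no exact seed) whenever N >= 1."""
        for N, mu in [(1, 0.05), (5, 0.1), (10, 0.02)]:
            params = SeedingParams(k=50, gamma=19, p=0.01, N=N, mu=mu)
            mem = prob_no_on_target_mem(params, epsilon=1e-9)
            exact = prob_no_on_target_exact(params)[50]
            assert mem >= exact - 1e-12


class TestMonteCarlo:
    def test_agrees_with_matrix_method(self):
        params = SeedingParams(k=50, gamma=19, p=0.01, N=5, mu=0.05)
        a = prob_no_on_target_mem(params, epsilon=1e-10)
        est = mem_monte_carlo(params, 1_000_000, rng_seed=99)
        assert abs((1 - a) - est.p_hat) < 4 * est.stderr

    def test_no_duplicates_estimates_exact_seed_probability(self):
        params = SeedingParams(k=40, gamma=10, p=0.05, N=0)
        est = mem_monte_carlo(params, 400_000, rng_seed=7)
        expect = 1 - prob_no_on_target_exact(params)[40]
        assert abs(est.p_hat - expect) < 4 * est.stderr

    def test_reproducible_for_fixed_seed(self):
        params = SeedingParams(k=50, gamma=19, p=0.02, N=8, mu=0.08)
        e1 = mem_monte_carlo(params, 50_000, rng_seed=13)
        e2 = mem_monte_carlo(params, 50_000, rng_seed=13)
        assert e1.p_hat == e2.p_hat
        assert e1.stderr == pytest.approx(
            np.sqrt(e1.p_hat * (1 - e1.p_hat) / 50_000))


class TestOffTarget:
    def test_no_duplicates(self):
        out = off_target_mem(SeedingParams(k=30, gamma=9, p=0.1, N=0))
        assert out.p_off == 0.0

    def test_triple_sums_to_one(self):
        out = off_target_mem(SeedingParams(k=50, gamma=19, p=0.01, N=3, mu=0.06),
                             epsilon=1e-9)
        assert out.p_on + out.p_off + out.p_null == pytest.approx(1.0)

    def test_large_n_switches_to_monte_carlo(self):
        out = off_target_mem(SeedingParams(k=40, gamma=19, p=0.01, N=500, mu=0.06),
                             n_samples=50_000, rng_seed=3)
        assert out.method == "monte_carlo"
        assert out.n_samples == 50_000 and out.stderr is not None


class TestCounterintuitiveProperties:
    def test_shortening_a_read_can_create_a_seed(self):
        """A hard mask extending past the target's final matches hides the
        target; trimming those read nucleotides turns it into a soft mask
        and the stretch becomes a shared on-target MEM seed."""
        from seedprob.oracle import SimulatedInstance, detect_mem_on_target
        k, gamma = 10, 4
        target_matches = np.array([True] * 8 + [False, False])
        dup_matches = np.ones((1, k), dtype=bool)  # duplicate matches everywhere
        full = SimulatedInstance(target_matches, dup_matches)
        assert not detect_mem_on_target(full, gamma)
        trimmed = SimulatedInstance(target_matches[:8], dup_matches[:, :8])
        assert detect_mem_on_target(trimmed, gamma)
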