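"""The nucleotide-level oracle: generative model, detectors, estimators."""

import numpy as np
import pytest

from seedprob.exact_seeds import SeedingParams, off_target_exact, \
    prob_no_on_target_exact, prob_no_seed_either_exact
from seedprob.oracle import (
    SimulatedInstance,
    best_location,
    detect_fixed_seed,
    detect_mem_on_target,
    detect_spaced_seed,
    estimate_event_probability,
    exhaustive_event_probability,
    simulate_batch,
    simulate_instance,
    write_instance_fasta,
)
from seedprob.spaced_seeds import SpacedSeedModel


class TestGenerativeModel:
    def test_per_position_marginals(self, rng):
        params = SeedingParams(k=50, gamma=10, p=0.07, N=2, mu=0.12)
        err, dup = simulate_batch(params, 40_000, rng)
        n_pos = err.size
        se = np.sqrt(0.07 * 0.93 / n_pos)
        assert abs(err.mean() - 0.07) < 4 * se
        # duplicates match errors with probability mu/3, correct bases with 1-mu
        at_err = dup[:, 0, :][err]
        se = np.sqrt((0.12 / 3) * (1 - 0.12 / 3) / at_err.size)
        assert abs(at_err.mean() - 0.12 / 3) < 4 * se
        at_ok = dup[:, 1, :][~err]
        se = np.sqrt(0.12 * 0.88 / at_ok.size)
        assert abs(at_ok.mean() - 0.88) < 4 * se

    def test_identical_duplicates_at_mu_zero(self):
        params = SeedingParams(k=40, gamma=5, p=0.2, N=3, mu=0.0)
        inst = simulate_instance(params, rng_seed=4)
        assert np.all(inst.dup_matches == inst.target_matches[None, :])

    def test_materialized_nucleotides_agree_with_patterns(self):
        params = SeedingParams(k=30, gamma=5, p=0.3, N=2, mu=0.3)
        inst = simulate_instance(params, rng_seed=9)
        read = np.frombuffer(inst.read.encode(), dtype="S1")
        target = np.frombuffer(inst.target.encode(), dtype="S1")
        assert np.array_equal(inst.target_matches, read == target)
        for j, dseq in enumerate(inst.duplicates):
            d = np.frombuffer(dseq.encode(), dtype="S1")
            assert np.array_equal(inst.dup_matches[j], read == d)


class TestDetectors:
    def test_all_match_read_is_seeded(self):
        inst = SimulatedInstance(np.ones(10, bool), np.zeros((0, 10), bool))
        assert detect_fixed_seed(inst, 0, gamma=7)
        assert detect_mem_on_target(inst, gamma=7)

    def test_detector_consistency_across_families(self, rng):
        """Exact seeds = skip-0 seeds = all-1 spaced model."""
        params = SeedingParams(k=25, gamma=6, p=0.25, N=1, mu=0.3)
        model = SpacedSeedModel("1" * 6)
        for seed in range(30):
            inst = simulate_instance(params, rng_seed=seed, materialize=False)
            for si in (0, 1):
                a = detect_fixed_seed(inst, si, gamma=6, n=0)
                assert a == detect_fixed_seed(inst, si, gamma=6)
                assert a == detect_spaced_seed(inst, si, model)

    def test_skipping_can_lose_the_only_seed(self):
        # a run of exactly gamma matches starting at an even (1-based: 2nd)
        # position seeds at n=0 but not with skip-1 starts
        matches = np.array([False, True, True, True, False, False])
        inst = SimulatedInstance(matches, np.zeros((0, 6), bool))
        assert detect_fixed_seed(inst, 0, gamma=3, n=0)
        assert not detect_fixed_seed(inst, 0, gamma=3, n=1)

    def test_single_error_can_hide_target_for_every_gamma(self):
        """Two duplicates whose matches join across the single error
        hard-mask every nucleotide: no on-target MEM seed at any gamma."""
        k, e = 9, 4
        tmatch = np.ones(k, bool)
        tmatch[e] = False
        dup = np.zeros((2, k), bool)
        dup[0, : e + 1] = True    # matches left half plus the error
        dup[1, e:] = True         # matches the error plus right half
        inst = SimulatedInstance(tmatch, dup)
        for gamma in range(1, 5):
            assert not detect_mem_on_target(inst, gamma)

    def test_mem_reduces_to_run_detection_without_duplicates(self):
        m = np.array([True, True, False, True, True, True])
        inst = SimulatedInstance(m, np.zeros((0, 6), bool))
        assert detect_mem_on_target(inst, 3)
        assert not detect_mem_on_target(inst, 4)


class TestBestLocation:
    def test_error_free_read_maps_to_target(self):
        params = SeedingParams(k=20, gamma=5, p=1e-9, N=2, mu=0.3)
        inst = simulate_instance(params, rng_seed=1)
        assert best_location(inst) == 0

    def test_ties_break_toward_target(self):
        inst = SimulatedInstance(np.ones(8, bool), np.ones((2, 8), bool))
        assert best_location(inst) == 0

    def test_perfect_duplicate_match_implies_hard_masked_target(self, rng):
        """If some duplicate matches the read perfectly while the target
        does not, the target is hard-masked everywhere: the read cannot be
        seeded on-target, so it is mapped to the better-scoring duplicate."""
        params = SeedingParams(k=8, gamma=3, p=0.2, N=3, mu=0.15)
        checked = 0
        for seed in range(400):
            inst = simulate_instance(params, rng_seed=seed, materialize=False)
            perfect_dup = bool(inst.dup_matches.all(axis=1).any())
            if perfect_dup and not inst.target_matches.all():
                checked += 1
                assert not detect_mem_on_target(inst, params.gamma)
                assert best_location(inst) != 0
        assert checked > 0


class TestEstimators:
    def test_estimate_matches_recurrence(self):
        params = SeedingParams(k=20, gamma=5, p=0.1)
        est = estimate_event_probability("no_target_seed", params, 300_000, 3)
        expect = prob_no_on_target_exact(params)[20]
        assert abs(est.p_hat - expect) < 4 * est.stderr

    def test_estimate_reproducible(self):
        params = SeedingParams(k=15, gamma=4, p=0.2, N=1, mu=0.2)
        e1 = estimate_event_probability("off_target", params, 50_000, 8)
        e2 = estimate_event_probability("off_target", params, 50_000, 8)
        assert e1.p_hat == e2.p_hat

    def test_callable_event_agrees_with_named(self):
        params = SeedingParams(k=12, gamma=4, p=0.2, N=1, mu=0.3)
        named = estimate_event_probability("no_mem_on_target", params, 30_000, 5)
        custom = estimate_event_probability(
            lambda inst: not detect_mem_on_target(inst, 4), params, 3_000, 5)
        assert abs(named.p_hat - custom.p_hat) < 4 * (named.stderr + custom.stderr)

    def test_invalid_sample_count(self):
        with pytest.raises(ValueError):
            estimate_event_probability(
                "null", SeedingParams(k=5, gamma=2, p=0.1), 0, 1)


class TestExhaustive:
    def test_exact_pipeline_quantities(self):
        params = SeedingParams(k=10, gamma=3, p=0.2, N=1, mu=0.25)
        assert exhaustive_event_probability("no_target_seed", params) == \
            pytest.approx(prob_no_on_target_exact(params)[10], abs=1e-12)
        assert exhaustive_event_probability("no_seed_pair", params) == \
            pytest.approx(prob_no_seed_either_exact(params, epsilon=1e-12),
                          abs=1e-12)

    def test_off_target_exact_at_single_duplicate(self):
        params = SeedingParams(k=9, gamma=3, p=0.2, N=1, mu=0.3)
        exh = exhaustive_event_probability("off_target", params)
        pipe = off_target_exact(params, epsilon=1e-12)
        assert pipe.p_off == pytest.approx(exh, abs=1e-12)

    def test_too_large_instances_rejected(self):
        with pytest.raises(ValueError):
            exhaustive_event_probability(
                "null", SeedingParams(k=30, gamma=5, p=0.1, N=2, mu=0.1))


class TestFastaExport:
    def test_roundtrip_through_biopython(self, tmp_path):
        from Bio import SeqIO
        params = SeedingParams(k=25, gamma=5, p=0.1, N=2, mu=0.1)
        inst = simulate_instance(params, rng_seed=6)
        path = tmp_path / "instance.fa"
        write_instance_fasta(inst, str(path))
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        assert records["target"] == inst.target
        assert records["read"] == inst.read
        assert records["duplicate_1"] == inst.duplicates[0]
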