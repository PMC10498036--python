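"""Maze scoring, Monte Carlo nulls and the observed-vs-null comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabehave import (
    AgentSpec,
    NullDistribution,
    RAMTrial,
    TransitionMatrix,
    compare_to_null,
    count_errors,
    estimate_transition_matrix,
    expected_random_errors,
    generate_ram_trial,
    random_errors_variance,
    simulate_random_null,
    simulate_stereotypic_null,
)
from metabehave.ram import RAMError


def trial(visits, n_arms=8):
    return RAMTrial(chick_id="c", trial_number=1, visits=np.array(visits),
                    n_arms=n_arms)


class TestCountErrors:
    def test_perfect_trial(self):
        assert count_errors(trial(range(8))) == 0
        assert trial(range(8)).completed

    def test_single_revisit(self):
        assert count_errors(trial([0, 1, 1, 2, 3, 4, 5, 6, 7])) == 1

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        visits=st.lists(st.integers(0, 7), min_size=1, max_size=40),
        perm_seed=st.integers(0, 2**31 - 1),
    )
    def test_relabelling_invariance(self, visits, perm_seed):
        """Error counts do not depend on how arms are numbered."""
        perm = np.random.default_rng(perm_seed).permutation(8)
        assert count_errors(trial(visits)) == count_errors(
            trial(perm[np.array(visits)])
        )


class TestRandomNull:
    def test_matches_coupon_collector_moments(self):
        """Mean within 3 Monte Carlo SEs of 8*H_8 - 8 = 13.7429 at both
        10^4 and 10^5 iterations."""
        expected = expected_random_errors(8)
        assert expected == pytest.approx(13.742857142857142)
        for iters, seed in ((10_000, 11), (100_000, 12)):
            null = simulate_random_null(8, iters, seed=seed)
            sem = np.sqrt(random_errors_variance(8) / iters)
            assert abs(null.mean - expected) < 3 * sem
            assert null.sem == pytest.approx(sem, rel=0.05)

    def test_single_arm_never_errs(self):
        null = simulate_random_null(1, 100, seed=0)
        assert null.mean == 0.0

    def test_visit_cap_truncates(self):
        capped = simulate_random_null(8, 2000, seed=3, visit_cap=10)
        free = simulate_random_null(8, 2000, seed=3)
        assert (~capped.completed).any()
        assert np.all(capped.errors >= 0)
        assert capped.errors.max() <= 10 - 1  # at least one arm is distinct
        assert capped.mean < free.mean  # truncation can only lose revisits

    def test_deterministic_given_seed(self):
        a = simulate_random_null(8, 500, seed=42)
        b = simulate_random_null(8, 500, seed=42)
        assert np.array_equal(a.errors, b.errors)


class TestAgents:
    def test_perfect_memory_is_a_permutation(self):
        t = generate_ram_trial(
            AgentSpec(kind="memory", memory_fidelity=1.0), seed=0
        )
        assert sorted(t.visits) == list(range(8))
        assert count_errors(t) == 0

    def test_random_agent_mean_near_coupon_collector(self):
        rng = np.random.default_rng(5)
        agent = AgentSpec(kind="random")
        errs = [
            count_errors(generate_ram_trial(agent, seed=rng)) for _ in range(3000)
        ]
        sem = np.sqrt(random_errors_variance(8) / len(errs))
        assert abs(np.mean(errs) - expected_random_errors(8)) < 4 * sem

    def test_clockwise_stereotype_is_errorless(self):
        tm = np.roll(np.eye(8), 1, axis=1)
        t = generate_ram_trial(AgentSpec(kind="stereotypic", transition_matrix=tm),
                               seed=9)
        assert count_errors(t) == 0
        assert t.completed

    def test_memory_monotonicity(self):
        """Higher memory fidelity gives fewer errors on average."""
        rng = np.random.default_rng(6)
        means = []
        for rho in (0.2, 0.8):
            agent = AgentSpec(kind="memory", memory_fidelity=rho)
            means.append(
                np.mean(
                    [count_errors(generate_ram_trial(agent, seed=rng))
                     for _ in range(800)]
                )
            )
        assert means[1] < means[0]


class TestTransitionMatrix:
    def test_clockwise_point_masses(self):
        t = trial(range(8))
        tm = estimate_transition_matrix([t], mode="absolute")
        for i in range(7):
            assert tm.probs[i, i + 1] == 1.0
        # unvisited row (arm 7 has no outgoing transition) backs off to uniform
        assert np.allclose(tm.probs[7], 1.0 / 8)

    def test_relative_offset_clockwise(self):
        tm = estimate_transition_matrix([trial(range(8))], mode="relative_offset")
        assert tm.probs[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(np.roll(tm.probs, -1, axis=1)), 1.0)

    def test_estimation_consistency(self):
        """Estimated probabilities converge to the generating matrix."""
        rng = np.random.default_rng(21)
        true = np.full((8, 8), 0.5 / 7)
        np.fill_diagonal(true, 0.0)
        true += np.roll(np.eye(8), 1, axis=1) * (0.5 - 0.5 / 7)
        true /= true.sum(axis=1, keepdims=True)
        agent = AgentSpec(kind="stereotypic", transition_matrix=true, visit_cap=80)
        trials = [
            generate_ram_trial(agent, seed=rng, trial_number=i)
            for i in range(6500)
        ]
        est = estimate_transition_matrix(trials, mode="absolute")
        n_transitions = sum(len(t.visits) - 1 for t in trials)
        assert n_transitions > 1e5
        assert np.max(np.abs(est.probs - true)) < 0.02

    def test_no_transitions_raises(self):
        with pytest.raises(RAMError, match="transition"):
            estimate_transition_matrix([trial([3])])


class TestStereotypicNull:
    def test_deterministic_clockwise_zero_errors(self):
        tm = TransitionMatrix(np.eye(8), np.roll(np.eye(8), 1, axis=1))
        null = simulate_stereotypic_null(tm, iterations=300, seed=1)
        assert null.mean == 0.0

    def test_uniform_matrix_matches_random_null(self):
        """A memoryless uniform chain is the random model; the two
        simulators agree distributionally (two-sample KS)."""
        from scipy.stats import ks_2samp

        tm = TransitionMatrix(np.ones((8, 8)), np.full((8, 8), 1 / 8))
        a = simulate_stereotypic_null(tm, iterations=3000, seed=2)
        b = simulate_random_null(8, 3000, seed=3)
        assert ks_2samp(a.errors, b.errors).pvalue > 0.01

    def test_self_loop_hits_cap(self):
        probs = np.eye(8)
        tm = TransitionMatrix(np.eye(8), probs)
        null = simulate_stereotypic_null(tm, iterations=50, seed=4, visit_cap=100)
        assert not null.completed.any()
        assert np.all(null.errors == 100 - 1)

    def test_absorbing_chain_without_cap_raises(self):
        tm = TransitionMatrix(np.eye(8), np.eye(8))
        with pytest.raises(RAMError, match="cover"):
            simulate_stereotypic_null(tm, iterations=5, seed=5, max_steps=200)


class TestCompareToNull:
    @pytest.fixture
    def null(self):
        return NullDistribution("random", 1000,
                                np.random.default_rng(0).poisson(13.61, 1000))

    def test_zero_variance_at_null_mean(self):
        null = NullDistribution("random", 4, np.array([10, 10, 10, 10]))
        res = compare_to_null([10.0, 10.0, 10.0], null)
        assert res.t == 0.0 and res.p == 0.5

    def test_zero_variance_below_null_mean(self, null):
        res = compare_to_null([2.0, 2.0], null)
        assert res.p == 0.0

    def test_study_scale_consistency(self, null):
        """132 observed trials with mean 11.64 and SEM 0.65 against a null
        mean of 13.61 give t close to -3 and a sub-0.01 one-sided p."""
        rng = np.random.default_rng(8)
        raw = rng.normal(size=132)
        z = (raw - raw.mean()) / raw.std(ddof=1)
        observed = 11.64 + (0.65 * np.sqrt(132)) * z
        shifted = NullDistribution("random", null.iterations,
                                   null.errors - null.errors.mean() + 13.61)
        res = compare_to_null(observed, shifted)
        assert res.df == 131
        assert -3.3 < res.t < -2.8
        assert res.p < 0.01

    def test_requires_two_observations(self, null):
        with pytest.raises(RAMError):
            compare_to_null([5.0], null)
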