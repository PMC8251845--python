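"""Greedy matching algorithms: exact small-instance distributions, invariants,
and equivalence of the fast order-statistics implementation with the naive
reference."""

from collections import defaultdict
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from greedymatch import (
    MatchConfig,
    RepeatedMatching,
    Scenario,
    greedy_caliper_match,
    nn_caliper_match,
    simulate_cohort,
)
from greedymatch.matching import (
    greedy_caliper_match_reference,
    nn_caliper_match_reference,
)
from greedymatch.propensity import fit_propensity

from conftest import make_toy


def exact_matchset_distribution(algorithm, tps, cps, width):
    """Brute-force enumeration of the matched-set distribution.

    Averages over all treated permutations and, within each, over the uniform
    random choices (eligible controls for caliper-random; minimal-distance
    ties for NN).  Returns {frozenset of (treated_id, control_id): prob} with
    ids in the make_toy convention (treated first).
    """
    nt = len(tps)
    dist: dict[frozenset, float] = defaultdict(float)
    n_perm = 1
    for i in range(2, nt + 1):
        n_perm *= i

    def recurse(order, avail, acc, prob):
        if not order:
            dist[frozenset(acc)] += prob
            return
        ti, rest = order[0], order[1:]
        s = tps[ti]
        if algorithm == "caliper_random":
            chosen = [c for c in avail if s - width <= cps[c] <= s + width]
        else:
            if avail:
                d = min(abs(cps[c] - s) for c in avail)
                chosen = [c for c in avail if abs(cps[c] - s) == d] if d <= width else []
            else:
                chosen = []
        if not chosen:
            recurse(rest, avail, acc, prob)
            return
        for c in chosen:
            recurse(rest, avail - {c}, acc + [(ti, nt + c)], prob / len(chosen))

    for perm in permutations(range(nt)):
        recurse(list(perm), set(range(len(cps))), [], 1.0 / n_perm)
    return dict(dist)


def empirical_matchset_distribution(matcher, cohort, fit, width, n_seeds):
    counts: dict[frozenset, int] = defaultdict(int)
    for seed in range(n_seeds):
        config = MatchConfig(caliper_width=width, seed=seed)
        ms = matcher(fit, cohort, config)
        counts[frozenset(map(tuple, ms.pairs))] += 1
    return counts


class TestTrivialExamples:
    def test_no_control_in_caliper(self, toy):
        cohort, fit = toy([0.50], [0.90])
        ms = greedy_caliper_match(fit, cohort, MatchConfig(caliper_width=0.10, seed=0))
        assert ms.n_pairs == 0 and ms.n_treated_unmatched == 1

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_forced_match(self, toy, seed):
        cohort, fit = toy([0.50], [0.50])
        ms = greedy_caliper_match(fit, cohort, MatchConfig(caliper_width=0.10, seed=seed))
        assert ms.pairs.tolist() == [[0, 1]]

    def test_nn_unique_nearest(self, toy):
        cohort, fit = toy([0.50], [0.48, 0.60])
        for seed in range(20):
            ms = nn_caliper_match(fit, cohort, MatchConfig(caliper_width=0.10, seed=seed))
            assert ms.pairs.tolist() == [[0, 1]]  # the 0.48 control

    def test_nn_symmetric_tie_is_fair(self, toy):
        # scores exactly representable in binary, so the two distances tie
        # exactly; the tie must be broken uniformly
        cohort, fit = toy([0.50], [0.25, 0.75])
        picks = np.array([
            nn_caliper_match(fit, cohort, MatchConfig(caliper_width=0.30, seed=s))
            .pairs[0, 1]
            for s in range(10_000)
        ])
        assert abs(np.mean(picks == 1) - 0.5) < 0.02


class TestExactDistributions:
    def test_caliper_random_matches_enumeration(self, toy):
        tps, cps, width = [0.30, 0.50, 0.70], [0.32, 0.49, 0.52], 0.05
        cohort, fit = toy(tps, cps)
        exact = exact_matchset_distribution("caliper_random", tps, cps, width)
        n = 20_000
        counts = empirical_matchset_distribution(
            greedy_caliper_match, cohort, fit, width, n)
        assert set(counts) <= set(exact)
        for outcome, p in exact.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(outcome, 0) / n - p) <= 3 * se + 1e-12

    @pytest.mark.parametrize("algorithm, matcher", [
        ("caliper_random", greedy_caliper_match),
        ("nn_caliper", nn_caliper_match),
    ])
    def test_goodness_of_fit_on_small_instances(self, toy, algorithm, matcher):
        """Empirical matched-set frequencies on <=4x4 instances are consistent
        with exact enumeration (chi-square, p > 0.001)."""
        rng = np.random.default_rng(2024)
        for _ in range(3):
            nt, nc = rng.integers(2, 5), rng.integers(2, 5)
            tps = np.round(rng.uniform(0.2, 0.8, nt), 2).tolist()
            cps = np.round(rng.uniform(0.2, 0.8, nc), 2).tolist()
            width = 0.15
            exact = exact_matchset_distribution(algorithm, tps, cps, width)
            cohort, fit = make_toy(tps, cps)
            n = 8000
            counts = empirical_matchset_distribution(matcher, cohort, fit, width, n)
            outcomes = sorted(exact, key=sorted)
            observed = [counts.get(o, 0) for o in outcomes]
            expected = [exact[o] * n for o in outcomes]
            if len(outcomes) > 1:
                assert chisquare(observed, expected).pvalue > 0.001
            else:
                assert observed[0] == n

    def test_nn_order_dependence_two_outcomes(self, toy):
        tps, cps, width = [0.50, 0.52], [0.51, 0.60], 0.05
        cohort, fit = toy(tps, cps)
        counts = empirical_matchset_distribution(
            nn_caliper_match, cohort, fit, width, 10_000)
        first = frozenset({(0, 2)})   # treated 0.50 takes the 0.51 control
        second = frozenset({(1, 2)})  # treated 0.52 takes it instead
        assert set(counts) == {first, second}
        assert abs(counts[first] / 10_000 - 0.5) < 0.02


@pytest.fixture(scope="module")
def medium_cohort_fit():
    sc = Scenario(n=1500, p_treat=0.4, p_outcome=0.5, true_or=1.0, seed=17)
    cohort = simulate_cohort(sc)
    return cohort, fit_propensity(cohort)


class TestFastEqualsReference:
    @pytest.mark.parametrize("fast, ref", [
        (greedy_caliper_match, greedy_caliper_match_reference),
        (nn_caliper_match, nn_caliper_match_reference),
    ])
    def test_bit_identical_on_random_instances(self, fast, ref):
        rng = np.random.default_rng(7)
        for trial in range(25):
            nt, nc = rng.integers(1, 50), rng.integers(1, 70)
            # coarse grid of scores forces plenty of exact ties
            tps = rng.choice(np.linspace(0.1, 0.9, 12), nt)
            cps = rng.choice(np.linspace(0.1, 0.9, 12), nc)
            cohort, fit = make_toy(tps, cps)
            width = float(rng.uniform(0.02, 0.4))
            config = MatchConfig(caliper_width=width, seed=int(rng.integers(10_000)))
            a, b = fast(fit, cohort, config), ref(fit, cohort, config)
            np.testing.assert_array_equal(a.pairs, b.pairs)
            assert a.n_treated_unmatched == b.n_treated_unmatched

    @pytest.mark.parametrize("fast, ref", [
        (greedy_caliper_match, greedy_caliper_match_reference),
        (nn_caliper_match, nn_caliper_match_reference),
    ])
    def test_bit_identical_on_simulated_cohort(self, medium_cohort_fit, fast, ref):
        cohort, fit = medium_cohort_fit
        for seed in (0, 1, 2):
            config = MatchConfig(caliper_multiplier=0.2, seed=seed)
            a, b = fast(fit, cohort, config), ref(fit, cohort, config)
            np.testing.assert_array_equal(a.pairs, b.pairs)


class TestInvariants:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        tps=st.lists(st.floats(0.05, 0.95), min_size=1, max_size=8),
        cps=st.lists(st.floats(0.05, 0.95), min_size=1, max_size=8),
        width=st.floats(0.01, 0.3),
        seed=st.integers(0, 2**16),
        algorithm=st.sampled_from(["caliper_random", "nn_caliper"]),
    )
    def test_structural_invariants(self, tps, cps, width, seed, algorithm):
        from greedymatch.matching import MATCHERS
        cohort, fit = make_toy(tps, cps)
        config = MatchConfig(algorithm=algorithm, caliper_width=width, seed=seed)
        ms = MATCHERS[algorithm](fit, cohort, config)
        # without replacement: all ids distinct
        assert len(set(ms.pairs[:, 0])) == ms.n_pairs
        assert len(set(ms.pairs[:, 1])) == ms.n_pairs
        # caliper containment
        if ms.n_pairs:
            gaps = np.abs(fit.ps[ms.pairs[:, 0]] - fit.ps[ms.pairs[:, 1]])
            assert np.all(gaps <= width + 1e-12)
        # accounting identity
        assert ms.n_pairs + ms.n_treated_unmatched == len(tps)
        # determinism
        ms2 = MATCHERS[algorithm](fit, cohort, config)
        np.testing.assert_array_equal(ms.pairs, ms2.pairs)

    def test_infinite_caliper_nn_matches_everyone(self, toy):
        rng = np.random.default_rng(3)
        cohort, fit = make_toy(rng.uniform(0.1, 0.9, 20), rng.uniform(0.1, 0.9, 30))
        ms = nn_caliper_match(fit, cohort, MatchConfig(caliper_width=10.0, seed=5))
        assert ms.n_pairs == 20 and ms.n_treated_unmatched == 0

    def test_caliper_random_at_least_as_variable_as_nn(self):
        """Across random orderings of one cohort, the OR spread under
        caliper-random matching is at least that of NN caliper matching."""
        sc = Scenario(n=2000, p_treat=0.5, p_outcome=0.5, true_or=1.0, seed=31)
        cohort = simulate_cohort(sc)
        fit = fit_propensity(cohort)
        variances = {}
        for algorithm in ("caliper_random", "nn_caliper"):
            model = RepeatedMatching(cohort, algorithm, 0.2, propensity_fit=fit)
            res = model.fit(reps=200, base_seed=31)
            ors = res.per_repetition.query("defined")["or_hat"]
            variances[algorithm] = float(np.var(np.log(ors)))
        assert variances["caliper_random"] >= variances["nn_caliper"]
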