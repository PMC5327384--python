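"""Log-rank statistic, variance, chi-square tail and the rank decomposition."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import corank as cr
from conftest import random_cohort, random_group


class TestLogrankStatistic:
    def test_hand_example(self, two_subject_cohort):
        # t=1: O1=1, E1=1/2; t=2: O1=0, E1=0
        g = cr.GroupAssignment(np.array([1, 0]))
        assert cr.logrank_statistic(two_subject_cohort, g) == pytest.approx(0.5)

    def test_antisymmetry_under_complement(self, small_cohort):
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = random_group(rng, small_cohort.n, int(rng.integers(1, small_cohort.n)))
            L = cr.logrank_statistic(small_cohort, g)
            Lc = cr.logrank_statistic(small_cohort, g.complement())
            assert L + Lc == pytest.approx(0.0, abs=1e-9)

    def test_all_group_members_censored_after_events_gives_negative_L(self):
        # carriers censored after the last event: O_1j = 0 at every event time
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 1, 1, 0, 0])
        co = cr.SurvivalCohort(t, e)
        g = cr.GroupAssignment(np.array([0, 0, 0, 1, 1]))
        L = cr.logrank_statistic(co, g)
        # -sum over events of R_1j O_j / R_j = -(2/5 + 2/4 + 2/3)
        assert L == pytest.approx(-(2 / 5 + 2 / 4 + 2 / 3))
        assert L < 0

    def test_degenerate_group_rejected(self, small_cohort):
        with pytest.raises(cr.DegenerateGroupError):
            cr.logrank_statistic(small_cohort, cr.GroupAssignment(np.zeros(12, dtype=int)))
        with pytest.raises(cr.DegenerateGroupError):
            cr.logrank_statistic(small_cohort, cr.GroupAssignment(np.ones(12, dtype=int)))

    def test_no_events_rejected(self):
        co = cr.SurvivalCohort(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
        with pytest.raises(cr.NoEventsError):
            cr.logrank_statistic(co, cr.GroupAssignment(np.array([1, 0, 0])))

    def test_matches_lifelines_on_untied_cohort(self):
        """Independent oracle: lifelines' statsmodels-grade log-rank chi2."""
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(5)
        co = random_cohort(rng, 40)
        g = random_group(rng, 40, 15)
        L = cr.logrank_statistic(co, g)
        V = cr.logrank_variance(co, g)
        res = logrank_test(
            co.times[g.x == 1], co.times[g.x == 0],
            event_observed_A=co.events[g.x == 1],
            event_observed_B=co.events[g.x == 0],
        )
        assert L * L / V == pytest.approx(res.test_statistic, rel=1e-9)
        assert cr.alrt_pvalue(L, V) == pytest.approx(res.p_value, rel=1e-9)


class TestLogrankVariance:
    def test_hand_example(self, two_subject_cohort):
        g = cr.GroupAssignment(np.array([1, 0]))
        assert cr.logrank_variance(two_subject_cohort, g) == pytest.approx(0.25)

    def test_symmetric_under_complement(self, small_cohort):
        rng = np.random.default_rng(1)
        g = random_group(rng, 12, 5)
        assert cr.logrank_variance(small_cohort, g) == pytest.approx(
            cr.logrank_variance(small_cohort, g.complement())
        )

    def test_single_event_pair(self):
        co = cr.SurvivalCohort(np.array([1.0, 2.0]), np.array([1, 0]))
        g = cr.GroupAssignment(np.array([1, 0]))
        assert cr.logrank_variance(co, g) == pytest.approx(0.25)

    def test_nonnegative(self, small_cohort):
        rng = np.random.default_rng(2)
        for _ in range(20):
            g = random_group(rng, 12, int(rng.integers(1, 12)))
            assert cr.logrank_variance(small_cohort, g) >= 0


class TestAlrtPvalue:
    def test_zero_statistic_gives_p_one(self):
        assert cr.alrt_pvalue(0.0, 0.5) == pytest.approx(1.0)

    def test_chi2_five_percent_point(self):
        assert cr.alrt_pvalue(math.sqrt(3.841459), 1.0) == pytest.approx(0.05, abs=1e-6)

    def test_hand_example(self):
        assert cr.alrt_pvalue(0.5, 0.25) == pytest.approx(0.3173, abs=1e-4)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            cr.alrt_pvalue(1.0, 0.0)


class TestCooccurrence:
    def test_direct_count(self):
        co = cr.SurvivalCohort(np.arange(1.0, 5.0), np.array([1, 1, 0, 0]))
        assert cr.cooccurrence(co, cr.GroupAssignment(np.array([1, 0, 1, 0]))) == 1

    def test_extremes(self, small_cohort):
        x_cens = (small_cohort.events == 0).astype(int)
        assert cr.cooccurrence(small_cohort, cr.GroupAssignment(x_cens)) == 0
        x_all_events = (small_cohort.events == 1).astype(int)
        assert (cr.cooccurrence(small_cohort, cr.GroupAssignment(x_all_events))
                == small_cohort.d)


class TestRankDecomposition:
    def test_reconstruction_identity_randomized(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            co = random_cohort(rng, n)
            g = random_group(rng, n, int(rng.integers(1, n)))
            dec = cr.rank_decomposition(co, g)
            L = cr.logrank_statistic(co, g)
            assert abs(dec.L - L) < 1e-10
            assert dec.k - dec.s1 - 1e-9 <= L <= dec.k + 1e-9

    def test_s1_depends_only_on_cohort_and_n1(self, small_cohort):
        rng = np.random.default_rng(4)
        s1s = {cr.rank_decomposition(small_cohort, random_group(rng, 12, 5)).s1
               for _ in range(10)}
        assert len({round(s, 12) for s in s1s}) == 1

    def test_k0_assignment_is_negative(self):
        t = np.arange(1.0, 7.0)
        e = np.array([1, 1, 0, 0, 0, 0])
        co = cr.SurvivalCohort(t, e)
        g = cr.GroupAssignment(np.array([0, 0, 1, 1, 0, 0]))
        dec = cr.rank_decomposition(co, g)
        assert dec.k == 0
        assert dec.L == pytest.approx(-(dec.s1 - dec.middle))
        assert dec.L < 0

    def test_top_stratum_below_k(self):
        # all carriers are the earliest events: L near its maximum, still <= k
        t = np.arange(1.0, 9.0)
        e = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        co = cr.SurvivalCohort(t, e)
        g = cr.GroupAssignment(np.array([1, 1, 1, 0, 0, 0, 0, 0]))
        dec = cr.rank_decomposition(co, g)
        assert dec.k == 3
        assert dec.L < dec.k

    def test_mixed_ties_rejected(self, mixed_tie_cohort):
        g = cr.GroupAssignment(np.array([1, 0, 1, 0, 0]))
        with pytest.raises(ValueError, match="mixed tie"):
            cr.rank_decomposition(mixed_tie_cohort, g)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_permutation_mean_zero(self, seed):
        """Mean of L over all C(n, n1) assignments is exactly zero."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        co = random_cohort(rng, n)
        n1 = int(rng.integers(1, n))
        total = 0.0
        count = 0
        for idx in itertools.combinations(range(n), n1):
            x = np.zeros(n, dtype=np.int8)
            x[list(idx)] = 1
            total += cr.logrank_statistic(co, cr.GroupAssignment(x))
            count += 1
        assert total / count == pytest.approx(0.0, abs=1e-9)


class TestTieAveraging:
    def test_no_mixed_ties_is_plain_statistic(self, small_cohort):
        g = cr.GroupAssignment(np.array([1, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0]))
        for seed in (0, 1, 99):
            assert cr.tie_averaged_logrank(small_cohort, g, 5, seed) == pytest.approx(
                cr.logrank_statistic(small_cohort, g)
            )

    def test_two_ordering_average(self, mixed_tie_cohort):
        """Brute force: average of the two within-block orderings.

        Block (event, censored) at t=2 with 4 at risk, carriers = subjects
        at t=1 and the censored one at t=2.  Event-first: the censored
        subject is still at risk for the tied event; censored-first: it is
        not.  The tie-averaged statistic converges to the mean of the two.
        """
        g = cr.GroupAssignment(np.array([1, 0, 1, 0, 0]))

        def ordering(event_first):
            # expand the block into distinct pseudo-times
            if event_first:
                t = np.array([1.0, 2.0, 2.5, 3.0, 4.0])
                e = np.array([1, 1, 0, 0, 1])
                x = np.array([1, 0, 1, 0, 0])
            else:
                t = np.array([1.0, 2.0, 2.5, 3.0, 4.0])
                e = np.array([1, 0, 1, 0, 1])
                x = np.array([1, 1, 0, 0, 0])
            return cr.logrank_statistic(cr.SurvivalCohort(t, e), cr.GroupAssignment(x))

        expected = 0.5 * (ordering(True) + ordering(False))
        got = cr.tie_averaged_logrank(mixed_tie_cohort, g, n_tie_perms=2000, rng_seed=8)
        assert got == pytest.approx(expected, abs=5e-3)

    def test_seed_determinism(self, mixed_tie_cohort):
        g = cr.GroupAssignment(np.array([1, 0, 1, 0, 0]))
        a = cr.tie_averaged_logrank(mixed_tie_cohort, g, 20, rng_seed=5)
        b = cr.tie_averaged_logrank(mixed_tie_cohort, g, 20, rng_seed=5)
        assert a == b

    def test_scores_sum_to_zero_with_ties(self, mixed_tie_cohort):
        scores = cr.logrank_scores(mixed_tie_cohort, 50, rng_seed=3)
        assert scores.sum() == pytest.approx(0.0, abs=1e-12)


class TestCohortStructure:
    def test_tie_block_detection(self, mixed_tie_cohort):
        assert mixed_tie_cohort.tie_blocks == [(1, 3)]
        assert mixed_tie_cohort.mixed_tie_blocks == [(1, 3)]

    def test_pure_tie_block_not_mixed(self):
        co = cr.SurvivalCohort(np.array([1.0, 1.0, 2.0]), np.array([1, 1, 0]))
        assert co.tie_blocks == [(0, 2)]
        assert co.mixed_tie_blocks == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            cr.SurvivalCohort(np.array([2.0, 1.0]), np.array([1, 1]))

    def test_from_unsorted_sorts_and_keeps_ids(self):
        co = cr.SurvivalCohort.from_unsorted([3.0, 1.0, 2.0], [1, 0, 1], ["c", "a", "b"])
        assert list(co.times) == [1.0, 2.0, 3.0]
        assert co.sample_ids == ("a", "b", "c")
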