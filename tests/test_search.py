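"""Harmony-search machinery: linearization, BW, tabu registry, full runs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiharmony import (
    HarmonyMemory,
    ScoredModel,
    SearchConfig,
    SearchExhausted,
    TabuRegistry,
    draw_bw,
    exhaustive_search,
    fhsa_run,
    improvise,
    interaction_model,
    linear_to_pair,
    local_search_unvisited,
    pair_to_linear,
    simulate_dataset,
)
from epiharmony.search import linear_to_pair0, pair_index0


class TestLinearization:
    def test_first_element(self):
        assert pair_to_linear(1, 2, 10) == 1

    def test_last_pair_equals_exhaustive_count(self):
        # the full scan over 100 markers comprises 100*99/2 = 4950 models
        assert pair_to_linear(99, 100, 100) == 4950

    def test_bijection_at_n12(self):
        image = sorted(
            pair_to_linear(i, j, 12)
            for i in range(1, 12)
            for j in range(i + 1, 13)
        )
        assert image == list(range(1, 67))

    def test_inverse_first_and_last(self):
        assert linear_to_pair(1, 10) == (1, 2)
        for n in (2, 5, 37):
            m = n * (n - 1) // 2
            assert linear_to_pair(m, n) == (n - 1, n)

    def test_round_trip_exhaustive_n12(self):
        for k in range(1, 67):
            i, j = linear_to_pair(k, 12)
            assert pair_to_linear(i, j, 12) == k

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(2, 200), st.data())
    def test_round_trip_property(self, n, data):
        m = n * (n - 1) // 2
        k = data.draw(st.integers(1, m))
        i, j = linear_to_pair(k, n)
        assert 1 <= i < j <= n
        assert pair_to_linear(i, j, n) == k

    @pytest.mark.parametrize("bad", [(2, 2, 10), (3, 2, 10), (0, 1, 10), (9, 11, 10)])
    def test_invalid_pairs_rejected(self, bad):
        with pytest.raises(ValueError):
            pair_to_linear(*bad)


class TestDrawBW:
    def test_forced_lower_bound(self, rng):
        assert all(draw_bw(1, rng) == 1 for _ in range(50))

    def test_upper_clamp_for_large_remaining(self, rng):
        draws = draw_bw(10**6, rng, size=20_000)
        assert draws.max() == 10
        # a draw below 10 requires u < 1e-5: essentially never in 20k draws
        assert (draws == 10).mean() > 0.999

    def test_matches_literal_formula(self, rng):
        """Empirical distribution equals direct simulation of the update."""
        remaining = 5
        draws = draw_bw(remaining, rng, size=100_000)
        oracle_rng = np.random.default_rng(4)
        oracle = np.floor(
            np.minimum(10, np.maximum(oracle_rng.random(100_000) * remaining, 1))
        ).astype(int)
        got = np.bincount(draws, minlength=11)[1:] / len(draws)
        want = np.bincount(oracle, minlength=11)[1:] / len(oracle)
        assert np.abs(got - want).max() < 0.01

    def test_exhausted_registry_rejected(self, rng):
        with pytest.raises(SearchExhausted):
            draw_bw(0, rng)


class TestTabuRegistry:
    def test_invariant_counts(self):
        reg = TabuRegistry(8)
        assert reg.n_pairs == 28
        for k in (1, 5, 28):
            reg.mark_visited(k)
        assert reg.remaining + int(reg.visited.sum()) == 28

    def test_double_visit_rejected(self):
        reg = TabuRegistry(5)
        reg.mark_visited(3)
        with pytest.raises(ValueError):
            reg.mark_visited(3)

    def test_traversal_reaches_all_unvisited(self, rng):
        reg = TabuRegistry(9)  # 36 pairs
        visited = set(rng.choice(np.arange(1, 37), size=20, replace=False).tolist())
        for k in visited:
            reg.mark_visited(k)
        start = reg.seek_unvisited(1)
        seen = {start}
        node = int(reg.next[start])
        while node != start:
            seen.add(node)
            node = int(reg.next[node])
        assert seen == set(range(1, 37)) - visited

    def test_local_search_never_returns_visited(self, rng):
        for _ in range(30):
            reg = TabuRegistry(10)  # 45 pairs
            n_visit = int(rng.integers(1, 44))
            for k in rng.choice(np.arange(1, 46), size=n_visit, replace=False):
                reg.mark_visited(int(k))
            k0 = int(rng.integers(1, 46))
            found = local_search_unvisited(reg, k0, rng)
            assert not reg.is_visited(found)

    def test_single_remaining_always_returned(self, rng):
        reg = TabuRegistry(8)
        survivor = 17
        for k in range(1, 29):
            if k != survivor:
                reg.mark_visited(k)
        for k0 in (1, 10, 17, 28):
            assert local_search_unvisited(reg, k0, rng) == survivor

    def test_exhausted_signals(self, rng):
        reg = TabuRegistry(3)
        for k in (1, 2, 3):
            reg.mark_visited(k)
        with pytest.raises(SearchExhausted):
            local_search_unvisited(reg, 1, rng)


def _memory_with(pairs, criterion="k2"):
    mem = HarmonyMemory(len(pairs), criterion)
    for idx, pair in enumerate(pairs):
        mem.add(ScoredModel(pair, float(idx), float(idx)))
    return mem


class TestHarmonyMemory:
    def test_worst_replacement_strict(self):
        mem = _memory_with([(0, 1), (0, 2)])
        # ties with the worst do not enter
        assert not mem.consider(ScoredModel((1, 2), 1.0, 1.0))
        assert mem.consider(ScoredModel((1, 3), 0.5, 0.5))
        assert (0, 2) not in mem
        assert (1, 3) in mem

    def test_capacity_never_exceeded(self):
        mem = _memory_with([(0, 1), (0, 2)])
        for b in range(3, 30):
            mem.consider(ScoredModel((0, b), -float(b), 0.0))
            assert len(mem) == 2

    def test_best_and_worst_indices_track_criterion(self):
        mem = HarmonyMemory(3, "gini")
        mem.add(ScoredModel((0, 1), 9.0, 0.4))
        mem.add(ScoredModel((0, 2), 1.0, 0.1))
        mem.add(ScoredModel((1, 2), 5.0, 0.3))
        assert mem.best.pair == (0, 2)
        assert mem.worst.pair == (0, 1)


class TestImprovise:
    def test_degenerate_memory_always_returns_its_pair(self, rng):
        hm1 = _memory_with([(2, 6)])
        hm2 = _memory_with([(2, 6)], "gini")
        cfg = SearchConfig(hmcr=1.0, par=0.0, hms1=1, hms2=1)
        for _ in range(100):
            assert improvise(hm1, hm2, cfg, 10, rng) == (2, 6)

    def test_zero_hmcr_marginals_uniform(self, rng):
        """Pure random improvisation: each locus uniform over 1..N."""
        from scipy.stats import chisquare

        hm1 = _memory_with([(0, 1)])
        hm2 = _memory_with([(0, 1)], "gini")
        cfg = SearchConfig(hmcr=0.0, par=0.0, hms1=1, hms2=1)
        n = 20
        counts = np.zeros(n)
        n_draws = 50_000
        for _ in range(n_draws):
            a, b = improvise(hm1, hm2, cfg, n, rng)
            counts[a] += 1
            counts[b] += 1
        # each locus appears in a draw with probability 2/n
        stat = chisquare(counts)
        assert stat.pvalue > 0.001

    def test_zero_bandwidth_pitch_keeps_dimension(self, rng):
        # best == only harmony, so |best - random| = 0 and pitch is a no-op
        hm1 = _memory_with([(4, 8)])
        hm2 = _memory_with([(4, 8)], "gini")
        cfg = SearchConfig(hmcr=1.0, par=1.0, hms1=1, hms2=1)
        for _ in range(50):
            assert improvise(hm1, hm2, cfg, 12, rng) == (4, 8)

    def test_result_always_canonical(self, rng):
        hm1 = _memory_with([(0, 5), (3, 9)])
        hm2 = _memory_with([(1, 2), (7, 8)], "gini")
        cfg = SearchConfig(hmcr=0.7, par=0.5, hms1=2, hms2=2)
        for _ in range(500):
            a, b = improvise(hm1, hm2, cfg, 10, rng)
            assert 0 <= a < b < 10


@pytest.fixture(scope="module")
def medium_dataset():
    model = interaction_model(0.4)
    ds, truth = simulate_dataset(model, 200, 200, 25, seed=13)
    return ds, truth


class TestFhsaRun:
    def test_trace_unique_and_bounded(self, medium_dataset):
        ds, _ = medium_dataset
        cfg = SearchConfig(hms1=10, hms2=10, mmes=150, seed=2)
        result = fhsa_run(ds, cfg)
        assert len(result.trace) == result.mes <= 150
        assert len(set(result.trace)) == len(result.trace)

    def test_equals_exhaustive_at_full_budget(self, medium_dataset):
        """Budget = C(N,2) makes the search provably exhaustive."""
        ds, _ = medium_dataset
        m = 25 * 24 // 2
        oracle = exhaustive_search(ds)
        for seed in (0, 1, 2):
            cfg = SearchConfig(hms1=10, hms2=10, mmes=m, seed=seed)
            result = fhsa_run(ds, cfg)
            assert result.mes == m
            assert result.hm1.best.pair == oracle.best_k2_pair
            assert result.hm2.best.pair == oracle.best_gini_pair

    def test_worst_scores_monotone_nonincreasing(self, medium_dataset):
        """Worst-replacement can only improve each memory's worst score."""
        ds, _ = medium_dataset
        # same seed, increasing budgets: each run extends the previous one
        prev_w1 = prev_w2 = np.inf
        for budget in (20, 60, 120, 250):
            r = fhsa_run(ds, SearchConfig(hms1=8, hms2=8, mmes=budget, seed=5))
            w1 = r.hm1.score_of(r.hm1.worst)
            w2 = r.hm2.score_of(r.hm2.worst)
            assert w1 <= prev_w1 + 1e-12
            assert w2 <= prev_w2 + 1e-12
            prev_w1, prev_w2 = w1, w2

    def test_deterministic_given_seed(self, medium_dataset):
        ds, _ = medium_dataset
        cfg = SearchConfig(hms1=6, hms2=6, mmes=100, seed=42)
        r1, r2 = fhsa_run(ds, cfg), fhsa_run(ds, cfg)
        assert r1.trace == r2.trace
        assert [e.pair for e in r1.hm1.entries] == [e.pair for e in r2.hm1.entries]

    def test_mmes_clamped_with_warning(self, medium_dataset):
        ds, _ = medium_dataset
        cfg = SearchConfig(hms1=5, hms2=5, mmes=10**6, seed=0)
        with pytest.warns(UserWarning, match="clamp"):
            result = fhsa_run(ds, cfg)
        assert result.mes == 25 * 24 // 2
        assert result.stop_reason == "exhausted"

    def test_early_stop_on_truth(self, medium_dataset):
        ds, truth = medium_dataset
        cfg = SearchConfig(hms1=10, hms2=10, mmes=300, seed=1)
        result = fhsa_run(ds, cfg, truth_pair=truth, early_stop=True)
        assert result.stop_reason in ("early_stop", "mmes_reached")
        if result.stop_reason == "early_stop":
            assert truth in result.candidate_pairs()

    def test_zero_based_wrappers_consistent(self):
        assert pair_index0((0, 1), 10) == 1
        assert linear_to_pair0(1, 10) == (0, 1)
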