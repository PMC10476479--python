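"""Exhaustive oracle and genetic search: correctness, determinism, equivalence."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import entroseg as es
from entroseg.entropy import GuardExceededError
from entroseg.imaging import DomainError

from conftest import random_histogram


def naive_best_thresholds(probs, m, base=2.0):
    """Independent brute-force oracle: direct double loop over all candidate
    vectors, evaluating each class entropy from the raw definition.  Shares no
    code with the implementation under test."""
    z = len(probs)
    best = None
    best_j = None
    for cuts in itertools.combinations(range(1, z), m):
        bounds = [0] + list(cuts) + [z]
        total = 0.0
        feasible = True
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            e = 0.0
            for o in range(lo, hi):
                e += probs[o]
            if e <= 0.0:
                feasible = False
                break
            h = 0.0
            for o in range(lo, hi):
                if probs[o] > 0:
                    r = probs[o] / e
                    h -= r * math.log(r, base)
            total += h
        if feasible and (best_j is None or total > best_j):
            best_j = total
            best = cuts
    return best, best_j


class TestExhaustiveSearch:
    def test_uniform_four_levels(self):
        h = es.GrayHistogram(np.full(4, 0.25), 4)
        r = es.exhaustive_search(h, 1)
        assert r.best_thresholds.cuts == (2,)
        assert abs(r.best_value - 2.0) < 1e-12
        # the off-center cuts tie at log2(3)
        side = es.kapur_objective(h, es.ThresholdVector((1,), n_levels=4))
        assert abs(side - math.log2(3)) < 1e-12

    def test_two_spike_tie_breaks_lexicographically(self):
        p = np.zeros(16)
        p[3] = p[11] = 0.5
        r = es.exhaustive_search(es.GrayHistogram(p, 2), 1)
        assert r.best_thresholds.cuts == (4,)  # smallest cut above the lower spike
        assert r.best_value == 0.0

    def test_uniform_five_levels_two_cuts(self):
        """Optimum splits class sizes as evenly as possible: sum of log sizes."""
        h = es.GrayHistogram(np.full(5, 0.2), 5)
        r = es.exhaustive_search(h, 2)
        naive, naive_j = naive_best_thresholds(h.probs.tolist(), 2)
        assert r.best_thresholds.cuts == naive
        assert abs(r.best_value - 2.0) < 1e-12  # sizes (1,2,2): 0 + 1 + 1 bits
        assert r.best_thresholds.cuts == (1, 3)  # lexicographically first of the ties

    @given(st.integers(0, 2**31), st.integers(4, 16), st.integers(1, 2))
    @settings(max_examples=40)
    def test_matches_independent_brute_force(self, seed, z, m):
        h = random_histogram(z, np.random.default_rng(seed))
        r = es.exhaustive_search(h, m)
        naive, naive_j = naive_best_thresholds(h.probs.tolist(), m)
        assert r.best_thresholds.cuts == naive
        assert abs(r.best_value - naive_j) < 1e-9

    def test_feasibility_error_when_too_few_levels(self):
        p = np.zeros(8)
        p[2] = 1.0
        with pytest.raises(es.FeasibilityError):
            es.exhaustive_search(es.GrayHistogram(p, 10), 1)
        p[5] = 0.5
        p[2] = 0.5
        with pytest.raises(es.FeasibilityError):
            es.exhaustive_search(es.GrayHistogram(p, 10), 2)

    def test_guard_error(self):
        h = es.GrayHistogram(np.full(256, 1 / 256), 256)
        with pytest.raises(GuardExceededError):
            es.exhaustive_search(h, 3, guard=10_000)

    def test_result_value_matches_reevaluation(self, rng):
        h = random_histogram(32, rng)
        r = es.exhaustive_search(h, 2)
        assert r.best_value == es.kapur_objective(h, r.best_thresholds)


class TestSearchConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"m": 0},
            {"population_size": 1},
            {"crossover_rate": 1.5},
            {"mutation_rate": -0.1},
            {"max_generations": 0},
            {"patience": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(DomainError):
            es.SearchConfig(**kwargs)


class TestPopulationSearch:
    def test_fixed_seed_reproducible(self, rng):
        h = random_histogram(64, rng)
        cfg = es.SearchConfig(m=2, seed=42)
        a = es.population_search(h, cfg)
        b = es.population_search(h, cfg)
        assert a.best_thresholds == b.best_thresholds
        assert a.history == b.history
        assert a.evaluations == b.evaluations
        assert a.to_json() == b.to_json()

    def test_different_seeds_may_differ_in_trajectory(self, rng):
        h = random_histogram(64, rng)
        a = es.population_search(h, es.SearchConfig(m=2, seed=0))
        b = es.population_search(h, es.SearchConfig(m=2, seed=1))
        assert a.history != b.history  # distinct search paths

    def test_history_is_non_decreasing(self, rng):
        for _ in range(5):
            h = random_histogram(128, rng)
            r = es.population_search(h, es.SearchConfig(m=2, seed=3))
            assert all(b >= a for a, b in zip(r.history, r.history[1:]))

    def test_matches_oracle_on_small_problems(self, rng):
        for seed in range(8):
            h = random_histogram(32, np.random.default_rng(900 + seed))
            r_exh = es.exhaustive_search(h, 1)
            r_pop = es.population_search(h, es.SearchConfig(m=1, seed=seed))
            assert abs(r_pop.best_value - r_exh.best_value) < 1e-9

    def test_result_is_feasible_and_reevaluated(self, rng):
        h = random_histogram(64, rng)
        r = es.population_search(h, es.SearchConfig(m=3, seed=5))
        j = es.kapur_objective(h, r.best_thresholds)
        assert j is not None and j == r.best_value

    def test_feasibility_error_on_spike(self):
        p = np.zeros(16)
        p[4] = 1.0
        with pytest.raises(es.FeasibilityError):
            es.population_search(es.GrayHistogram(p, 5), es.SearchConfig(m=1, seed=0))

    def test_evaluation_budget_respected(self, rng):
        h = random_histogram(64, rng)
        cfg = es.SearchConfig(m=2, seed=9, population_size=10, max_generations=5, patience=5)
        r = es.population_search(h, cfg)
        assert r.evaluations <= 10 * 5
        assert r.generations_run <= 5


class TestSegment:
    def test_zero_noise_phantom_recovered_perfectly(self):
        """Classes at disjoint gray levels: every Dice is exactly 1."""
        spec = es.preset("liver3", shape=(48, 48), noise_sd=0.0, seed=0)
        image, truth = es.generate_phantom(spec)
        _, labels, _ = es.segment(image, m=2)
        report = es.evaluate(labels, truth)
        assert report.per_class_dice == (1.0, 1.0, 1.0)
        assert report.overall_accuracy == 1.0

    def test_constant_image_is_infeasible(self):
        im = es.GrayImage(np.full((8, 8), 7, dtype=np.int64), n_levels=256)
        with pytest.raises(es.FeasibilityError):
            es.segment(im, m=1)

    def test_population_and_exhaustive_agree_on_four_class_phantom(self):
        spec = es.PhantomSpec(
            shape=(64, 64),
            classes=(
                es.TissueClass("background", "full-field", 8.0),
                es.TissueClass("gallbladder", ("disk", (50.0, 50.0), 9.0), 22.0),
                es.TissueClass("liver", ("ellipse", (28.0, 28.0), (20.0, 16.0), 0.3), 38.0),
                es.TissueClass("tumor", ("disk", (24.0, 24.0), 7.0), 55.0),
            ),
            noise_sd=1.5,
            seed=21,
            n_levels=64,
        )
        image, _ = es.generate_phantom(spec)
        tv_exh, _, _ = es.segment(image, m=3, method="exhaustive")
        cfg = es.SearchConfig(m=3, seed=4, population_size=60, max_generations=200, patience=60)
        tv_pop, _, _ = es.segment(image, m=3, method="population", config=cfg)
        assert tv_pop.cuts == tv_exh.cuts

    def test_report_carries_search_metadata(self, liver3_small):
        _, image, _ = liver3_small
        _, _, result = es.segment(image, m=2, method="population")
        d = result.to_dict()
        assert d["method"] == "population"
        assert d["seed"] == 0 and d["config"]["population_size"] == 30
        assert len(d["history"]) == d["generations_run"]
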