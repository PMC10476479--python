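"""Threshold optimization: exact exhaustive oracle and population-based search.

Both optimizers maximize the Kapur maximum-entropy objective over sorted
integer cut vectors.  ``exhaustive_search`` enumerates every candidate vector
and is the ground truth; ``population_search`` is an elitist integer-coded
genetic algorithm following the standard model / objective / fitness /
stochastic-search pipeline, with infeasible candidates (empty classes)
assigned worst fitness.  Ties are always broken toward the lexicographically
smallest cut vector so both optimizers are fully deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .entropy import (
    DEFAULT_ENUMERATION_GUARD,
    GuardExceededError,
    KapurEvaluator,
    _objective_from_cuts,
    n_candidate_vectors,
    resolve_base,
)
from .imaging import (
    DomainError,
    GrayHistogram,
    GrayImage,
    LabelMap,
    ThresholdVector,
    apply_thresholds,
    compute_histogram,
)

__all__ = [
    "SearchConfig",
    "SearchResult",
    "FeasibilityError",
    "exhaustive_search",
    "population_search",
    "segment",
]


class FeasibilityError(RuntimeError):
    """No threshold vector can give every class nonzero mass."""


@dataclass(frozen=True)
class SearchConfig:
    """Hyperparameters of the population search.

    Defaults (population 30, crossover 0.9, per-gene mutation 0.1, at most 100
    generations with patience 20) are conventional GA settings, not tuned to
    any particular image.  A fixed ``seed`` makes the run fully reproducible.
    """

    m: int = 1
    population_size: int = 30
    max_generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    seed: int = 0
    patience: int = 20
    base: float | str = 2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise DomainError("m must be >= 1")
        if self.population_size < 2:
            raise DomainError("population_size must be >= 2")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must be in [0, 1], got {v}")
        if self.max_generations < 1 or self.patience < 1:
            raise DomainError("max_generations and patience must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["base"] = "e" if d["base"] == math.e else d["base"]
        return d


@dataclass(frozen=True)
class SearchResult:
    """Outcome of a threshold search.

    ``best_value`` is always a fresh :func:`~entroseg.entropy.kapur_objective`
    evaluation of ``best_thresholds``; ``history`` is the per-generation best
    objective (non-decreasing under elitism; a single entry for the
    exhaustive oracle).
    """

    best_thresholds: ThresholdVector
    best_value: float
    base: float
    evaluations: int
    generations_run: int
    history: tuple[float, ...]
    seed: int | None
    method: Literal["exhaustive", "population"]
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "thresholds": list(self.best_thresholds.cuts),
            "n_levels": self.best_thresholds.n_levels,
            "objective": self.best_value,
            "base": "e" if self.base == math.e else self.base,
            "evaluations": self.evaluations,
            "generations_run": self.generations_run,
            "history": list(self.history),
            "seed": self.seed,
            "config": self.config,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _check_feasible(hist: GrayHistogram, m: int) -> None:
    k = int(hist.nonzero_levels().size)
    if k < m + 1:
        raise FeasibilityError(
            f"m={m} thresholds need at least {m + 1} distinct nonzero-mass gray "
            f"levels; histogram has {k}"
        )


def exhaustive_search(
    hist: GrayHistogram,
    m: int,
    base: float | str = 2,
    guard: int = DEFAULT_ENUMERATION_GUARD,
) -> SearchResult:
    """Globally optimal threshold vector by full enumeration.

    Candidates are visited in lexicographic order and compared strictly, so
    ties resolve to the lexicographically smallest optimal vector.  Raises
    :class:`~entroseg.entropy.GuardExceededError` when ``C(Z-1, m)`` exceeds
    ``guard`` and :class:`FeasibilityError` when no feasible vector exists.
    """
    if m < 1:
        raise DomainError("m must be >= 1")
    _check_feasible(hist, m)
    z = hist.n_levels
    n_cand = n_candidate_vectors(z, m)
    if n_cand > guard:
        raise GuardExceededError(
            f"C({z - 1}, {m}) = {n_cand} exceeds the enumeration guard of {guard}; "
            "reduce Z or m, or use population_search"
        )
    b = resolve_base(base)
    import itertools

    best_cuts: tuple[int, ...] | None = None
    best_val = -math.inf
    evals = 0
    for cuts in itertools.combinations(range(1, z), m):
        evals += 1
        j = _objective_from_cuts(hist.probs, cuts, b)
        if j is not None and j > best_val:
            best_val = j
            best_cuts = cuts
    if best_cuts is None:  # pragma: no cover - pre-screened by _check_feasible
        raise FeasibilityError("no feasible threshold vector exists")
    tv = ThresholdVector(best_cuts, n_levels=z)
    return SearchResult(
        best_thresholds=tv,
        best_value=best_val,
        base=b,
        evaluations=evals,
        generations_run=1,
        history=(best_val,),
        seed=None,
        method="exhaustive",
    )


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

def _repair_chromosome(child: np.ndarray, m: int, z: int, rng: np.random.Generator) -> np.ndarray:
    """Sorted, strictly-increasing length-m chromosome in [1, Z-1].

    The only repair applied to malformed children: sort, drop duplicates, and
    redraw the lost genes uniformly from the unused levels.
    """
    child = np.unique(np.clip(child, 1, z - 1))
    if child.size < m:
        pool = np.setdiff1d(np.arange(1, z), child, assume_unique=False)
        extra = rng.choice(pool, size=m - child.size, replace=False)
        child = np.sort(np.concatenate([child, extra]))
    return child


def _lex_less(a: np.ndarray, b: np.ndarray) -> bool:
    for x, y in zip(a, b):
        if x != y:
            return bool(x < y)
    return False


def population_search(hist: GrayHistogram, config: SearchConfig) -> SearchResult:
    """Elitist integer-coded genetic algorithm over sorted cut vectors.

    Chromosomes are strictly increasing cut vectors; fitness is the Kapur
    objective with infeasible candidates at ``-inf``.  Each generation keeps
    the best individual unchanged (elitism), fills the rest by binary-
    tournament selection, uniform crossover of aligned genes, and per-gene
    mutation that either takes a local step or redraws the cut uniformly in
    ``[1, Z-1]``; sort + de-duplicate is the only repair.  Stops after
    ``max_generations`` or ``patience`` generations without improvement.
    Identical seed, config and histogram give an identical result.
    """
    m, z = config.m, hist.n_levels
    _check_feasible(hist, m)
    if z - 1 < m:
        raise FeasibilityError(f"m={m} cuts cannot fit in [1, {z - 1}]")
    rng = np.random.default_rng(config.seed)
    evaluator = KapurEvaluator(hist, config.base)
    pop_n = config.population_size
    step = max(4, z // 8)  # cap on local-mutation step, scales with gray resolution

    pop = np.empty((pop_n, m), dtype=np.int64)
    for i in range(pop_n):
        pop[i] = np.sort(rng.choice(np.arange(1, z), size=m, replace=False))
    fitness = evaluator.evaluate_batch(pop)
    evaluations = pop.shape[0]

    def gen_best(pop: np.ndarray, fitness: np.ndarray) -> int:
        best = 0
        for i in range(1, pop.shape[0]):
            if fitness[i] > fitness[best] or (
                fitness[i] == fitness[best] and _lex_less(pop[i], pop[best])
            ):
                best = i
        return best

    bi = gen_best(pop, fitness)
    best_cuts, best_fit = pop[bi].copy(), float(fitness[bi])
    history = [best_fit]
    stale = 0
    generations_run = 1

    for _ in range(1, config.max_generations):
        children = np.empty_like(pop)
        children[0] = best_cuts  # elite
        for i in range(1, pop_n):
            # binary tournament, twice
            parents = []
            for _p in range(2):
                a, b = rng.integers(0, pop_n, size=2)
                win = a if (
                    fitness[a] > fitness[b]
                    or (fitness[a] == fitness[b] and _lex_less(pop[a], pop[b]))
                ) else b
                parents.append(pop[win])
            if rng.random() < config.crossover_rate:
                mask = rng.random(m) < 0.5
                child = np.where(mask, parents[0], parents[1])
            else:
                child = parents[0].copy()
            mut = rng.random(m) < config.mutation_rate
            if mut.any():
                child = child.copy()
                for g in np.flatnonzero(mut):
                    if rng.random() < 0.75:
                        # local step with geometric magnitude: mostly +-1/+-2,
                        # occasionally long jumps, so stalls near the optimum
                        # get refined while plateaus can still be escaped
                        magnitude = min(int(rng.geometric(0.5)), step)
                        sign = 1 if rng.random() < 0.5 else -1
                        child[g] = child[g] + sign * magnitude
                    else:
                        child[g] = rng.integers(1, z)
            children[i] = _repair_chromosome(child, m, z, rng)
        pop = children
        fitness = evaluator.evaluate_batch(pop)
        evaluations += pop.shape[0]
        generations_run += 1
        bi = gen_best(pop, fitness)
        improved = fitness[bi] > best_fit
        if improved or (fitness[bi] == best_fit and _lex_less(pop[bi], best_cuts)):
            best_cuts, best_fit = pop[bi].copy(), float(fitness[bi])
        history.append(best_fit)
        stale = 0 if improved else stale + 1
        if stale >= config.patience:
            break

    if not math.isfinite(best_fit):  # pragma: no cover - pre-screened
        raise FeasibilityError("search found no feasible threshold vector")
    tv = ThresholdVector(tuple(int(c) for c in best_cuts), n_levels=z)
    final = _objective_from_cuts(hist.probs, tv.cuts, resolve_base(config.base))
    assert final is not None
    return SearchResult(
        best_thresholds=tv,
        best_value=final,
        base=resolve_base(config.base),
        evaluations=evaluations,
        generations_run=generations_run,
        history=tuple(history),
        seed=config.seed,
        method="population",
        config=config.to_dict(),
    )


def segment(
    image: GrayImage,
    m: int,
    method: Literal["exhaustive", "population"] = "exhaustive",
    config: SearchConfig | None = None,
    base: float | str = 2,
    dialect: str = "partition",
    guard: int = DEFAULT_ENUMERATION_GUARD,
) -> tuple[ThresholdVector, LabelMap, SearchResult]:
    """End-to-end pipeline: histogram -> threshold search -> label map."""
    hist = compute_histogram(image)
    if method == "exhaustive":
        result = exhaustive_search(hist, m, base=base, guard=guard)
    elif method == "population":
        if config is None:
            config = SearchConfig(m=m, base=base)
        elif config.m != m:
            config = dataclasses.replace(config, m=m)
        result = population_search(hist, config)
    else:
        raise DomainError(f"unknown method {method!r}")
    labels = apply_thresholds(image, result.best_thresholds, dialect=dialect)
    return result.best_thresholds, labels, result
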