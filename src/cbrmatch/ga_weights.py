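"""Genetic-algorithm learning of the WHVDM attribute weights.

Given a reference case set R and a test set T, the GA evolves a weight vector
w (0 <= w_i <= 1, sum w_i = 1) maximizing the number of correctly predicted
test cases,

    fitness(w) = sum_{t in T} I(y_t = y_{s(t)}),    s(t) = argmin_r WHVDM(t, r),

where I is the indicator function.  Chromosomes are non-negative real gene
vectors decoded by simplex normalization (genes / sum genes), so every decoded
individual satisfies the weight constraints by construction.  Operators:
tournament selection, arithmetic blend crossover, additive Gaussian mutation
clipped at 0, single-elite carryover; early stop when every test case is
predicted correctly.

The per-attribute distance components d_i^2(t, r) do not depend on w, so they
are computed once as an (n, |T|, |R|) tensor and each generation's fitness is
a single matrix product — the GA cost is independent of the metric's cost.
Conditional probabilities come from the reference set only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .case_model import CaseBase, CaseBaseError
from .whvdm import (
    DistanceConfig,
    check_weight_vector,
    component_tensor,
    estimate_cond_probs,
)

__all__ = ["GAConfig", "Chromosome", "fitness", "learn_weights"]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    mutation_sd: float = 0.05
    tournament_size: int = 3
    elitism: int = 1
    seed: int = 0

    def __post_init__(self):
        for r in (self.crossover_rate, self.mutation_rate):
            if not (0 <= r <= 1):
                raise CaseBaseError("rates must lie in [0, 1]")
        if min(self.population_size, self.generations, self.tournament_size) < 1:
            raise CaseBaseError("counts must be >= 1")
        if not (0 <= self.elitism < self.population_size):
            raise CaseBaseError("elitism must be < population_size")


@dataclass
class Chromosome:
    """Non-negative gene vector; decoded weights = genes / sum(genes)."""

    genes: np.ndarray

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=float)
        if np.any(self.genes < 0) or self.genes.sum() <= 0:
            raise CaseBaseError("genes must be non-negative with positive sum")

    def decode(self) -> np.ndarray:
        w = self.genes / self.genes.sum()
        return check_weight_vector(w, self.genes.size)


def _label_index(cases, class_order):
    idx = {a: k for k, a in enumerate(class_order)}
    return np.array([idx[c.y] for c in cases])


def _batch_fitness(W: np.ndarray, D2: np.ndarray, ref_labels: np.ndarray,
                   test_labels: np.ndarray, shape) -> np.ndarray:
    """Fitness of every row of W at once via one matrix product."""
    dist = (W @ D2).reshape(W.shape[0], *shape)
    nearest = np.argmin(dist, axis=2)  # first min = earliest stored case
    return (ref_labels[nearest] == test_labels[None, :]).sum(axis=1)


def fitness(chrom: Chromosome, reference: CaseBase, test: CaseBase,
            config: DistanceConfig = DistanceConfig()) -> int:
    """Count of correctly 1-NN-predicted test cases under the decoded weights."""
    if len(reference.cases) == 0 or len(test.cases) == 0:
        raise CaseBaseError("reference and test sets must be non-empty")
    w = chrom.decode()
    table = estimate_cond_probs(reference, alpha=config.alpha)
    D = component_tensor(test.cases, reference, table, config)
    D2 = D.reshape(D.shape[0], -1)
    ref_labels = _label_index(reference.cases, reference.class_values)
    test_labels = np.array(
        [list(reference.class_values).index(c.y) for c in test.cases]
    )
    return int(_batch_fitness(w[None, :], D2, ref_labels, test_labels,
                              D.shape[1:])[0])


def learn_weights(reference: CaseBase, test: CaseBase,
                  ga: GAConfig = GAConfig(),
                  dist: DistanceConfig = DistanceConfig()):
    """Evolve the attribute weight vector maximizing test-set 1-NN correctness.

    Returns ``(weights, trace)`` where ``trace`` is a list of
    ``(generation, best_fitness, mean_fitness)`` rows; with elitism >= 1 the
    best-so-far fitness is monotone non-decreasing, and identical seeds give
    identical results.
    """
    n = len(reference.schema)
    if n == 1:
        return np.array([1.0]), [(0, None, None)]
    if len(reference.cases) == 0 or len(test.cases) == 0:
        raise CaseBaseError("reference and test sets must be non-empty")

    rng = np.random.default_rng(ga.seed)
    table = estimate_cond_probs(reference, alpha=dist.alpha)
    D = component_tensor(test.cases, reference, table, dist)
    D2 = D.reshape(n, -1)
    ref_labels = _label_index(reference.cases, reference.class_values)
    test_labels = np.array(
        [list(reference.class_values).index(c.y) for c in test.cases]
    )

    # flat-Dirichlet population plus one uniform-weights individual
    pop = rng.dirichlet(np.ones(n), size=ga.population_size)
    pop[0] = np.full(n, 1.0 / n)

    def decode(P):
        return P / P.sum(axis=1, keepdims=True)

    fit = _batch_fitness(decode(pop), D2, ref_labels, test_labels, D.shape[1:])
    best_idx = int(np.argmax(fit))
    best_genes, best_fit = pop[best_idx].copy(), int(fit[best_idx])
    trace = [(0, best_fit, float(fit.mean()))]

    for gen in range(1, ga.generations + 1):
        if best_fit == len(test.cases):
            break
        children = np.empty_like(pop)
        # elite carryover
        elite_order = np.argsort(-fit, kind="stable")[: ga.elitism]
        children[: ga.elitism] = pop[elite_order]
        for j in range(ga.elitism, ga.population_size):
            def tournament():
                contenders = rng.integers(0, ga.population_size,
                                          size=ga.tournament_size)
                return pop[contenders[np.argmax(fit[contenders])]]

            p1 = tournament()
            if rng.random() < ga.crossover_rate:
                u = rng.random()
                child = u * p1 + (1 - u) * tournament()
            else:
                child = p1.copy()
            mask = rng.random(n) < ga.mutation_rate
            child = child + mask * rng.normal(0.0, ga.mutation_sd, size=n)
            child = np.clip(child, 0.0, None)
            if child.sum() <= 0:
                child = np.full(n, 1.0 / n)
            children[j] = child
        pop = children
        fit = _batch_fitness(decode(pop), D2, ref_labels, test_labels,
                             D.shape[1:])
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_fit = int(fit[gen_best])
            best_genes = pop[gen_best].copy()
        trace.append((gen, best_fit, float(fit.mean())))

    weights = best_genes / best_genes.sum()
    return check_weight_vector(weights, n), trace
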