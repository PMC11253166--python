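"""Genetic curation of small, transferable training subsets.

A fixed-size subset of a pool benchset is bred for transferability: the
fitness of a candidate subset is the reciprocal of its mean transferability
ratio (at the fully flexible seven-parameter model) to a collection of
evaluation subsets, so lower cross-set error means higher fitness.  Several
independent runs produce a population of "pretty transferable" candidates,
from which the final subset is selected by a diversity-biased score

    score(c) = N_el(c) / mean_{p in {1,4,7}} Tbar_p(c),

where ``Tbar_p`` is the mean transferability of the candidate over the
evaluation subsets at parameter count p, and ``N_el`` is the number of unique
chemical elements it contains.  Averaging over several p guards against
accidental transferability at one specific flexibility; the element-count
numerator biases against over-representation of the most common chemistry.

The score's exact functional form is a reconstruction honouring those
constraints (larger element diversity and lower mean transferability are
both rewarded); treat it as this package's operationalization, not a
canonical formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_data import Benchset, unique_elements
from .fitting import XygRegressor
from .metrics import DEFAULT_ETA, transferability
from .xyg_model import design_matrix, reference_energies

DEFAULT_P_LIST = (1, 4, 7)


@dataclass
class GAOptions:
    population: int = 32
    generations: int = 200
    tournament_k: int = 2
    mutation_rate: float = 0.05
    elitism: int = 2
    fitness_p: int = 7
    eta: float = DEFAULT_ETA
    seed: int = 0

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be at least 2")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population:
            raise ValueError("elitism must be in [0, population)")


@dataclass
class SubsetCandidate:
    indices: tuple  # sorted process indices into the pool
    fitness: float | None = None
    n_el: int | None = None
    tbar: dict = field(default_factory=dict)  # p -> mean transferability
    score: float | None = None


class _Evaluator:
    """Caches designs, eval-subset accuracy limits and candidate fitnesses."""

    def __init__(self, pool: Benchset, eval_subsets, eta: float = DEFAULT_ETA,
                 allow_overlap: bool = True):
        self.pool = pool
        self.eta = eta
        self.X = design_matrix(pool)
        self.y = reference_energies(pool)
        self.evals = []
        for s in eval_subsets:
            self.evals.append((s.name, design_matrix(s), reference_energies(s)))
        self._self_mad = {}   # (set index, p) -> MAD_S@S
        self._fitness = {}    # (frozenset, p) -> mean transferability
        self.allow_overlap = allow_overlap

    def self_mad(self, k: int, p: int) -> float:
        key = (k, p)
        if key not in self._self_mad:
            _, Xs, ys = self.evals[k]
            est = XygRegressor(p=p).fit(Xs, ys)
            self._self_mad[key] = est.mad_
        return self._self_mad[key]

    def mean_transferability(self, indices, p: int) -> float:
        """Mean over eval subsets S of T_S@candidate at parameter count p."""
        key = (frozenset(indices), p)
        if key not in self._fitness:
            idx = list(indices)
            est = XygRegressor(p=p).fit(self.X[idx], self.y[idx])
            ts = []
            for k, (_, Xs, ys) in enumerate(self.evals):
                mad_sc = float(np.mean(np.abs(Xs @ est.coef_ - ys)))
                ts.append(transferability(mad_sc, self.self_mad(k, p), self.eta).t)
            self._fitness[key] = float(np.mean(ts))
        return self._fitness[key]

    def fitness(self, indices, p: int) -> float:
        return 1.0 / self.mean_transferability(indices, p)

    def n_el(self, indices) -> int:
        return len(unique_elements(self.pool.restrict(list(indices))))


def _repair(indices: set, size: int, n_pool: int, rng) -> tuple:
    """Force a candidate back to exactly ``size`` distinct indices."""
    idx = set(int(i) for i in indices)
    while len(idx) > size:
        idx.remove(int(rng.choice(sorted(idx))))
    if len(idx) < size:
        missing = np.setdiff1d(np.arange(n_pool), sorted(idx))
        add = rng.choice(missing, size=size - len(idx), replace=False)
        idx.update(int(i) for i in add)
    return tuple(sorted(idx))


def _crossover(a: tuple, b: tuple, size: int, n_pool: int, rng) -> tuple:
    """Uniform crossover over the union of parent genes, with size repair."""
    union = sorted(set(a) | set(b))
    keep = [g for g in union if (g in a and g in b) or rng.random() < 0.5]
    return _repair(set(keep), size, n_pool, rng)


def _mutate(indices: tuple, size: int, n_pool: int, rate: float, rng) -> tuple:
    idx = set(indices)
    outside = np.setdiff1d(np.arange(n_pool), list(idx))
    for g in list(idx):
        if outside.size and rng.random() < rate:
            j = int(rng.integers(outside.size))
            idx.remove(g)
            idx.add(int(outside[j]))
            outside[j] = g
    return _repair(idx, size, n_pool, rng)


def _ga_run(ev: _Evaluator, size: int, opts: GAOptions, rng) -> SubsetCandidate:
    n_pool = len(ev.pool.processes)
    p = opts.fitness_p

    def random_candidate():
        return tuple(sorted(int(i) for i in rng.choice(n_pool, size=size, replace=False)))

    pop = [random_candidate() for _ in range(opts.population)]
    fits = [ev.fitness(c, p) for c in pop]
    best_idx = int(np.argmax(fits))
    best, best_fit = pop[best_idx], fits[best_idx]

    for _ in range(opts.generations):
        order = np.argsort(fits)[::-1]
        new_pop = [pop[i] for i in order[: opts.elitism]]
        while len(new_pop) < opts.population:
            parents = []
            for _ in range(2):
                contenders = rng.choice(opts.population, size=opts.tournament_k, replace=False)
                winner = max(contenders, key=lambda i: fits[i])
                parents.append(pop[int(winner)])
            child = _crossover(parents[0], parents[1], size, n_pool, rng)
            child = _mutate(child, size, n_pool, opts.mutation_rate, rng)
            new_pop.append(child)
        pop = new_pop
        fits = [ev.fitness(c, p) for c in pop]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best, best_fit = pop[gen_best], fits[gen_best]

    return SubsetCandidate(indices=best, fitness=best_fit, n_el=ev.n_el(best))


def ga_breed(pool: Benchset, eval_subsets, n_candidates: int, size: int,
             opts: GAOptions | None = None) -> list:
    """Breed ``n_candidates`` transferable subsets by independent GA runs.

    Each run draws its random stream from the master seed plus its run index,
    so runs are independent and the whole procedure is reproducible.
    """
    opts = opts or GAOptions()
    if size >= len(pool.processes):
        raise ValueError("subset size must be smaller than the pool")
    if not eval_subsets:
        raise ValueError("at least one evaluation subset is required")
    ev = _Evaluator(pool, eval_subsets, eta=opts.eta)
    out = []
    for run in range(n_candidates):
        rng = np.random.default_rng([opts.seed, run])
        out.append(_ga_run(ev, size, opts, rng))
    return out


def exhaustive_best(pool: Benchset, eval_subsets, size: int,
                    opts: GAOptions | None = None) -> SubsetCandidate:
    """Brute-force best subset by fitness — independent oracle for small pools."""
    import itertools

    opts = opts or GAOptions()
    ev = _Evaluator(pool, eval_subsets, eta=opts.eta)
    n_pool = len(pool.processes)
    best, best_fit = None, -np.inf
    for combo in itertools.combinations(range(n_pool), size):
        f = ev.fitness(combo, opts.fitness_p)
        if f > best_fit:
            best, best_fit = combo, f
    return SubsetCandidate(indices=best, fitness=best_fit, n_el=ev.n_el(best))


def diversity_score(n_el: int, mean_tbar: float) -> float:
    """score = N_el / (mean over p of Tbar_p); higher is better."""
    if mean_tbar <= 0:
        raise ValueError("mean transferability must be positive")
    return n_el / mean_tbar


def score_candidate(c: SubsetCandidate, pool: Benchset, eval_subsets,
                    p_list=DEFAULT_P_LIST, eta: float = DEFAULT_ETA,
                    _evaluator: _Evaluator | None = None) -> float:
    """Diversity-biased selection score of a candidate subset.

    Fills in the candidate's ``n_el``, per-p mean transferabilities and
    ``score`` fields, and returns the score.
    """
    if not p_list:
        raise ValueError("p_list must be non-empty")
    ev = _evaluator or _Evaluator(pool, eval_subsets, eta=eta)
    c.n_el = ev.n_el(c.indices)
    c.tbar = {int(p): ev.mean_transferability(c.indices, p) for p in p_list}
    c.score = diversity_score(c.n_el, float(np.mean(list(c.tbar.values()))))
    return c.score


def select_best(candidates, pool: Benchset, eval_subsets,
                p_list=DEFAULT_P_LIST, eta: float = DEFAULT_ETA,
                name: str = "selected") -> Benchset:
    """Materialize the argmax-score candidate as a benchset.

    Ties break toward higher element count, then lexicographically lower
    indices.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates to select from")
    ev = _Evaluator(pool, eval_subsets, eta=eta)
    for c in candidates:
        score_candidate(c, pool, eval_subsets, p_list=p_list, eta=eta, _evaluator=ev)
    best = max(
        enumerate(candidates),
        key=lambda ic: (ic[1].score, ic[1].n_el, tuple(-i for i in ic[1].indices), -ic[0]),
    )[1]
    return pool.restrict(list(best.indices), name=name)
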