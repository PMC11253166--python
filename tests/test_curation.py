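import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tatkit.curation import (
    GAOptions,
    SubsetCandidate,
    _crossover,
    _mutate,
    _repair,
    diversity_score,
    exhaustive_best,
    ga_breed,
    score_candidate,
    select_best,
)
from tatkit.synthetic_data import (
    Regime,
    PLANTED_FLAT,
    PLANTED_SHARP,
    SyntheticSpec,
    generate_benchset,
    generate_curation_pool,
)


@pytest.fixture(scope="module")
def toy_pool():
    spec = SyntheticSpec(
        n_species=10, n_processes=12,
        regimes=[Regime("r1", PLANTED_SHARP), Regime("r2", PLANTED_FLAT)],
        noise_sigma=0.3, seed=7, name="toy_pool",
    )
    pool = generate_benchset(spec)
    evals = [pool.by_subset(s) for s in pool.subsets]
    return pool, evals


def test_diversity_score_formula():
    # Equal mean transferability, element counts 10 vs 5: score ratio 2.
    assert diversity_score(10, 1.3) / diversity_score(5, 1.3) == pytest.approx(2.0)
    # Perfect transferability (all T = 1) scores exactly N_el.
    for m in (3, 15):
        assert diversity_score(m, 1.0) == m
    with pytest.raises(ValueError):
        diversity_score(5, 0.0)


def test_ga_determinism_and_size_invariant(toy_pool):
    pool, evals = toy_pool
    opts = GAOptions(seed=4, generations=10, population=8)
    a = ga_breed(pool, evals, n_candidates=2, size=4, opts=opts)
    b = ga_breed(pool, evals, n_candidates=2, size=4, opts=opts)
    assert [c.indices for c in a] == [c.indices for c in b]
    assert [c.fitness for c in a] == [c.fitness for c in b]
    for c in a:
        assert len(c.indices) == 4
        assert len(set(c.indices)) == 4


def test_ga_contract_errors(toy_pool):
    pool, evals = toy_pool
    with pytest.raises(ValueError):
        ga_breed(pool, evals, n_candidates=1, size=len(pool.processes))
    with pytest.raises(ValueError):
        ga_breed(pool, [], n_candidates=1, size=4)


@settings(max_examples=100, deadline=None)
@given(
    genes=st.sets(st.integers(min_value=0, max_value=29), max_size=12),
    size=st.integers(min_value=1, max_value=10),
    seed=st.integers(min_value=0, max_value=1000),
)
def test_repair_always_restores_size(genes, size, seed):
    rng = np.random.default_rng(seed)
    repaired = _repair(genes, size, 30, rng)
    assert len(repaired) == size
    assert len(set(repaired)) == size
    assert all(0 <= g < 30 for g in repaired)


@settings(max_examples=60, deadline=None)
@given(seed=st.integers(min_value=0, max_value=1000))
def test_crossover_and_mutation_preserve_size(seed):
    rng = np.random.default_rng(seed)
    n_pool, size = 20, 6
    a = tuple(sorted(rng.choice(n_pool, size=size, replace=False)))
    b = tuple(sorted(rng.choice(n_pool, size=size, replace=False)))
    child = _crossover(a, b, size, n_pool, rng)
    assert len(child) == size and len(set(child)) == size
    mutant = _mutate(child, size, n_pool, 0.3, rng)
    assert len(mutant) == size and len(set(mutant)) == size


def test_fitness_invariant_to_index_order(toy_pool):
    pool, evals = toy_pool
    from tatkit.curation import _Evaluator

    ev = _Evaluator(pool, evals)
    assert ev.mean_transferability((0, 3, 5, 7), 7) == \
        ev.mean_transferability((7, 5, 3, 0), 7)


def test_ga_reaches_exhaustive_optimum(toy_pool):
    pool, evals = toy_pool
    best = exhaustive_best(pool, evals, size=4)
    cands = ga_breed(pool, evals, n_candidates=1, size=4,
                     opts=GAOptions(seed=0, generations=60, population=24))
    assert cands[0].fitness >= 0.95 * best.fitness


def test_score_candidate_fills_fields(toy_pool):
    pool, evals = toy_pool
    c = SubsetCandidate(indices=(0, 1, 6, 7))
    score = score_candidate(c, pool, evals, p_list=(1, 4, 7))
    assert c.score == score > 0
    assert set(c.tbar) == {1, 4, 7}
    assert c.n_el is not None
    assert score == pytest.approx(
        c.n_el / np.mean([c.tbar[1], c.tbar[4], c.tbar[7]]))
    with pytest.raises(ValueError):
        score_candidate(c, pool, evals, p_list=())


def test_select_best_ordering_and_recomputation(toy_pool):
    pool, evals = toy_pool
    single = [SubsetCandidate(indices=(0, 1, 2, 3))]
    chosen = select_best(single, pool, evals)
    assert [p.id for p in chosen.processes] == \
        [pool.processes[i].id for i in (0, 1, 2, 3)]

    rng = np.random.default_rng(5)
    cands = [
        SubsetCandidate(indices=tuple(sorted(
            int(i) for i in rng.choice(12, size=4, replace=False))))
        for _ in range(6)
    ]
    chosen = select_best(cands, pool, evals)
    # Independent re-scoring argmax must agree.
    scores = [score_candidate(SubsetCandidate(indices=c.indices), pool, evals)
              for c in cands]
    best_idx = int(np.argmax(scores))
    assert [p.id for p in chosen.processes] == \
        [pool.processes[i].id for i in cands[best_idx].indices]


def test_selection_picks_planted_subset():
    pool, planted = generate_curation_pool(seed=0)
    evals = [pool.by_subset(s) for s in pool.subsets]
    rng = np.random.default_rng(99)
    n = len(pool.processes)
    cands = [SubsetCandidate(indices=planted)] + [
        SubsetCandidate(indices=tuple(sorted(
            int(i) for i in rng.choice(n, size=len(planted), replace=False))))
        for _ in range(8)
    ]
    chosen = select_best(cands, pool, evals)
    assert [p.id for p in chosen.processes] == \
        [pool.processes[i].id for i in planted]


def test_select_best_empty_rejected(toy_pool):
    pool, evals = toy_pool
    with pytest.raises(ValueError):
        select_best([], pool, evals)
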