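"""Seeded generators of synthetic benchsets with planted coefficient vectors.

Real component energies require quantum-chemistry calculations; these
generators emulate their statistical structure instead, so that every part of
the toolkit is testable without external data:

* per-component magnitude hierarchy (exchange components much larger than MP2
  components, mimicking real energetics) — stylized constants, not fitted to
  any real data;
* one or more "chemistry regimes", each with its own planted coefficient
  vector (distinct optima in parameter space) and its own landscape
  flatness — per-component scale factors that, when small, make the error
  landscape insensitive to the corresponding parameters;
* reference energies generated from the planted model plus Gaussian noise;
* per-species element sets drawn from a configurable pool.

All randomness flows from a single seed through fixed sub-streams (species,
processes, noise), so enlarging the species table never perturbs the noise
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_data import Benchset, Process, Species
from .xyg_model import design_matrix

#: Per-component species scales in hartree; exchange >> MP2 hierarchy.
DEFAULT_COMPONENT_SCALES = (0.05, 0.015, 0.05, 0.015, 0.03, 0.008, 0.02)

DEFAULT_ELEMENT_POOL = (
    "H", "C", "N", "O", "F", "S", "Cl", "P", "Si", "B",
    "Fe", "Cu", "Zn", "Ni", "Br",
)

#: Planted coefficient vectors for the default two-regime fixture.  The two
#: regimes share similar exchange slots but are displaced strongly along the
#: correlation/MP2 direction, so low-p models transfer between them while
#: high-p models overfit regime-specific structure.
PLANTED_SHARP = (0.55, 0.10, 0.42, -0.08, 0.62, 0.30, 0.55)
PLANTED_FLAT = (0.57, 0.08, 0.44, -0.06, 0.30, 1.10, 0.90)

#: Flatness of the "flat" regime: the correlation design columns that the MP2
#: fraction acts on are shrunk, so the flat set's errors are nearly
#: insensitive to that parameter direction (an easy-to-learn set whose own
#: optimum is therefore poorly located).
FLAT_MP2_FACTORS = (1.0, 1.0, 1.0, 1.0, 0.05, 0.02, 0.02)


@dataclass(frozen=True)
class Regime:
    name: str
    planted_a: tuple
    weight: float = 1.0
    flatness: tuple = (1.0,) * 7


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic benchset generator."""

    n_species: int = 40
    n_processes: int = 200
    regimes: list = field(default_factory=lambda: [
        Regime("main", planted_a=PLANTED_SHARP)
    ])
    noise_sigma: float = 0.5
    component_scales: tuple = DEFAULT_COMPONENT_SCALES
    element_pool: tuple = DEFAULT_ELEMENT_POOL
    elements_per_species: tuple = (1, 4)
    stoich_sizes: tuple = (2, 5)
    coefficients: tuple = (-2.0, -1.0, 1.0, 2.0)
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self):
        if not self.regimes:
            raise ValueError("at least one regime is required")
        if any(r.weight <= 0 for r in self.regimes):
            raise ValueError("regime weights must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for r in self.regimes:
            if any(f <= 0 for f in r.flatness):
                raise ValueError(f"regime {r.name!r}: flatness factors must be positive")


def _allocate(total: int, weights) -> list:
    """Largest-remainder allocation of ``total`` over ``weights``."""
    w = np.asarray(weights, dtype=float)
    exact = total * w / w.sum()
    counts = np.floor(exact).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:rem]] += 1
    return counts.tolist()


def _make_species(spec: SyntheticSpec, rng, regime: Regime, count: int, start: int,
                  element_subpool=None) -> list:
    lo, hi = spec.elements_per_species
    pool = list(element_subpool if element_subpool is not None else spec.element_pool)
    scales = np.asarray(spec.component_scales) * np.asarray(regime.flatness)
    out = []
    for k in range(count):
        comps = rng.normal(0.0, 1.0, size=7) * scales
        n_el = int(rng.integers(lo, hi + 1))
        n_el = min(n_el, len(pool))
        elements = {}
        for sym in rng.choice(pool, size=n_el, replace=False):
            elements[str(sym)] = int(rng.integers(1, 4))
        from collections import Counter
        out.append(Species(id=f"S{start + k:04d}", elements=Counter(elements),
                           components=tuple(comps)))
    return out


def _make_processes(spec: SyntheticSpec, rng, regime: Regime, species_ids, count, start):
    lo, hi = spec.stoich_sizes
    if len(species_ids) < 2:
        raise ValueError(f"regime {regime.name!r}: needs at least 2 species")
    procs = []
    for k in range(count):
        m = int(rng.integers(lo, min(hi, len(species_ids)) + 1))
        chosen = rng.choice(len(species_ids), size=m, replace=False)
        coeffs = rng.choice(spec.coefficients, size=m)
        stoich = tuple((species_ids[int(i)], float(c)) for i, c in zip(chosen, coeffs))
        procs.append(Process(id=f"P{start + k:04d}", stoichiometry=stoich,
                             ref_energy=0.0, subset=regime.name))
    return procs


def generate_benchset(spec: SyntheticSpec, return_noise: bool = False):
    """Generate a seeded benchset with planted-model reference energies.

    Species components are Gaussian with the per-component magnitude
    hierarchy, scaled by the owning regime's flatness factors; processes are
    sparse random stoichiometries over their regime's species; each reference
    energy is the planted-model prediction plus N(0, noise_sigma²) noise.
    """
    ss = np.random.SeedSequence(spec.seed)
    species_rng, process_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    sp_counts = _allocate(spec.n_species, [r.weight for r in spec.regimes])
    pr_counts = _allocate(spec.n_processes, [r.weight for r in spec.regimes])
    if any(c < 2 for c in sp_counts):
        raise ValueError("n_species too small to give every regime at least 2 species")
    if any(c < 1 for c in pr_counts):
        raise ValueError("n_processes too small to populate every regime")

    species = []
    regime_species_ids = []
    start = 0
    for regime, count in zip(spec.regimes, sp_counts):
        batch = _make_species(spec, species_rng, regime, count, start)
        species.extend(batch)
        regime_species_ids.append([sp.id for sp in batch])
        start += count

    processes = []
    start = 0
    for regime, ids, count in zip(spec.regimes, regime_species_ids, pr_counts):
        processes.extend(_make_processes(spec, process_rng, regime, ids, count, start))
        start += count

    table = {sp.id: sp for sp in species}
    bench = Benchset(name=spec.name, processes=processes, species_table=table)

    # Reference energies: planted model + noise, regime by regime in order.
    D = design_matrix(bench)
    noise = noise_rng.normal(0.0, spec.noise_sigma, size=len(processes)) \
        if spec.noise_sigma > 0 else np.zeros(len(processes))
    planted = {r.name: np.asarray(r.planted_a, dtype=float) for r in spec.regimes}
    refs = np.array([
        D[j] @ planted[proc.subset] + noise[j] for j, proc in enumerate(processes)
    ])
    bench.processes = [
        Process(id=p.id, stoichiometry=p.stoichiometry, ref_energy=float(refs[j]),
                subset=p.subset)
        for j, p in enumerate(bench.processes)
    ]
    if return_noise:
        return bench, noise
    return bench


def default_two_regime_spec(seed: int = 0, n_species: int = 40,
                            n_processes: int = 160,
                            noise_sigma: float = 0.5) -> SyntheticSpec:
    """The default sharp/flat fixture emulating reaction-vs-barrier asymmetry."""
    return SyntheticSpec(
        n_species=n_species,
        n_processes=n_processes,
        regimes=[
            Regime("sharp", planted_a=PLANTED_SHARP, flatness=(1.0,) * 7),
            Regime("flat", planted_a=PLANTED_FLAT, flatness=FLAT_MP2_FACTORS),
        ],
        noise_sigma=noise_sigma,
        seed=seed,
        name="two_regime",
    )


def generate_two_regime(spec: SyntheticSpec | None = None, seed: int = 0):
    """Generate a (sharp, flat) benchset pair sharing one species table.

    The sharp regime's error landscape is sensitive to all parameters; the
    flat regime's MP2 design columns are shrunk, so its errors are nearly
    insensitive to the MP2 fractions.  Training on the flat set therefore
    leaves those parameters poorly determined and transfers badly to the
    sharp set, while the reverse transfer is mild — the hallmark asymmetry of
    easy-to-learn versus information-rich sets.
    """
    spec = spec or default_two_regime_spec(seed=seed)
    if len(spec.regimes) != 2:
        raise ValueError("generate_two_regime requires exactly 2 regimes")
    combined = generate_benchset(spec)
    names = [r.name for r in spec.regimes]
    out = []
    for nm in names:
        idx = [i for i, p in enumerate(combined.processes) if p.subset == nm]
        procs = [combined.processes[i] for i in idx]
        out.append(Benchset(name=nm, processes=procs,
                            species_table=combined.species_table))
    return tuple(out)


def default_curation_spec(seed: int = 0) -> SyntheticSpec:
    """Three-regime pool used for curation fixtures.

    The majority regime dominates the pool (as common chemistry dominates
    real pools), and the regimes' planted optima are displaced, so random
    subsets mostly train the majority regime and transfer poorly to the
    minority ones, while a regime-balanced subset trains a compromise that
    transfers to all three.
    """
    base = np.asarray(PLANTED_SHARP)
    d2 = base + np.array([0.0, 0.0, 0.0, 0.0, 0.25, 0.20, 0.0])
    d3 = base + np.array([-0.15, 0.0, 0.12, 0.0, 0.0, 0.0, 0.25])
    return SyntheticSpec(
        n_species=42,
        n_processes=72,
        regimes=[
            Regime("reactions", planted_a=tuple(base), weight=4.0),
            Regime("barriers", planted_a=tuple(d2), weight=1.0),
            Regime("metals", planted_a=tuple(d3), weight=1.0),
        ],
        noise_sigma=0.3,
        seed=seed,
        name="curation_pool",
    )


def generate_curation_pool(spec: SyntheticSpec | None = None, planted_size: int = 12,
                           seed: int = 0):
    """Pool benchset with a planted high-quality subset; returns its indices.

    The planted subset is built with balanced regime coverage and species
    whose element sets tile the whole element pool, so both its mean
    transferability and its element count beat those of random size-matched
    subsets.  Non-planted processes use species drawn from a small common
    sub-pool of elements.
    """
    spec = spec or default_curation_spec(seed=seed)
    if planted_size >= spec.n_processes:
        raise ValueError("planted_size must be smaller than n_processes")
    n_regimes = len(spec.regimes)
    if planted_size < n_regimes:
        raise ValueError("planted_size must cover every regime at least once")

    ss = np.random.SeedSequence(spec.seed)
    species_rng, process_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    # Ordinary species draw elements from a small common sub-pool; each
    # "diverse" species carries exactly one rare element, assigned round-robin,
    # so reaching full element coverage requires (essentially) the whole
    # planted subset rather than a few of its processes.
    common_pool = list(spec.element_pool[:4])
    rare_pool = list(spec.element_pool[4:]) or common_pool
    planted_per_regime = _allocate(planted_size, [1.0] * n_regimes)
    sp_counts = _allocate(spec.n_species, [r.weight for r in spec.regimes])
    if any(c <= d for c, d in zip(sp_counts, planted_per_regime)):
        raise ValueError("n_species too small for the requested planted_size")

    from collections import Counter
    species = []
    ordinary_ids, diverse_ids = [], []
    start = 0
    tile = 0
    for regime, count, n_div in zip(spec.regimes, sp_counts, planted_per_regime):
        ordinary = _make_species(spec, species_rng, regime, count - n_div, start,
                                 element_subpool=common_pool)
        start += count - n_div
        diverse = []
        scales = np.asarray(spec.component_scales) * np.asarray(regime.flatness)
        for k in range(n_div):
            comps = species_rng.normal(0.0, 1.0, size=7) * scales
            elements = Counter({rare_pool[tile % len(rare_pool)]: 1,
                                common_pool[tile % len(common_pool)]: 1})
            tile += 1
            diverse.append(Species(id=f"S{start + k:04d}", elements=elements,
                                   components=tuple(comps)))
        start += n_div
        species.extend(ordinary + diverse)
        ordinary_ids.append([sp.id for sp in ordinary])
        diverse_ids.append([sp.id for sp in diverse])

    # Planted processes first (balanced over regimes; each is anchored to its
    # own diverse species but draws the rest from the whole regime for a
    # well-conditioned design), then ordinary processes.
    rest = spec.n_processes - planted_size
    rest_counts = _allocate(rest, [r.weight for r in spec.regimes])

    processes = []
    start = 0
    lo_m, hi_m = spec.stoich_sizes
    for regime, div_ids, ord_ids, count in zip(spec.regimes, diverse_ids,
                                               ordinary_ids, planted_per_regime):
        all_ids = ord_ids + div_ids
        for k in range(count):
            m = int(process_rng.integers(lo_m, min(hi_m, len(all_ids)) + 1))
            anchor = div_ids[k % len(div_ids)]
            others = [s for s in all_ids if s != anchor]
            chosen = [anchor] + [
                others[int(i)]
                for i in process_rng.choice(len(others), size=m - 1, replace=False)
            ]
            coeffs = process_rng.choice(spec.coefficients, size=m)
            processes.append(Process(
                id=f"P{start + k:04d}",
                stoichiometry=tuple((sid, float(c)) for sid, c in zip(chosen, coeffs)),
                ref_energy=0.0, subset=regime.name,
            ))
        start += count
    planted_indices = tuple(range(planted_size))
    for regime, ids, count in zip(spec.regimes, ordinary_ids, rest_counts):
        processes.extend(_make_processes(spec, process_rng, regime, ids, count, start))
        start += count

    table = {sp.id: sp for sp in species}
    bench = Benchset(name=spec.name, processes=processes, species_table=table)
    D = design_matrix(bench)
    noise = noise_rng.normal(0.0, spec.noise_sigma, size=len(processes)) \
        if spec.noise_sigma > 0 else np.zeros(len(processes))
    planted = {r.name: np.asarray(r.planted_a, dtype=float) for r in spec.regimes}
    refs = [float(D[j] @ planted[p.subset] + noise[j])
            for j, p in enumerate(processes)]
    bench.processes = [
        Process(id=p.id, stoichiometry=p.stoichiometry, ref_energy=refs[j], subset=p.subset)
        for j, p in enumerate(bench.processes)
    ]
    return bench, planted_indices
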