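from collections import Counter

import numpy as np
import pytest

from tatkit.chem_data import Benchset, Process, Species


def make_species(sid, components, elements=("H",)):
    return Species(id=sid, elements=Counter(elements), components=tuple(components))


def make_benchset(name, species, processes):
    return Benchset(name=name, processes=list(processes),
                    species_table={sp.id: sp for sp in species})


@pytest.fixture
def unit_component_benchset():
    """One species with c = (1, 0, ..., 0) hartree and the process '1·X'."""
    sp = make_species("X", [1, 0, 0, 0, 0, 0, 0])
    proc = Process(id="p1", stoichiometry=[("X", 1.0)], ref_energy=0.0, subset="s")
    return make_benchset("unit", [sp], [proc])


@pytest.fixture
def random_benchset():
    """Small random benchset with hand-built species and processes."""
    rng = np.random.default_rng(42)
    species = [
        make_species(f"S{i}", rng.normal(size=7) * 0.02, elements=("C", "H", "O"))
        for i in range(5)
    ]
    procs = []
    for j in range(8):
        ids = rng.choice(5, size=3, replace=False)
        coeffs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=3)
        procs.append(Process(
            id=f"p{j}", stoichiometry=[(f"S{i}", float(c)) for i, c in zip(ids, coeffs)],
            ref_energy=float(rng.normal(scale=10)), subset="s",
        ))
    return make_benchset("rand", species, procs)


@pytest.fixture
def noise_free_benchset():
    """Synthetic benchset with zero noise (exact planted linear system)."""
    from tatkit.synthetic_data import SyntheticSpec, generate_benchset

    spec = SyntheticSpec(n_species=20, n_processes=50, noise_sigma=0.0, seed=11)
    return generate_benchset(spec), np.asarray(spec.regimes[0].planted_a)
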