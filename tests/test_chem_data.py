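from collections import Counter

import numpy as np
import pytest

from tatkit.chem_data import (
    Benchset,
    Process,
    SchemaError,
    Species,
    format_formula,
    load_benchset,
    parse_formula,
    unique_elements,
    write_benchset,
)
from tatkit.synthetic_data import SyntheticSpec, generate_benchset

from conftest import make_benchset, make_species


@pytest.mark.parametrize("formula,expected", [
    ("H2O", {"H": 2, "O": 1}),
    ("C2H6O", {"C": 2, "H": 6, "O": 1}),
    ("FeCl3", {"Fe": 1, "Cl": 3}),
    ("H", {"H": 1}),
])
def test_parse_formula(formula, expected):
    assert parse_formula(formula) == Counter(expected)


@pytest.mark.parametrize("bad", ["", "2H", "h2o", "C2h6"])
def test_parse_formula_rejects_malformed(bad):
    with pytest.raises(SchemaError):
        parse_formula(bad)


def test_format_formula_hill_order_round_trip():
    for formula in ["C2H6O", "H2O", "Cl3Fe", "CH4", "C6H5BrO2"]:
        assert format_formula(parse_formula(formula)) == formula


def test_species_invariants():
    with pytest.raises(SchemaError):
        Species(id="x", elements=Counter(), components=(0,) * 7)
    with pytest.raises(SchemaError):
        Species(id="x", elements=Counter({"H": 1}), components=(0,) * 6)
    with pytest.raises(SchemaError):
        Species(id="x", elements=Counter({"H": 1}),
                components=(float("nan"),) + (0.0,) * 6)


def test_process_invariants():
    with pytest.raises(SchemaError):
        Process(id="p", stoichiometry=[], ref_energy=0.0, subset="s")
    with pytest.raises(SchemaError):
        Process(id="p", stoichiometry=[("X", 0.0)], ref_energy=0.0, subset="s")


def test_benchset_requires_resolvable_species():
    sp = make_species("A", [0.0] * 7)
    proc = Process(id="p", stoichiometry=[("B", 1.0)], ref_energy=0.0, subset="s")
    with pytest.raises(SchemaError, match="B"):
        Benchset(name="b", processes=[proc], species_table={"A": sp})


def test_round_trip_single_process(tmp_path, unit_component_benchset):
    write_benchset(unit_component_benchset, tmp_path / "sp.csv", tmp_path / "pr.csv")
    again = load_benchset(tmp_path / "sp.csv", tmp_path / "pr.csv")
    assert len(again.processes) == 1
    assert again == unit_component_benchset


def test_round_trip_random_synthetic(tmp_path):
    bench = generate_benchset(SyntheticSpec(n_species=12, n_processes=25, seed=3))
    write_benchset(bench, tmp_path / "sp.csv", tmp_path / "pr.csv")
    loaded = load_benchset(tmp_path / "sp.csv", tmp_path / "pr.csv")
    # Lossless at 12 significant digits: a second write/load cycle is exact.
    write_benchset(loaded, tmp_path / "sp2.csv", tmp_path / "pr2.csv")
    again = load_benchset(tmp_path / "sp2.csv", tmp_path / "pr2.csv")
    assert again == loaded
    assert [p.subset for p in loaded.processes] == [p.subset for p in bench.processes]
    assert [p.id for p in loaded.processes] == [p.id for p in bench.processes]
    for p_orig, p_back in zip(bench.processes, loaded.processes):
        assert p_back.ref_energy == pytest.approx(p_orig.ref_energy, rel=1e-11)


def test_load_unknown_species_names_it(tmp_path, unit_component_benchset):
    write_benchset(unit_component_benchset, tmp_path / "sp.csv", tmp_path / "pr.csv")
    text = (tmp_path / "pr.csv").read_text().replace("X:1", "Qz:1")
    (tmp_path / "pr.csv").write_text(text)
    with pytest.raises(SchemaError, match="Qz"):
        load_benchset(tmp_path / "sp.csv", tmp_path / "pr.csv")


def test_load_missing_column(tmp_path, unit_component_benchset):
    write_benchset(unit_component_benchset, tmp_path / "sp.csv", tmp_path / "pr.csv")
    lines = (tmp_path / "sp.csv").read_text().splitlines()
    trimmed = "\n".join(",".join(l.split(",")[:-1]) for l in lines)
    (tmp_path / "sp.csv").write_text(trimmed)
    with pytest.raises(SchemaError, match="c7"):
        load_benchset(tmp_path / "sp.csv", tmp_path / "pr.csv")


def test_write_empty_benchset_rejected(tmp_path, unit_component_benchset):
    b = unit_component_benchset
    b.processes = []
    with pytest.raises(SchemaError):
        write_benchset(b, tmp_path / "sp.csv", tmp_path / "pr.csv")


def test_unique_elements_examples():
    water = make_species("H2O", [0.0] * 7, elements=("H", "H", "O"))
    proc = Process(id="p", stoichiometry=[("H2O", 1.0)], ref_energy=0.0, subset="s")
    b = make_benchset("w", [water], [proc])
    assert unique_elements(b) == {"H", "O"}

    ch4 = make_species("CH4", [0.0] * 7, elements=("C", "H"))
    feo = make_species("FeO", [0.0] * 7, elements=("Fe", "O"))
    procs = [
        Process(id="p1", stoichiometry=[("CH4", 1.0)], ref_energy=0.0, subset="s"),
        Process(id="p2", stoichiometry=[("FeO", -1.0)], ref_energy=0.0, subset="s"),
    ]
    b2 = make_benchset("two", [ch4, feo], procs)
    assert unique_elements(b2) == {"C", "H", "Fe", "O"}


def test_unique_elements_monotone_and_order_invariant():
    bench = generate_benchset(SyntheticSpec(n_species=15, n_processes=30, seed=5))
    full = unique_elements(bench)
    rng = np.random.default_rng(0)
    for _ in range(5):
        idx = sorted(rng.choice(len(bench.processes), size=10, replace=False))
        assert unique_elements(bench.restrict(idx)) <= full
    shuffled = bench.restrict(list(rng.permutation(len(bench.processes))))
    assert unique_elements(shuffled) == full
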