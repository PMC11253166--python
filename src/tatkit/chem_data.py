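"""Data model and file I/O for species, processes, and benchmark sets.

A benchmark set ("benchset") is a collection of chemical processes — reactions,
barriers, ionisation potentials and the like — each defined by a stoichiometric
combination of species and a reference energy.  Every species carries a vector
of seven precomputed energy components (in hartree) which a linear
density-functional approximation combines; the reference energies and all
derived error metrics live in kcal/mol.

On disk a benchset is a pair of CSV files:

* ``species.csv`` — columns ``id, formula, c1..c7``; components in hartree;
  ``formula`` is a Hill-order composition string such as ``C2H6O``.
* ``processes.csv`` — columns ``id, benchset, subset, stoichiometry,
  ref_kcal``; the stoichiometry is a semicolon-joined list of
  ``species_id:coefficient`` terms.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

#: kcal/mol per hartree (CODATA-derived).
HARTREE_TO_KCAL = 627.509474

#: Number of energy components in the linear model.
N_COMPONENTS = 7

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class SchemaError(ValueError):
    """A benchset file violates the CSV schema or a data-model invariant."""


def parse_formula(formula: str) -> Counter:
    """Parse a composition string like ``"C2H6O"`` into an element multiset."""
    if not formula or not isinstance(formula, str):
        raise SchemaError(f"empty or non-string formula: {formula!r}")
    pos = 0
    counts: Counter = Counter()
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise SchemaError(f"cannot parse formula {formula!r} at position {pos}")
        if m.group(0) == "":
            break
        counts[m.group(1)] += int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula) or not counts:
        raise SchemaError(f"cannot parse formula {formula!r}")
    return counts


def format_formula(elements: Counter) -> str:
    """Render an element multiset as a Hill-order formula string."""
    symbols = sorted(elements)
    if "C" in elements:
        symbols = ["C"] + (["H"] if "H" in elements else [])
        symbols += sorted(s for s in elements if s not in ("C", "H"))
    parts = []
    for s in symbols:
        n = elements[s]
        parts.append(s if n == 1 else f"{s}{n}")
    return "".join(parts)


@dataclass(frozen=True)
class Species:
    """A chemical species: an element multiset plus seven energy components."""

    id: str
    elements: Counter
    components: tuple  # 7 floats, hartree

    def __post_init__(self):
        if not self.elements:
            raise SchemaError(f"species {self.id!r}: empty element composition")
        comp = tuple(float(c) for c in self.components)
        if len(comp) != N_COMPONENTS:
            raise SchemaError(
                f"species {self.id!r}: expected {N_COMPONENTS} components, got {len(comp)}"
            )
        if not all(c == c and abs(c) != float("inf") for c in comp):
            raise SchemaError(f"species {self.id!r}: non-finite component")
        object.__setattr__(self, "components", comp)


@dataclass(frozen=True)
class Process:
    """A stoichiometric combination of species with a reference energy.

    ``stoichiometry`` is a tuple of ``(species_id, coefficient)`` pairs;
    positive coefficients are products, negative are reactants.  The reference
    energy is in kcal/mol.  ``subset`` labels the chemistry category the
    process belongs to.
    """

    id: str
    stoichiometry: tuple  # ((species_id, coeff), ...)
    ref_energy: float
    subset: str

    def __post_init__(self):
        stoich = tuple((str(s), float(c)) for s, c in self.stoichiometry)
        if len(stoich) < 1:
            raise SchemaError(f"process {self.id!r}: empty stoichiometry")
        if any(c == 0.0 for _, c in stoich):
            raise SchemaError(f"process {self.id!r}: zero stoichiometric coefficient")
        object.__setattr__(self, "stoichiometry", stoich)
        object.__setattr__(self, "ref_energy", float(self.ref_energy))


@dataclass
class Benchset:
    """An ordered collection of processes plus the species they reference."""

    name: str
    processes: list = field(default_factory=list)
    species_table: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.processes:
            raise SchemaError(f"benchset {self.name!r}: no processes")
        seen = set()
        for proc in self.processes:
            if proc.id in seen:
                raise SchemaError(f"benchset {self.name!r}: duplicate process id {proc.id!r}")
            seen.add(proc.id)
            for sid, _ in proc.stoichiometry:
                if sid not in self.species_table:
                    raise SchemaError(
                        f"benchset {self.name!r}: process {proc.id!r} references "
                        f"unknown species {sid!r}"
                    )

    def __len__(self) -> int:
        return len(self.processes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Benchset):
            return NotImplemented
        return (
            self.name == other.name
            and self.processes == other.processes
            and self.species_table == other.species_table
        )

    @property
    def subsets(self) -> list:
        """Subset labels in first-appearance order."""
        out = []
        for p in self.processes:
            if p.subset not in out:
                out.append(p.subset)
        return out

    def restrict(self, indices, name: str | None = None) -> "Benchset":
        """A new benchset containing the processes at ``indices`` (in order)."""
        procs = [self.processes[i] for i in indices]
        species = {
            sid: self.species_table[sid]
            for p in procs
            for sid, _ in p.stoichiometry
        }
        return Benchset(name or f"{self.name}[{len(procs)}]", procs, species)

    def by_subset(self, label: str, name: str | None = None) -> "Benchset":
        idx = [i for i, p in enumerate(self.processes) if p.subset == label]
        if not idx:
            raise SchemaError(f"benchset {self.name!r}: no processes with subset {label!r}")
        return self.restrict(idx, name or label)


def unique_elements(b: Benchset) -> set:
    """Union of element sets over all species appearing in any process of ``b``."""
    out: set = set()
    for proc in b.processes:
        for sid, _ in proc.stoichiometry:
            out |= set(b.species_table[sid].elements)
    return out


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def load_benchset(species_path, processes_path, name: str | None = None) -> Benchset:
    """Load and validate a benchset from its two CSV files.

    Row order is preserved.  Raises :class:`SchemaError` naming the offending
    row on any malformed or unresolvable entry.
    """
    comp_cols = [f"c{i}" for i in range(1, N_COMPONENTS + 1)]
    sp_df = pd.read_csv(species_path, dtype={"id": str, "formula": str})
    _require_columns(sp_df, ["id", "formula", *comp_cols], species_path)
    species_table = {}
    for row_no, row in enumerate(sp_df.itertuples(index=False), start=2):
        try:
            comps = [float(getattr(row, c)) for c in comp_cols]
        except (TypeError, ValueError) as exc:
            raise SchemaError(
                f"{species_path}: row {row_no}: non-numeric component ({exc})"
            ) from exc
        try:
            sp = Species(id=str(row.id), elements=parse_formula(row.formula), components=comps)
        except SchemaError as exc:
            raise SchemaError(f"{species_path}: row {row_no}: {exc}") from exc
        if sp.id in species_table:
            raise SchemaError(f"{species_path}: row {row_no}: duplicate species id {sp.id!r}")
        species_table[sp.id] = sp

    pr_df = pd.read_csv(
        processes_path, dtype={"id": str, "benchset": str, "subset": str, "stoichiometry": str}
    )
    _require_columns(pr_df, ["id", "benchset", "subset", "stoichiometry", "ref_kcal"], processes_path)
    processes = []
    set_names = set()
    for row_no, row in enumerate(pr_df.itertuples(index=False), start=2):
        terms = []
        for term in str(row.stoichiometry).split(";"):
            term = term.strip()
            if not term:
                continue
            sid, _, coeff = term.rpartition(":")
            if not sid:
                raise SchemaError(
                    f"{processes_path}: row {row_no}: malformed stoichiometry term {term!r}"
                )
            try:
                terms.append((sid, float(coeff)))
            except ValueError as exc:
                raise SchemaError(
                    f"{processes_path}: row {row_no}: non-numeric coefficient in {term!r}"
                ) from exc
        unknown = sorted({sid for sid, _ in terms if sid not in species_table})
        if unknown:
            raise SchemaError(
                f"{processes_path}: row {row_no}: unknown species {', '.join(unknown)}"
            )
        try:
            ref = float(row.ref_kcal)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{processes_path}: row {row_no}: non-numeric ref_kcal") from exc
        processes.append(
            Process(id=str(row.id), stoichiometry=terms, ref_energy=ref, subset=str(row.subset))
        )
        set_names.add(str(row.benchset))

    if name is None:
        name = set_names.pop() if len(set_names) == 1 else "benchset"
    return Benchset(name=name, processes=processes, species_table=species_table)


def write_benchset(b: Benchset, species_path, processes_path) -> None:
    """Write a benchset to its two CSV files, re-loadable to an equal value.

    Floats are written at 12 significant digits, so the load/write round trip
    is lossless for values representable at that precision.
    """
    b.validate()
    comp_cols = [f"c{i}" for i in range(1, N_COMPONENTS + 1)]
    sp_rows = [
        {
            "id": sp.id,
            "formula": format_formula(sp.elements),
            **{c: f"{v:.12g}" for c, v in zip(comp_cols, sp.components)},
        }
        for sp in b.species_table.values()
    ]
    pd.DataFrame(sp_rows, columns=["id", "formula", *comp_cols]).to_csv(species_path, index=False)

    pr_rows = [
        {
            "id": p.id,
            "benchset": b.name,
            "subset": p.subset,
            "stoichiometry": ";".join(f"{sid}:{coeff:.12g}" for sid, coeff in p.stoichiometry),
            "ref_kcal": f"{p.ref_energy:.12g}",
        }
        for p in b.processes
    ]
    pd.DataFrame(
        pr_rows, columns=["id", "benchset", "subset", "stoichiometry", "ref_kcal"]
    ).to_csv(processes_path, index=False)
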