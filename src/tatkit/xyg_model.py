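"""The seven-component linear DFA family and its nested parameterizations.

The model energy of a species is a linear combination ``sum_i a_i * c_i`` of
seven precomputed energy components: HF (exact) exchange, an auxiliary
exchange slot, (m)GGA exchange, an auxiliary correlation slot, (m)GGA
correlation, and the same-spin and opposite-spin MP2 correlation energies.
A family member with ``p`` free parameters (p = 1..7) is obtained by tying or
zeroing components of the coefficient vector ``a`` according to fixed
reduction rules, so the p-parameter families are nested: every model
expressible at ``p`` is also expressible at ``p + 1``.

Because the model is linear in ``a``, the predicted energy of a chemical
process reduces to a dot product ``a . d`` with a per-process design row
``d = K * sum_j nu_j c_j`` (``K`` the hartree→kcal/mol conversion), which this
module assembles into an ordinary design matrix.
"""

from __future__ import annotations

import numpy as np

from .chem_data import HARTREE_TO_KCAL, N_COMPONENTS, Benchset

#: Human-readable labels for the seven coefficient slots.
COMPONENT_LABELS = (
    "HF exchange",
    "auxiliary exchange",
    "(m)GGA exchange",
    "auxiliary correlation",
    "(m)GGA correlation",
    "same-spin MP2",
    "opposite-spin MP2",
)

#: Free-parameter names, in order, for each p.
FREE_PARAM_NAMES = {
    1: ("alpha",),
    2: ("alpha", "beta"),
    3: ("a1", "a3", "a6"),
    4: ("a1", "a2", "a3", "a6"),
    5: ("a1", "a2", "a3", "a5", "a6"),
    6: ("a1", "a2", "a3", "a4", "a5", "a6"),
    7: ("a1", "a2", "a3", "a4", "a5", "a6", "a7"),
}


def _check_p(p: int) -> None:
    if not (isinstance(p, (int, np.integer)) and 1 <= p <= 7):
        raise ValueError(f"p must be an integer in 1..7, got {p!r}")


def expand_params(p: int, values) -> np.ndarray:
    """Expand ``p`` free parameters into the full 7-component vector.

    Reduction rules:

    * p=1 (exact-exchange fraction α): a = (α, 0, 1−α, 0, 1−α², α², α²)
    * p=2 (α and MP2 fraction β):      a = (α, 0, 1−α, 0, 1−β, β, β)
    * p=3 (a1, a3, a6): a2 = a4 = 0, a5 = 1 − a6, a7 = a6
    * p=4 (a1, a2, a3, a6): a4 = 0, a5 = 1 − a6, a7 = a6
    * p=5 (all but a4, a7): a4 = 0, a7 = a6
    * p=6 (all but a7): a7 = a6
    * p=7: identity
    """
    _check_p(p)
    v = np.asarray(values, dtype=float).ravel()
    if v.size != p:
        raise ValueError(f"expected {p} free parameters, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValueError("free parameters must be finite")
    if p == 1:
        (alpha,) = v
        return np.array([alpha, 0.0, 1 - alpha, 0.0, 1 - alpha**2, alpha**2, alpha**2])
    M, b = affine_expansion(p)
    return M @ v + b


def affine_expansion(p: int):
    """Matrix/offset ``(M, b)`` with ``a = M @ free + b`` for p = 2..7.

    The p=1 rule is quadratic in α and has no affine expansion.
    """
    _check_p(p)
    if p == 1:
        raise ValueError("p=1 expansion is quadratic, not affine")
    M = np.zeros((N_COMPONENTS, p))
    b = np.zeros(N_COMPONENTS)
    if p == 2:  # free: alpha, beta
        M[0, 0] = 1.0
        M[2, 0] = -1.0
        b[2] = 1.0
        M[4, 1] = -1.0
        b[4] = 1.0
        M[5, 1] = M[6, 1] = 1.0
        return M, b
    # For p >= 3 the free parameters are a subset of the a_i themselves.
    slots = {3: (0, 2, 5), 4: (0, 1, 2, 5), 5: (0, 1, 2, 4, 5), 6: (0, 1, 2, 3, 4, 5), 7: tuple(range(7))}[p]
    for k, slot in enumerate(slots):
        M[slot, k] = 1.0
    if p in (3, 4):  # a5 = 1 - a6
        i6 = slots.index(5)
        M[4, i6] = -1.0
        b[4] = 1.0
    if p <= 6:  # a7 = a6
        M[6, slots.index(5)] = 1.0
    return M, b


def lift_params(p: int, values) -> np.ndarray:
    """Map free parameters at ``p`` to equivalent free parameters at ``p + 1``.

    Witnesses the nesting of the family; the p=1→2 lift uses β = α².
    """
    _check_p(p)
    if p == 7:
        raise ValueError("p=7 has no parent parameterization")
    v = np.asarray(values, dtype=float).ravel()
    if p == 1:
        return np.array([v[0], v[0] ** 2])
    a = expand_params(p, v)
    slots = {2: (0, 2, 5), 3: (0, 1, 2, 5), 4: (0, 1, 2, 4, 5), 5: (0, 1, 2, 3, 4, 5), 6: tuple(range(7))}[p]
    return a[list(slots)]


def design_matrix(b: Benchset) -> np.ndarray:
    """Design matrix ``D`` (n_processes × 7), in kcal/mol per unit coefficient.

    Row ``j`` satisfies ``a @ D[j] == model ΔE of process j`` for every
    coefficient vector ``a``.
    """
    rows = np.zeros((len(b.processes), N_COMPONENTS))
    for j, proc in enumerate(b.processes):
        for sid, coeff in proc.stoichiometry:
            rows[j] += coeff * np.asarray(b.species_table[sid].components)
    return rows * HARTREE_TO_KCAL


def reference_energies(b: Benchset) -> np.ndarray:
    """Reference energies of the processes of ``b``, in kcal/mol, in order."""
    return np.array([p.ref_energy for p in b.processes], dtype=float)


def predict(a, b: Benchset) -> np.ndarray:
    """Model energies (kcal/mol) of every process of ``b`` under coefficients ``a``."""
    a = np.asarray(a, dtype=float).ravel()
    if a.size != N_COMPONENTS:
        raise ValueError(f"expected {N_COMPONENTS} coefficients, got {a.size}")
    if not np.all(np.isfinite(a)):
        raise ValueError("coefficients must be finite")
    return design_matrix(b) @ a
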