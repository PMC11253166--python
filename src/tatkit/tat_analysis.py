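"""Transferability matrices, transfer-energy matrices and error summaries.

Given a collection of benchsets, each set is used once as a training set
(column) and once as a test set (row): entry (B, A) holds MAD_B@A, the error
on B of the model trained on A, and the derived transferability ratio
T_B@A = (MAD_B@A + eta) / (MAD_B@B + eta).  Columns are training sets and rows
are test sets throughout; headers state this to prevent transposition bugs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_data import Benchset
from .fitting import FitOptions, FitResult, cross_mad, fit
from .metrics import DEFAULT_ETA, classify_errors, delta_mad, mad, transferability
from .xyg_model import design_matrix, reference_energies


@dataclass
class TMatrix:
    """Cross-set MAD and transferability grids (row = test B, col = train A)."""

    sets: list
    mad: np.ndarray
    t: np.ndarray
    p: int
    eta: float = DEFAULT_ETA
    fits: dict = field(default_factory=dict)

    def to_frame(self, which: str = "t") -> pd.DataFrame:
        data = {"t": self.t, "mad": self.mad}[which]
        df = pd.DataFrame(data, index=self.sets, columns=self.sets)
        df.index.name = "test_set (rows) \\ train_set (cols)"
        return df

    def offdiagonal(self, which: str = "t") -> np.ndarray:
        data = {"t": self.t, "mad": self.mad}[which]
        n = len(self.sets)
        mask = ~np.eye(n, dtype=bool)
        return data[mask]


@dataclass
class ErrorSummary:
    set_name: str
    frac_good: float
    frac_ok: float
    frac_bad: float


def _fit_all(sets, p, opts, cache=True):
    """Fit each set once; caching changes cost only, never values."""
    fits = {}
    for s in sets:
        try:
            fits[s.name] = fit(s, p, opts)
        except Exception as exc:
            raise RuntimeError(f"fit failed for set {s.name!r}: {exc}") from exc
        if not cache:
            # Recompute to demonstrate transparency; result must be identical.
            fits[s.name] = fit(s, p, opts)
    return fits


def tat_matrix(sets, p: int, opts: FitOptions | None = None,
               eta: float = DEFAULT_ETA, cache: bool = True) -> TMatrix:
    """Transferability matrix over a collection of benchsets at a given p.

    Each set is fitted once (training column); every (test, train) pair is
    scored by the cross MAD and the regularized ratio.  Row/column order
    follows the input order.
    """
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("at least two benchsets are required")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError(f"benchset names must be unique, got {names}")

    opts = opts or FitOptions()
    fits = _fit_all(sets, p, opts, cache=cache)
    n = len(sets)
    mads = np.zeros((n, n))
    tvals = np.zeros((n, n))
    for col, train in enumerate(sets):
        f = fits[train.name]
        for row, test in enumerate(sets):
            mads[row, col] = cross_mad(f, test)
    for row in range(n):
        for col in range(n):
            tvals[row, col] = transferability(mads[row, col], mads[row, row], eta).t
    return TMatrix(sets=names, mad=mads, t=tvals, p=p, eta=eta, fits=fits)


def transfer_energy_matrix(sets, p: int, opts: FitOptions | None = None,
                           tm: TMatrix | None = None) -> np.ndarray:
    """Matrix of transfer energies ΔMAD_B@A = MAD_B@A − MAD_B@B.

    Diagonal is exactly zero; entries are >= 0 whenever the training fits are
    global optima.
    """
    import warnings

    from .metrics import NonGlobalOptimumWarning

    if tm is None:
        tm = tat_matrix(sets, p, opts)
    n = len(tm.sets)
    out = np.zeros((n, n))
    for row in range(n):
        for col in range(n):
            if row == col:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", NonGlobalOptimumWarning)
                out[row, col] = delta_mad(tm.mad[row, col], tm.mad[row, row]).delta
    return out


def accuracy_limit(b: Benchset, p: int, opts: FitOptions | None = None) -> float:
    """MAD_A@A at parameter count p — the family's best possible error on A."""
    return fit(b, p, opts).mad


def error_summary(fit_result: FitResult, b: Benchset) -> ErrorSummary:
    """Good/ok/bad error-class fractions of a fitted model applied to ``b``."""
    errors = np.abs(design_matrix(b) @ fit_result.a - reference_energies(b))
    good, ok, bad = classify_errors(errors)
    return ErrorSummary(set_name=b.name, frac_good=good, frac_ok=ok, frac_bad=bad)


def write_matrix_csv(tm: TMatrix, path, which: str = "t") -> None:
    """CSV report at 6 significant digits (full precision goes to JSON)."""
    df = tm.to_frame(which)
    df.map(lambda x: float(f"{x:.6g}")).to_csv(path)


def write_matrix_json(tm: TMatrix, path) -> None:
    payload = {
        "orientation": "rows are test sets, columns are training sets",
        "sets": tm.sets,
        "p": tm.p,
        "eta": tm.eta,
        "mad": tm.mad.tolist(),
        "t": tm.t.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
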