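"""Error metrics and transferability quantities.

The central quantity is the two-set error MAD_B@A — the mean absolute
deviation on a test set B of a model whose parameters minimize the MAD on a
training set A.  The transferability matrix element

    T_B@A = (MAD_B@A + eta) / (MAD_B@B + eta),   eta = 0.01 kcal/mol,

normalizes that cross error by the family's accuracy limit on B; eta
regularizes the ratio when both errors are small.  T_B@B = 1 by construction,
and T_B@A >= 1 whenever the training optimum is global.  The transfer energy
ΔMAD_B@A = MAD_B@A − MAD_B@B is the energy cost of training on the "wrong"
set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Default regularizer for the transferability ratio, kcal/mol.
DEFAULT_ETA = 0.01

#: Error-class boundaries (kcal/mol): good < 1 <= ok <= 7 < bad.
GOOD_MAX = 1.0
OK_MAX = 7.0


class NonGlobalOptimumWarning(UserWarning):
    """A negative ΔMAD — the training optimum was not global."""


@dataclass(frozen=True)
class TransferabilityEntry:
    mad_ba: float
    mad_bb: float
    eta: float
    t: float


@dataclass(frozen=True)
class TransferEnergy:
    delta: float


def mad(pred, ref) -> float:
    """Mean absolute deviation between predictions and references (kcal/mol)."""
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.size != ref.size:
        raise ValueError(f"length mismatch: {pred.size} vs {ref.size}")
    if pred.size == 0:
        raise ValueError("mad of empty vectors is undefined")
    return float(np.mean(np.abs(pred - ref)))


def weighted_mad(pred, ref, weights) -> float:
    """Weighted mean absolute deviation ``sum w|e| / sum w``.

    A generic hook for weighted metrics (such as the weighted-MAD schemes used
    to balance weak and strong interactions); the weights are caller-supplied.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if not (pred.size == ref.size == w.size):
        raise ValueError("pred, ref and weights must have equal length")
    if pred.size == 0:
        raise ValueError("weighted_mad of empty vectors is undefined")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("weights must not all be zero")
    return float(np.sum(w * np.abs(pred - ref)) / total)


def transferability(mad_ba: float, mad_bb: float, eta: float = DEFAULT_ETA) -> TransferabilityEntry:
    """The regularized ratio T_B@A = (MAD_B@A + eta) / (MAD_B@B + eta)."""
    if mad_ba < 0 or mad_bb < 0:
        raise ValueError("MAD inputs must be non-negative")
    if eta <= 0:
        raise ValueError("eta must be positive")
    t = (mad_ba + eta) / (mad_bb + eta)
    return TransferabilityEntry(mad_ba=mad_ba, mad_bb=mad_bb, eta=eta, t=t)


def delta_mad(mad_ba: float, mad_bb: float) -> TransferEnergy:
    """Transfer energy ΔMAD_B@A = MAD_B@A − MAD_B@B.

    Negative values are not clamped: they indicate that the training MAD was
    not a global optimum, and a :class:`NonGlobalOptimumWarning` is emitted.
    """
    if mad_ba < 0 or mad_bb < 0:
        raise ValueError("MAD inputs must be non-negative")
    delta = mad_ba - mad_bb
    if delta < 0:
        warnings.warn(
            f"negative transfer energy ({delta:.6g} kcal/mol): training optimum "
            "appears non-global",
            NonGlobalOptimumWarning,
            stacklevel=2,
        )
    return TransferEnergy(delta=delta)


def classify_errors(abs_errors) -> tuple:
    """Fractions of processes with good (<1), ok ([1, 7]) and bad (>7) errors.

    Bin edges are in kcal/mol; both boundaries belong to the "ok" class.
    """
    e = np.asarray(abs_errors, dtype=float).ravel()
    if e.size == 0:
        raise ValueError("classify_errors of empty input is undefined")
    if np.any(e < 0):
        raise ValueError("absolute errors must be non-negative")
    n = e.size
    good = float(np.count_nonzero(e < GOOD_MAX)) / n
    bad = float(np.count_nonzero(e > OK_MAX)) / n
    return (good, 1.0 - good - bad, bad)
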