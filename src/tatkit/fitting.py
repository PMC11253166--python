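"""Training of the linear DFA family by mean-absolute-deviation minimization.

Because the model energy is linear in the coefficient vector and every p >= 2
parameterization is affine in its free parameters, minimizing the MAD is a
least-absolute-deviations problem and is solved *exactly* as a linear program
(auxiliary residual-bound variables, HiGHS).  That exactness is what makes the
transferability inequality T_B@A >= 1 provable rather than empirical.  The
one-parameter family is quadratic in the exchange fraction and is handled by a
dense scan refined by bounded scalar minimization.

LAD optima can be non-unique when the error landscape is flat along some
parameter direction; for determinism the free-parameter vector of minimal
Euclidean norm within the optimal face is selected (a quadratic refinement,
falling back to the raw LP vertex if it fails).

The core is the scikit-learn style estimator :class:`XygRegressor`; the
module-level :func:`fit`, :func:`grid_oracle` and :func:`cross_mad` operate on
benchsets and wrap it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .chem_data import Benchset, N_COMPONENTS
from .metrics import mad as _mad
from .xyg_model import affine_expansion, design_matrix, expand_params, reference_energies

_BOUND_ATOL = 1e-7  # how close a free parameter must be to the box to count as active


@dataclass
class FitOptions:
    """Options controlling the MAD minimization.

    box
        Bounds applied to every free parameter; generous by default since MP2
        fractions above 1 are legitimate.
    p1_range, p1_grid_step
        Scan window and step for the one-parameter exchange-fraction model.
    tolerance
        Optimality slack (kcal/mol) allowed to the min-norm refinement.
    """

    box: tuple = (-3.0, 3.0)
    p1_range: tuple = (-0.5, 1.5)
    p1_grid_step: float = 1e-3
    tolerance: float = 1e-8
    refine_min_norm: bool = True
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.box
        if not (lo < hi):
            raise ValueError("box must be a non-degenerate (lo, hi) interval")
        if self.p1_grid_step <= 0:
            raise ValueError("p1_grid_step must be positive")


@dataclass
class FitResult:
    """Optimal parameters and training MAD for a benchset at a given p."""

    p: int
    free: np.ndarray
    a: np.ndarray
    mad: float
    status: str  # global | bounded | underdetermined
    diagnostics: dict = field(default_factory=dict)


class XygRegressor(RegressorMixin, BaseEstimator):
    """Least-absolute-deviations regression over the nested 7-component family.

    Parameters
    ----------
    p : int, default 7
        Number of free parameters (1..7); smaller p constrains the coefficient
        vector by the family's reduction rules.
    box : (float, float)
        Bounds on each free parameter.
    p1_range, p1_grid_step : scan window / step for p=1.
    tol : float
        Optimality slack (kcal/mol) for the minimal-norm refinement.
    refine_min_norm : bool
        Break LAD ties by minimal Euclidean norm of the free parameters.

    Attributes
    ----------
    free_params_ : ndarray of shape (p,)
    coef_ : ndarray of shape (7,)
        Expanded coefficient vector.
    mad_ : float
        Training mean absolute deviation, kcal/mol.
    status_ : str
        ``"global"`` (LP optimum, no box bound active), ``"bounded"`` (a box
        bound is active), or ``"underdetermined"`` (design rank below p).
    """

    def __init__(self, p=7, box=(-3.0, 3.0), p1_range=(-0.5, 1.5),
                 p1_grid_step=1e-3, tol=1e-8, refine_min_norm=True):
        self.p = p
        self.box = box
        self.p1_range = p1_range
        self.p1_grid_step = p1_grid_step
        self.tol = tol
        self.refine_min_norm = refine_min_norm

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != N_COMPONENTS:
            raise ValueError(f"X must be (n_processes, {N_COMPONENTS})")
        if X.shape[0] != y.size:
            raise ValueError("X and y have inconsistent lengths")
        if X.shape[0] < 1:
            raise ValueError("at least one process is required")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite")
        if not (isinstance(self.p, (int, np.integer)) and 1 <= self.p <= 7):
            raise ValueError(f"p must be in 1..7, got {self.p!r}")

        self.n_features_in_ = N_COMPONENTS
        if self.p == 1:
            free, best_mad, diag = self._fit_p1(X, y)
            status = "global"
        else:
            free, best_mad, status, diag = self._fit_lp(X, y)
        self.free_params_ = free
        self.coef_ = expand_params(self.p, free)
        self.mad_ = best_mad
        self.status_ = status
        self.diagnostics_ = diag
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_

    # --------------------------------------------------------------- internals
    def _mad_of_alpha(self, alpha, X, y):
        return float(np.mean(np.abs(X @ expand_params(1, [alpha]) - y)))

    def _fit_p1(self, X, y):
        lo, hi = self.p1_range
        grid = np.arange(lo, hi + 0.5 * self.p1_grid_step, self.p1_grid_step)
        vals = np.abs(
            np.outer(grid, X[:, 0] - X[:, 2])
            + np.outer(grid**2, -X[:, 4] + X[:, 5] + X[:, 6])
            + (X[:, 2] + X[:, 4])[None, :]
            - y[None, :]
        ).mean(axis=1)
        k = int(np.argmin(vals))
        blo = grid[max(k - 1, 0)]
        bhi = grid[min(k + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            self._mad_of_alpha, bounds=(blo, bhi), args=(X, y),
            method="bounded", options={"xatol": 1e-12},
        )
        if res.fun <= vals[k]:
            alpha, best = float(res.x), float(res.fun)
        else:  # pragma: no cover - refinement can never be worse in practice
            alpha, best = float(grid[k]), float(vals[k])
        return np.array([alpha]), best, {"grid_points": grid.size}

    def _fit_lp(self, X, y):
        p = self.p
        n = X.shape[0]
        M, b = affine_expansion(p)
        Xm = X @ M  # (n, p) effective design in free parameters
        c0 = X @ b - y  # residual offset
        rank = int(np.linalg.matrix_rank(Xm))

        lo, hi = self.box
        c = np.concatenate([np.zeros(p), np.full(n, 1.0 / n)])
        A_ub = np.block([
            [Xm, -np.eye(n)],
            [-Xm, -np.eye(n)],
        ])
        b_ub = np.concatenate([-c0, c0])
        bounds = [(lo, hi)] * p + [(0.0, None)] * n
        res = optimize.linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
        if not res.success:  # pragma: no cover - bounded LAD LP is always feasible
            raise RuntimeError(f"LAD linear program failed: {res.message}")
        v = res.x[:p].copy()
        diag = {"lp_status": res.status, "design_rank": rank, "n_processes": n}

        # Rank deficiency guarantees a non-unique optimum; refine there.  At
        # full rank the LP vertex is generically unique and HiGHS is
        # deterministic, so no tie-break is needed.
        if self.refine_min_norm and rank < p:
            v_ref = self._min_norm_refine(Xm, c0, v, res.fun)
            if v_ref is not None:
                v = v_ref
                diag["min_norm_refined"] = True
        best_mad = float(np.mean(np.abs(Xm @ v + c0)))

        if rank < p:
            status = "underdetermined"
            diag["warning"] = "design rank below number of free parameters"
        elif np.any(np.abs(v - lo) < _BOUND_ATOL) or np.any(np.abs(v - hi) < _BOUND_ATOL):
            status = "bounded"
        else:
            status = "global"
        return v, best_mad, status, diag

    def _min_norm_refine(self, Xm, c0, v0, mad0):
        """Minimal-||free||² point of the optimal face, via SLSQP on the
        residual-bound formulation; returns None if refinement fails."""
        p = v0.size
        n = c0.size
        lo, hi = self.box
        cap = n * (mad0 + self.tol)
        s0 = np.abs(Xm @ v0 + c0) + 1e-12
        x0 = np.concatenate([v0, s0])

        def objective(x):
            return float(x[:p] @ x[:p])

        def objective_grad(x):
            g = np.zeros_like(x)
            g[:p] = 2 * x[:p]
            return g

        A1 = np.hstack([Xm, -np.eye(n)])   # r - s <= 0
        A2 = np.hstack([-Xm, -np.eye(n)])  # -r - s <= 0
        A3 = np.concatenate([np.zeros(p), np.ones(n)])[None, :]  # sum s <= cap
        cons = [
            {"type": "ineq", "fun": lambda x: -(A1 @ x) - c0, "jac": lambda x: -A1},
            {"type": "ineq", "fun": lambda x: -(A2 @ x) + c0, "jac": lambda x: -A2},
            {"type": "ineq", "fun": lambda x: cap - (A3 @ x), "jac": lambda x: -A3},
        ]
        bounds = [(lo, hi)] * p + [(0.0, None)] * n
        try:
            res = optimize.minimize(
                objective, x0, jac=objective_grad, bounds=bounds, constraints=cons,
                method="SLSQP", options={"maxiter": 200, "ftol": 1e-14},
            )
        except Exception:  # pragma: no cover
            return None
        if not res.success:
            return None
        v = res.x[:p]
        new_mad = float(np.mean(np.abs(Xm @ v + c0)))
        if new_mad > mad0 + 2 * self.tol or v @ v > v0 @ v0 + 1e-12:
            return None
        return v


def _result_from_estimator(est: XygRegressor) -> FitResult:
    return FitResult(
        p=est.p, free=est.free_params_, a=est.coef_,
        mad=est.mad_, status=est.status_, diagnostics=dict(est.diagnostics_),
    )


def fit(b: Benchset, p: int, opts: FitOptions | None = None) -> FitResult:
    """Minimize the MAD of the p-parameter model over benchset ``b``."""
    opts = opts or FitOptions()
    est = XygRegressor(
        p=p, box=opts.box, p1_range=opts.p1_range, p1_grid_step=opts.p1_grid_step,
        tol=opts.tolerance, refine_min_norm=opts.refine_min_norm,
    )
    est.fit(design_matrix(b), reference_energies(b))
    return _result_from_estimator(est)


def cross_mad(train_fit: FitResult, test: Benchset) -> float:
    """MAD_B@A: error on ``test`` of the model trained elsewhere."""
    return _mad(design_matrix(test) @ train_fit.a, reference_energies(test))


def grid_oracle(b: Benchset, p: int, grid) -> FitResult:
    """Exhaustive-enumeration reference for :func:`fit`.

    ``grid`` is a sequence of ``p`` one-dimensional arrays (one per free
    parameter); every combination is evaluated directly.  Intended as an
    independent verification oracle at small scale, limited to 1e7 points.
    """
    if not (1 <= p <= 7):
        raise ValueError(f"p must be in 1..7, got {p!r}")
    axes = [np.asarray(g, dtype=float).ravel() for g in grid]
    if len(axes) != p:
        raise ValueError(f"expected {p} grid axes, got {len(axes)}")
    total = int(np.prod([a.size for a in axes]))
    if total > 10**7:
        raise ValueError(f"grid too large: {total} points")

    X = design_matrix(b)
    y = reference_energies(b)
    best_mad = np.inf
    best_free = None
    # Chunked evaluation keeps memory bounded for big grids.
    chunk = max(1, 10**6 // max(len(b.processes), 1))
    combos = itertools.product(*axes)
    while True:
        block = list(itertools.islice(combos, chunk))
        if not block:
            break
        V = np.array(block)  # (g, p)
        A = np.array([expand_params(p, v) for v in V])  # (g, 7)
        mads = np.abs(A @ X.T - y[None, :]).mean(axis=1)
        k = int(np.argmin(mads))
        if mads[k] < best_mad:
            best_mad = float(mads[k])
            best_free = V[k]
    a = expand_params(p, best_free)
    return FitResult(p=p, free=np.asarray(best_free), a=a, mad=best_mad,
                     status="global", diagnostics={"grid_points": total})
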