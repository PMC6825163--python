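"""Coefficient identification by constrained linear least squares.

Every supported model is linear in its coefficients, so the fit is a
convex inequality-constrained linear least-squares problem.  It is solved
deterministically: the unconstrained solution is accepted when feasible,
otherwise the exact optimum is found by enumerating active sets of the
(at most five) linear constraints and solving the corresponding KKT
systems.  No random initialization is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .constitutive import (
    STABILITY_ROWS,
    CoefficientSet,
    Model,
)
from .errors import DomainError, InfeasibleError, UndefinedNormalizationError, ValidationError
from .io_tensile import TensileCurve

__all__ = ["FitOptions", "FitResult", "design_matrix", "fit_model", "nrmse"]


@dataclass(frozen=True)
class FitOptions:
    """Which physical constraints to enforce during fitting."""

    enforce_stability: bool = True
    enforce_linear_part: bool = True
    tolerance: float = 1e-10  # solver convergence / rank tolerance
    constraint_tol: float = 1e-8  # MPa; satisfaction margin at the optimum

    def __post_init__(self):
        if not self.tolerance > 0:
            raise ValidationError("tolerance must be > 0", fields=["tolerance"])


@dataclass(frozen=True)
class FitResult:
    coefficients: CoefficientSet
    nrmse: float
    active_constraints: tuple[str, ...]
    window: tuple[float, float]
    n_points: int
    residual_ss: float = 0.0


#: rows of the linear-part condition linear_part(C) >= 0 per model
_LINEAR_PART_ROWS = {
    Model.NEO_HOOKEAN: (1.0,),
    Model.YEOH: (1.0, 0.0),
    Model.MR3: (1.0, 0.0, -3.0),
    Model.MR5: (1.0, 0.0, -3.0, -6.0, 4.0),
}


def design_matrix(model: Model, stretches) -> np.ndarray:
    """Matrix whose column j is the stress sensitivity d(sigma)/d(C_j).

    The model stress at any coefficient vector equals the matrix-vector
    product, since every model is linear in its coefficients.
    """
    lam = np.atleast_1d(np.asarray(stretches, dtype=float))
    if np.any(lam <= 0):
        raise DomainError("stretch ratio must be > 0")
    if model is Model.NEO_HOOKEAN:
        cols = [2.0 * (lam - lam**-2)]
    elif model is Model.YEOH:
        cols = [
            2.0 * (lam - lam**-2),
            4.0 * (lam - lam**-2) * (lam**2 + 2.0 / lam - 3.0),
        ]
    else:
        cols = [
            2.0 * (lam - 1.0 / lam),
            2.0 * (1.0 - lam**-3),
            6.0 * (lam**2 - lam - 1.0 + lam**-2 + lam**-3 - lam**-4),
        ]
        if model is Model.MR5:
            cols.append(4.0 * lam * (1.0 - lam**-3) * (lam**2 + 2.0 / lam - 3.0))
            cols.append(4.0 * (2.0 * lam + lam**-2 - 3.0) * (1.0 - lam**-3))
    return np.column_stack(cols)


def constraint_matrix(model: Model, options: FitOptions) -> tuple[np.ndarray, list[str]]:
    """Stack the enabled inequality constraints as rows of G with G @ C >= 0."""
    rows, labels = [], []
    if options.enforce_stability:
        for label, row in STABILITY_ROWS[model]:
            rows.append(row)
            labels.append(f"stability:{label}")
    if options.enforce_linear_part:
        rows.append(_LINEAR_PART_ROWS[model])
        labels.append("linear_part>=0")
    if not rows:
        return np.zeros((0, model.n_coeffs)), []
    return np.asarray(rows, dtype=float), labels


def _kkt_solve(ata2: np.ndarray, atb2: np.ndarray, g_active: np.ndarray) -> np.ndarray:
    n, m = ata2.shape[0], g_active.shape[0]
    kkt = np.zeros((n + m, n + m))
    kkt[:n, :n] = ata2
    kkt[:n, n:] = g_active.T
    kkt[n:, :n] = g_active
    rhs = np.concatenate([atb2, np.zeros(m)])
    sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    return sol[:n]


def fit_model(
    curve: TensileCurve, model: Model, options: FitOptions | None = None
) -> FitResult:
    """Least-squares coefficients of ``model`` on ``curve``.

    Minimizes the sum of squared stress residuals subject to the linear
    inequality constraints selected in ``options`` (stability sign
    conditions and/or non-negative linear energy part).  The strict MR5
    condition C5 < 0 is relaxed to C5 <= 0 so the feasible set is closed;
    an exactly-zero C5 is reported as an active (boundary) constraint.
    """
    options = options or FitOptions()
    if len(curve) < model.n_coeffs + 1:
        raise ValidationError(
            f"need at least {model.n_coeffs + 1} points to fit {model.value}",
            fields=["curve"],
        )
    a = design_matrix(model, curve.stretch)
    b = curve.stress_MPa
    g, labels = constraint_matrix(model, options)

    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    if g.shape[0] and not np.all(g @ x >= -options.constraint_tol):
        x = _constrained_optimum(a, b, g, options)

    coeffs = CoefficientSet(model, tuple(x))
    predicted = a @ x
    residual_ss = float(np.sum((b - predicted) ** 2))
    active = tuple(
        label
        for label, margin in zip(labels, (g @ x) if g.shape[0] else [])
        if margin <= options.constraint_tol
    )
    return FitResult(
        coefficients=coeffs,
        nrmse=nrmse(b, predicted),
        active_constraints=active,
        window=(float(curve.stretch[0]), float(curve.stretch[-1])),
        n_points=len(curve),
        residual_ss=residual_ss,
    )


def _constrained_optimum(
    a: np.ndarray, b: np.ndarray, g: np.ndarray, options: FitOptions
) -> np.ndarray:
    """Exact convex-QP optimum by enumeration of constraint active sets."""
    ata2 = 2.0 * a.T @ a
    atb2 = 2.0 * a.T @ b
    best_x, best_r = None, np.inf
    m = g.shape[0]
    for size in range(1, m + 1):
        for subset in combinations(range(m), size):
            x = _kkt_solve(ata2, atb2, g[list(subset)])
            if np.all(g @ x >= -options.constraint_tol):
                r = float(np.sum((a @ x - b) ** 2))
                if best_x is None or r < best_r - options.tolerance * max(1.0, best_r):
                    best_x, best_r = x, r
    if best_x is None:
        raise InfeasibleError("no feasible solution found for the constraint set")
    return best_x


def nrmse(observed, predicted) -> float:
    """Root-mean-square error normalized by |mean(observed)|."""
    y_e = np.asarray(observed, dtype=float)
    y_m = np.asarray(predicted, dtype=float)
    if y_e.shape != y_m.shape or y_e.size == 0:
        raise ValidationError(
            "observed and predicted must be equal-length, non-empty",
            fields=["observed", "predicted"],
        )
    denom = abs(float(np.mean(y_e)))
    if denom == 0.0:
        raise UndefinedNormalizationError("mean of observed values is zero")
    return float(np.sqrt(np.mean((y_e - y_m) ** 2)) / denom)
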