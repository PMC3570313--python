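"""Penalized B-spline smoothing of the five-point OGTT series.

Each subject's measurements ``y_i(t_j)`` at the canonical minutes are
converted into a smooth curve ``x_i(t) = sum_k c_ki phi_k(t)`` by penalized
least squares::

    minimise  (Y - Phi C)' (Y - Phi C) + lambda * C' R C

where ``Phi`` is the J x K matrix of B-spline basis values at the design
times, ``R = int D2phi(s) D2phi(s)' ds`` penalizes total curvature, and the
smoothing parameter ``lambda`` is selected by generalized cross-validation.
With a knot at each of the five design points and cubic splines this gives
K = 7 basis functions, so a strictly positive penalty is required (K > J).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, optimize
from scipy.interpolate import BSpline

from .io import CANONICAL_TIMES

logger = logging.getLogger("ogttfda")

DEFAULT_ORDER = 4  # cubic
DEFAULT_LAMBDA_GRID = np.logspace(-4.0, 4.0, 25)


@dataclass(frozen=True)
class BasisSystem:
    """B-spline basis on [t_min, t_max] with exact Gram and penalty matrices.

    ``gram[j, k] = int phi_j phi_k dt`` and
    ``penalty[j, k] = int phi_j'' phi_k'' dt``, both computed by per-interval
    Gauss-Legendre quadrature exact for the piecewise-polynomial integrands.
    """

    order: int
    breakpoints: tuple[float, ...]
    knots: np.ndarray
    n_basis: int
    gram: np.ndarray
    penalty: np.ndarray

    @property
    def domain(self) -> tuple[float, float]:
        return self.breakpoints[0], self.breakpoints[-1]

    def design_matrix(self, t: np.ndarray | Sequence[float]) -> np.ndarray:
        """Dense |t| x K matrix of basis values; domain-checked."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.domain
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError(f"evaluation points must lie within [{lo}, {hi}]")
        return BSpline.design_matrix(
            t, self.knots, self.order - 1, extrapolate=False
        ).toarray()

    def derivative_matrix(self, t: np.ndarray, deriv: int = 2) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        eye = np.eye(self.n_basis)
        spl = BSpline(self.knots, eye, self.order - 1, extrapolate=False)
        return spl.derivative(deriv)(t)

    def same_system(self, other: "BasisSystem") -> bool:
        return (
            self.order == other.order
            and self.n_basis == other.n_basis
            and np.array_equal(self.knots, other.knots)
        )


def build_basis(
    breakpoints: Sequence[float] = CANONICAL_TIMES, order: int = DEFAULT_ORDER
) -> BasisSystem:
    """Construct the basis with a knot at each breakpoint.

    Boundary knots are repeated to multiplicity = order, so the number of
    basis functions is K = (# interior breakpoints) + order (K = 7 for the
    default five-point design with cubic splines).
    """
    bp = np.asarray(sorted(breakpoints), dtype=float)
    if bp.size < 2 or np.any(np.diff(bp) <= 0):
        raise ValueError("need >= 2 distinct, increasing breakpoints")
    if order < 2:
        raise ValueError("spline order must be >= 2")
    knots = np.concatenate([np.repeat(bp[0], order), bp[1:-1], np.repeat(bp[-1], order)])
    n_basis = len(bp) - 2 + order

    # Gauss-Legendre per knot interval: basis products have degree
    # 2*(order-1); order+1 nodes integrate degree 2*order+1 exactly.
    nodes, weights = np.polynomial.legendre.leggauss(order + 1)
    gram = np.zeros((n_basis, n_basis))
    penalty = np.zeros((n_basis, n_basis))
    eye = np.eye(n_basis)
    spl = BSpline(knots, eye, order - 1, extrapolate=False)
    d2 = spl.derivative(2) if order >= 3 else None
    for a, b in zip(bp[:-1], bp[1:]):
        x = 0.5 * (b - a) * nodes + 0.5 * (a + b)
        w = 0.5 * (b - a) * weights
        phi = spl(x)  # (nodes, K)
        gram += (phi * w[:, None]).T @ phi
        if d2 is not None:
            p2 = d2(x)
            penalty += (p2 * w[:, None]).T @ p2
    return BasisSystem(
        order=order,
        breakpoints=tuple(bp),
        knots=knots,
        n_basis=n_basis,
        gram=gram,
        penalty=penalty,
    )


@dataclass(frozen=True)
class FittedCurveSet:
    """The functional sample: per-subject coefficients under one basis.

    ``coefficients`` is K x n; ``lambda_`` the (shared) smoothing parameter;
    ``dof`` the trace of the smoothing hat matrix at that lambda.
    """

    basis: BasisSystem
    coefficients: np.ndarray
    lambda_: float
    gcv_value: float
    dof: float
    subject_ids: tuple[str, ...] | None = None

    @property
    def n_curves(self) -> int:
        return self.coefficients.shape[1]

    def evaluate(self, grid: np.ndarray | Sequence[float]) -> np.ndarray:
        return evaluate_curves(self, grid)


def _penalized_system(
    Y: np.ndarray, basis: BasisSystem, lam: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the penalized least squares via QR of the augmented system.

    Stacking ``[Phi; sqrt(lam) R^{1/2}]`` and QR-factorizing avoids forming
    the normal equations, keeping the solve accurate at very small lambda.
    Returns ``(C, Phi, hat)``.
    """
    Y = np.asarray(Y, dtype=float)
    J = len(basis.breakpoints)
    if Y.shape[0] != J:
        raise ValueError(f"Y must have {J} rows (one per breakpoint), got {Y.shape[0]}")
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y contains missing or non-finite cells; filter the cohort first")
    phi = basis.design_matrix(np.asarray(basis.breakpoints))
    d, Q = linalg.eigh(basis.penalty)
    root = np.sqrt(np.clip(d, 0.0, None))[:, None] * Q.T  # R = root' root
    augmented = np.vstack([phi, np.sqrt(lam) * root])
    q, r = np.linalg.qr(augmented)
    if np.min(np.abs(np.diag(r))) <= 1e-10 * np.max(np.abs(np.diag(r))):
        raise linalg.LinAlgError(
            "penalized system is singular (K > J with lambda = 0); "
            "use a strictly positive smoothing parameter"
        )
    C = linalg.solve_triangular(r, q[:J].T @ Y)
    X = linalg.solve_triangular(r, phi.T, trans="T")  # R^{-T} Phi'
    hat = X.T @ X
    return C, phi, hat


def fit_curves(
    Y: np.ndarray,
    basis: BasisSystem,
    lam: float,
    subject_ids: Sequence[str] | None = None,
) -> FittedCurveSet:
    """Fit all curves at a fixed smoothing parameter.

    ``Y`` is J x n with one row per breakpoint and no missing cells.
    """
    if not np.isfinite(lam) or lam < 0:
        raise ValueError("lambda must be finite and >= 0")
    C, phi, hat = _penalized_system(Y, basis, lam)
    J = Y.shape[0]
    dof = float(np.trace(hat))
    sse = float(np.sum((Y - phi @ C) ** 2))
    gcv = _pooled_gcv(sse, J, Y.shape[1], dof)
    return FittedCurveSet(
        basis=basis,
        coefficients=C,
        lambda_=float(lam),
        gcv_value=gcv,
        dof=dof,
        subject_ids=tuple(subject_ids) if subject_ids is not None else None,
    )


def _pooled_gcv(sse: float, J: int, n: int, dof: float) -> float:
    """Pooled GCV over subjects: sum_i J*SSE_i / (J - dof)^2."""
    if dof >= J:
        return np.inf
    return J * sse / (J - dof) ** 2


def _gcv_at(Y: np.ndarray, basis: BasisSystem, lam: float) -> tuple[float, float]:
    C, phi, hat = _penalized_system(Y, basis, lam)
    dof = float(np.trace(hat))
    sse = float(np.sum((Y - phi @ C) ** 2))
    return _pooled_gcv(sse, Y.shape[0], Y.shape[1], dof), dof


def select_lambda_gcv(
    Y: np.ndarray,
    basis: BasisSystem,
    grid: np.ndarray | Sequence[float] | None = None,
) -> tuple[float, np.ndarray]:
    """Select the shared smoothing parameter by pooled GCV.

    Evaluates GCV on a log-spaced grid, then refines the minimizer by
    bounded golden-section search between the neighbouring grid points.
    Grid points where the effective degrees of freedom reach J (GCV
    undefined) are skipped with a warning.  Deterministic for fixed input.

    Returns ``(lambda_star, gcv_curve)`` where ``gcv_curve`` has columns
    (lambda, gcv, dof).
    """
    grid = DEFAULT_LAMBDA_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("lambda grid must be non-empty with positive values")
    grid = np.sort(grid)
    J = len(basis.breakpoints)
    rows = []
    for lam in grid:
        gcv, dof = _gcv_at(Y, basis, lam)
        if not np.isfinite(gcv):
            logger.warning(
                "GCV undefined at lambda=%.3g (dof=%.3f >= J=%d); grid point skipped",
                lam,
                dof,
                J,
            )
        rows.append((lam, gcv, dof))
    curve = np.asarray(rows)
    finite = np.isfinite(curve[:, 1])
    if not np.any(finite):
        raise ValueError("GCV undefined on the whole grid; extend it to larger lambda")
    k = int(np.flatnonzero(finite)[np.argmin(curve[finite, 1])])
    lo = curve[max(k - 1, 0), 0]
    hi = curve[min(k + 1, len(grid) - 1), 0]
    if lo == hi:
        lam_star = lo
    else:
        res = optimize.minimize_scalar(
            lambda u: _gcv_at(Y, basis, float(np.exp(u)))[0],
            bounds=(np.log(lo), np.log(hi)),
            method="bounded",
            options={"xatol": 1e-6},
        )
        lam_star = float(np.exp(res.x))
        if _gcv_at(Y, basis, lam_star)[0] > curve[k, 1]:
            lam_star = float(curve[k, 0])
    logger.info("GCV-selected lambda = %.4g (grid minimum at %.4g)", lam_star, curve[k, 0])
    return float(lam_star), curve


def fit_with_gcv(
    Y: np.ndarray,
    basis: BasisSystem,
    mode: str = "shared",
    grid: np.ndarray | Sequence[float] | None = None,
    subject_ids: Sequence[str] | None = None,
) -> FittedCurveSet:
    """GCV-select lambda then fit; ``mode`` in {shared, per_curve}.

    The shared mode pools GCV over subjects (all share the identical design,
    so one lambda is stable); per-curve mode selects a lambda per subject,
    reporting their geometric mean as the set-level summary.
    """
    if mode == "shared":
        lam, _ = select_lambda_gcv(Y, basis, grid)
        return fit_curves(Y, basis, lam, subject_ids=subject_ids)
    if mode == "per_curve":
        cols, lams = [], []
        for i in range(Y.shape[1]):
            lam_i, _ = select_lambda_gcv(Y[:, [i]], basis, grid)
            cols.append(fit_curves(Y[:, [i]], basis, lam_i).coefficients[:, 0])
            lams.append(lam_i)
        lam_summary = float(np.exp(np.mean(np.log(lams))))
        C = np.column_stack(cols)
        phi = basis.design_matrix(np.asarray(basis.breakpoints))
        sse = float(np.sum((Y - phi @ C) ** 2))
        _, dof = _gcv_at(Y, basis, lam_summary)
        return FittedCurveSet(
            basis=basis,
            coefficients=C,
            lambda_=lam_summary,
            gcv_value=_pooled_gcv(sse, Y.shape[0], Y.shape[1], dof),
            dof=dof,
            subject_ids=tuple(subject_ids) if subject_ids is not None else None,
        )
    raise ValueError(f"mode must be 'shared' or 'per_curve', got {mode!r}")


def evaluate_curves(
    fit: FittedCurveSet, grid: np.ndarray | Sequence[float]
) -> np.ndarray:
    """Evaluate all fitted curves on ``grid``: returns n x |grid| values."""
    phi = fit.basis.design_matrix(grid)
    return (phi @ fit.coefficients).T


def default_grid(step: float = 1.0) -> np.ndarray:
    """The 1-minute evaluation grid over the 2-h test (121 points)."""
    return np.arange(0.0, 120.0 + 0.5 * step, step)


def roughness(fit: FittedCurveSet) -> np.ndarray:
    """Per-curve integrated squared second derivative c' R c."""
    C = fit.coefficients
    return np.einsum("ki,kl,li->i", C, fit.basis.penalty, C)


__all__ = [
    "BasisSystem",
    "FittedCurveSet",
    "build_basis",
    "fit_curves",
    "select_lambda_gcv",
    "fit_with_gcv",
    "evaluate_curves",
    "default_grid",
    "roughness",
    "DEFAULT_LAMBDA_GRID",
]
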