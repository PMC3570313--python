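"""Functional principal component analysis of the fitted curve sample.

The eigenfunctions (FPC curves) ``xi_k(t)`` maximise the variance of the
subject scores ``z_ki = int xi_k(t) (x_i(t) - mu(t)) dt`` subject to
``int xi_k^2 dt = 1`` and orthogonality to the earlier components.  With
curves expressed in a K-dimensional B-spline basis with Gram matrix W, the
problem reduces to the symmetric eigenproblem of ``W^{1/2} S W^{1/2}``
where S is the sample covariance of the (centered) coefficient vectors;
eigenfunction coefficients are ``b = W^{-1/2} u`` for eigenvector u.  The
basis is low-dimensional (K = 7 by default) so this is exact and cheap; a
dense-grid quadrature PCA is retained only as a test oracle.

Signs are canonicalized so that a positive first-component score means a
generally elevated curve: orient each xi so its time integral is positive,
falling back to xi(120) - xi(0) > 0 and then xi(0) > 0 for (near-)zero-mean
eigenfunctions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .smoothing import BasisSystem, FittedCurveSet, default_grid

logger = logging.getLogger("ogttfda")


@dataclass(frozen=True)
class FPCAResult:
    """Mean curve, eigenfunctions, eigenvalues and per-subject scores.

    ``eigenfunction_coefficients`` is K x m (basis coefficients of xi_k);
    ``variance_proportions`` are eigenvalues over the total functional
    variance (the trace of the covariance operator), so they sum to 1 over
    all K components.  ``scores`` is n x m, computed on centered curves.
    """

    basis: BasisSystem
    mean_coefficients: np.ndarray
    eigenfunction_coefficients: np.ndarray
    eigenvalues: np.ndarray
    variance_proportions: np.ndarray
    scores: np.ndarray
    n_components: int
    total_variance: float
    subject_ids: tuple[str, ...] | None = None

    def mean_curve(self, grid: np.ndarray) -> np.ndarray:
        return self.basis.design_matrix(grid) @ self.mean_coefficients

    def eigenfunctions(self, grid: np.ndarray) -> np.ndarray:
        """m x |grid| matrix of eigenfunction values."""
        return (self.basis.design_matrix(grid) @ self.eigenfunction_coefficients).T


def _sqrt_and_inv_sqrt(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d, V = linalg.eigh(W)
    if np.any(d <= 0):
        raise linalg.LinAlgError("Gram matrix not positive definite")
    return (V * np.sqrt(d)) @ V.T, (V / np.sqrt(d)) @ V.T


def _canonical_signs(basis: BasisSystem, B: np.ndarray) -> np.ndarray:
    """Sign flip per component: integral > 0, else rising, else positive start."""
    lo, hi = basis.domain
    # partition of unity: the constant 1 has all-ones coefficients, so
    # int xi dt = b' W 1.
    integrals = B.T @ basis.gram @ np.ones(basis.n_basis)
    ends = basis.design_matrix(np.array([lo, hi])) @ B  # (2, m)
    signs = np.ones(B.shape[1])
    for k in range(B.shape[1]):
        if abs(integrals[k]) >= 1e-6:
            signs[k] = np.sign(integrals[k])
        elif abs(ends[1, k] - ends[0, k]) >= 1e-6:
            signs[k] = np.sign(ends[1, k] - ends[0, k])
        elif ends[0, k] != 0:
            signs[k] = np.sign(ends[0, k])
    return signs


def run_fpca(fit: FittedCurveSet, n_components: int | None = None) -> FPCAResult:
    """Eigen-decompose the sample covariance operator of the fitted curves."""
    K = fit.basis.n_basis
    n = fit.n_curves
    if n < 2:
        raise ValueError("FPCA needs at least 2 curves")
    m = K if n_components is None else int(n_components)
    if m < 1 or m > K:
        raise ValueError(f"n_components must be in [1, {K}], got {m}")

    C = fit.coefficients
    cbar = C.mean(axis=1)
    Cc = C - cbar[:, None]
    S = (Cc @ Cc.T) / (n - 1)
    W_half, W_ihalf = _sqrt_and_inv_sqrt(fit.basis.gram)
    M = W_half @ S @ W_half
    M = 0.5 * (M + M.T)
    evals, U = linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    U = U[:, order]
    total = float(np.trace(M))

    B = W_ihalf @ U[:, :m]
    signs = _canonical_signs(fit.basis, B)
    B = B * signs
    # z_i = int xi (x_i - mu) dt = b' W (c_i - cbar)
    Z = (B.T @ fit.basis.gram @ Cc).T

    proportions = evals[:m] / total if total > 0 else np.zeros(m)
    logger.info(
        "FPCA: first three variance proportions %s (total variance %.4g)",
        np.round(proportions[: min(m, 3)], 4),
        total,
    )
    return FPCAResult(
        basis=fit.basis,
        mean_coefficients=cbar,
        eigenfunction_coefficients=B,
        eigenvalues=evals[:m],
        variance_proportions=proportions,
        scores=Z,
        n_components=m,
        total_variance=total,
        subject_ids=fit.subject_ids,
    )


def compute_scores(result: FPCAResult, fit: FittedCurveSet) -> np.ndarray:
    """Project a (possibly new) fitted sample onto the eigenfunctions.

    Scores are inner products of centered curves with the eigenfunctions,
    using the training-sample mean curve for centering.
    """
    if not result.basis.same_system(fit.basis):
        raise ValueError("FPCA result and curve set use different basis systems")
    Cc = fit.coefficients - result.mean_coefficients[:, None]
    return (result.eigenfunction_coefficients.T @ result.basis.gram @ Cc).T


def variance_table(result: FPCAResult) -> pd.DataFrame:
    """Eigenvalue / proportion / cumulative-proportion summary per component."""
    prop = result.variance_proportions
    return pd.DataFrame(
        {
            "component": np.arange(1, result.n_components + 1),
            "eigenvalue": result.eigenvalues,
            "proportion": prop,
            "cumulative": np.cumsum(prop),
        }
    )


def mode_curves(
    result: FPCAResult,
    component: int,
    multiple: float = 1.0,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean curve and mean +/- multiple * score-SD * eigenfunction.

    The standard mode-of-variation display: what a curve scoring
    ``multiple`` standard deviations above/below the mean on this component
    looks like.  ``component`` is 1-based.
    """
    if component < 1 or component > result.n_components:
        raise ValueError(f"component must be in [1, {result.n_components}]")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    mean = result.mean_curve(grid)
    xi = result.eigenfunctions(grid)[component - 1]
    sd = float(np.sqrt(result.eigenvalues[component - 1]))
    offset = multiple * sd * xi
    return pd.DataFrame(
        {
            "time_min": grid,
            "mean": mean,
            "plus": mean + offset,
            "minus": mean - offset,
        }
    )


def scores_frame(result: FPCAResult, n_components: int | None = None) -> pd.DataFrame:
    m = result.n_components if n_components is None else n_components
    cols = {f"fpc{k+1}": result.scores[:, k] for k in range(m)}
    ids = (
        list(result.subject_ids)
        if result.subject_ids is not None
        else [str(i) for i in range(result.scores.shape[0])]
    )
    return pd.DataFrame({"subject_id": ids, **cols}).set_index("subject_id")


def quartile_assignments(result: FPCAResult) -> pd.DataFrame:
    """Cross-classify subjects by FPC1/FPC2 score quartiles (3 x 3 panels).

    Rows and columns are 'low' (< Q1), 'mid' and 'high' (> Q3); every
    subject falls in exactly one panel.
    """
    if result.n_components < 2:
        raise ValueError("need at least 2 components for the quartile panels")

    def tercile_by_quartile(x: np.ndarray) -> np.ndarray:
        q1, q3 = np.quantile(x, [0.25, 0.75])
        return np.where(x < q1, "low", np.where(x > q3, "high", "mid"))

    f1 = tercile_by_quartile(result.scores[:, 0])
    f2 = tercile_by_quartile(result.scores[:, 1])
    ids = (
        list(result.subject_ids)
        if result.subject_ids is not None
        else [str(i) for i in range(result.scores.shape[0])]
    )
    return pd.DataFrame(
        {
            "subject_id": ids,
            "fpc1_band": f1,
            "fpc2_band": f2,
            "panel": [a + "/" + b for a, b in zip(f1, f2)],
        }
    ).set_index("subject_id")


__all__ = [
    "FPCAResult",
    "run_fpca",
    "compute_scores",
    "variance_table",
    "mode_curves",
    "scores_frame",
    "quartile_assignments",
]
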