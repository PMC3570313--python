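"""Functional analysis of variance across subject categories.

The model is ``x_lg(t) = beta_ref(t) + beta_g(t) + eps_lg(t)``: the
reference-category mean curve plus a per-category contrast curve.  Group
differences are assessed by the point-wise one-way F statistic

    F(t) = [between-group SS(t) / (G - 1)] / [within-group SS(t) / (n - G)]

with inference by permutation of whole-curve group labels: the point-wise
permutation p(t) curve, and an overall p from the permutation distribution
of ``max_t F(t)``.  Point-wise confidence bands for the contrasts use the
normal approximation with the pooled per-time residual variance.

Subjects with missing labels are excluded (with a logged count) from this
analysis only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .smoothing import FittedCurveSet, default_grid, evaluate_curves

logger = logging.getLogger("ogttfda")

DEFAULT_PERMUTATIONS = 1000


@dataclass
class FanovaResult:
    """Coefficient curves, F/p curves, overall p and point-wise bands."""

    grid: np.ndarray
    reference: str
    categories: tuple[str, ...]  # non-reference categories, stable order
    beta_ref: np.ndarray
    beta: dict[str, np.ndarray]  # category -> contrast curve on grid
    group_sizes: dict[str, int]
    F_curve: np.ndarray | None = None
    p_curve: np.ndarray | None = None
    p_overall: float | None = None
    ci_lower: dict[str, np.ndarray] = field(default_factory=dict)
    ci_upper: dict[str, np.ndarray] = field(default_factory=dict)
    n_permutations: int | None = None
    seed: int | None = None
    n_excluded_missing_label: int = 0

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """CSV-ready tables: per-category bands and the F/p curves."""
        out: dict[str, pd.DataFrame] = {}
        for g in self.categories:
            df = pd.DataFrame(
                {"time_min": self.grid, "beta": self.beta[g]}
            )
            if g in self.ci_lower:
                df["ci_lower"] = self.ci_lower[g]
                df["ci_upper"] = self.ci_upper[g]
            out[g] = df
        if self.F_curve is not None:
            out["test"] = pd.DataFrame(
                {"time_min": self.grid, "F": self.F_curve, "p": self.p_curve}
            )
        return out


def _clean_labels(
    fit: FittedCurveSet, labels
) -> tuple[np.ndarray, np.ndarray, int]:
    labels = np.asarray(pd.Series(labels), dtype=object)
    if labels.shape[0] != fit.n_curves:
        raise ValueError("one label per curve required")
    missing = np.array([l is None or (isinstance(l, float) and np.isnan(l)) for l in labels])
    if missing.any():
        logger.info("FANOVA: excluding %d subjects with missing labels", missing.sum())
    return labels[~missing], ~missing, int(missing.sum())


def _groupwise_f(X: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Point-wise one-way F over the columns of the n x T curve matrix."""
    n = X.shape[0]
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for g in range(n_groups):
        Xg = X[codes == g]
        mg = Xg.mean(axis=0)
        ssb += len(Xg) * (mg - grand) ** 2
        ssw += ((Xg - mg) ** 2).sum(axis=0)
    msb = ssb / (n_groups - 1)
    msw = ssw / (n - n_groups)
    F = np.where(msw > 0, msb / np.where(msw > 0, msw, 1.0), np.inf)
    return np.where((msb == 0) & (msw == 0), 0.0, F)


def fit_fanova(
    fit: FittedCurveSet,
    labels,
    reference: str,
    grid: np.ndarray | None = None,
) -> FanovaResult:
    """Estimate the reference mean curve and per-category contrast curves.

    Means are formed in coefficient space (each group's mean curve is the
    curve of its mean coefficient vector) and evaluated on the grid.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    labels_clean, keep, n_missing = _clean_labels(fit, labels)
    C = fit.coefficients[:, keep]
    levels = list(pd.unique(labels_clean))
    if reference not in levels:
        raise ValueError(f"reference category {reference!r} absent from labels")
    phi = fit.basis.design_matrix(grid)
    means = {g: phi @ C[:, labels_clean == g].mean(axis=1) for g in levels}
    sizes = {g: int((labels_clean == g).sum()) for g in levels}
    others = tuple(g for g in levels if g != reference)
    return FanovaResult(
        grid=grid,
        reference=reference,
        categories=others,
        beta_ref=means[reference],
        beta={g: means[g] - means[reference] for g in others},
        group_sizes=sizes,
        n_excluded_missing_label=n_missing,
    )


def permutation_test(
    fit: FittedCurveSet,
    labels,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Permutation F test over the evaluation grid.

    Returns ``(F_curve, p_curve, p_overall)`` with the add-one convention
    ``p = (1 + #{F_b >= F_obs}) / (B + 1)``; the overall p uses the
    permutation distribution of the maximal point-wise F.  Whole curves are
    permuted (labels shuffled across subjects), reproducibly under ``seed``.
    """
    if B < 1:
        raise ValueError("number of permutations must be >= 1")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    labels_clean, keep, _ = _clean_labels(fit, labels)
    levels, codes = np.unique(labels_clean.astype(str), return_inverse=True)
    counts = np.bincount(codes)
    if len(levels) < 2 or np.any(counts < 2):
        raise ValueError("permutation test needs >= 2 categories with >= 2 subjects")
    X = evaluate_curves(fit, grid)[keep]
    F_obs = _groupwise_f(X, codes, len(levels))
    max_obs = F_obs.max()

    rng = np.random.default_rng(seed)
    exceed_point = np.zeros_like(F_obs)
    exceed_max = 0
    for _ in range(B):
        perm = rng.permutation(codes)
        F_b = _groupwise_f(X, perm, len(levels))
        exceed_point += F_b >= F_obs
        if F_b.max() >= max_obs:
            exceed_max += 1
    p_curve = (1.0 + exceed_point) / (B + 1.0)
    p_overall = (1.0 + exceed_max) / (B + 1.0)
    return F_obs, p_curve, float(p_overall)


def pointwise_ci(
    fanova: FanovaResult,
    fit: FittedCurveSet,
    labels,
    level: float = 0.95,
) -> FanovaResult:
    """Attach point-wise normal-theory bands to the contrast curves.

    SE(t) = sqrt(s^2(t) (1/L_g + 1/L_ref)) with s^2(t) the pooled
    within-group residual variance at t (the per-time OLS estimate under
    reference coding).
    """
    labels_clean, keep, _ = _clean_labels(fit, labels)
    if any(v < 2 for v in fanova.group_sizes.values()):
        raise ValueError("point-wise CIs need >= 2 subjects per category")
    X = evaluate_curves(fit, fanova.grid)[keep]
    levels, codes = np.unique(labels_clean.astype(str), return_inverse=True)
    n, G = X.shape[0], len(levels)
    ssw = np.zeros(X.shape[1])
    for g in range(G):
        Xg = X[codes == g]
        ssw += ((Xg - Xg.mean(axis=0)) ** 2).sum(axis=0)
    s2 = ssw / (n - G)
    z = stats.norm.ppf(0.5 + level / 2.0)
    L_ref = fanova.group_sizes[fanova.reference]
    for g in fanova.categories:
        se = np.sqrt(s2 * (1.0 / fanova.group_sizes[g] + 1.0 / L_ref))
        fanova.ci_lower[g] = fanova.beta[g] - z * se
        fanova.ci_upper[g] = fanova.beta[g] + z * se
    return fanova


def run_fanova(
    fit: FittedCurveSet,
    labels,
    reference: str,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    grid: np.ndarray | None = None,
    level: float = 0.95,
) -> FanovaResult:
    """Estimates, permutation test and point-wise bands in one call."""
    result = fit_fanova(fit, labels, reference, grid)
    result.F_curve, result.p_curve, result.p_overall = permutation_test(
        fit, labels, B=B, seed=seed, grid=result.grid
    )
    result.n_permutations = B
    result.seed = seed
    pointwise_ci(result, fit, labels, level=level)
    return result


def pairwise_comparisons(
    fit: FittedCurveSet,
    labels,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Overall permutation p per category pair, via two-category refits.

    Each pair's test uses only that pair's subjects (labels of other
    categories treated as missing), mirroring pairwise mean-curve
    comparisons.  Seeds per pair are derived deterministically from
    ``seed``.
    """
    labels_arr = np.asarray(pd.Series(labels), dtype=object)
    levels = [
        l
        for l in pd.unique(labels_arr)
        if not (l is None or (isinstance(l, float) and np.isnan(l)))
    ]
    ss = np.random.SeedSequence(seed)
    rows = []
    from itertools import combinations

    pair_seeds = ss.spawn(len(list(combinations(levels, 2))))
    counts = {l: int((labels_arr == l).sum()) for l in levels}
    for (ga, gb), child in zip(combinations(levels, 2), pair_seeds):
        if counts[ga] < 2 or counts[gb] < 2:
            logger.warning(
                "pairwise FANOVA %s vs %s skipped (category with < 2 subjects)",
                ga, gb,
            )
            rows.append({"category_a": ga, "category_b": gb, "p_overall": np.nan})
            continue
        sub_labels = np.where(
            (labels_arr == ga) | (labels_arr == gb), labels_arr, None
        )
        pair_seed = int(child.generate_state(1)[0] % (2**31))
        _, _, p = permutation_test(fit, sub_labels, B=B, seed=pair_seed, grid=grid)
        rows.append({"category_a": ga, "category_b": gb, "p_overall": p})
    return pd.DataFrame(rows)


__all__ = [
    "FanovaResult",
    "fit_fanova",
    "permutation_test",
    "pointwise_ci",
    "run_fanova",
    "pairwise_comparisons",
    "DEFAULT_PERMUTATIONS",
]
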