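"""Multinomial logistic regression of the categorized late-pregnancy 2-h
glucose on early-pregnancy curve information.

The continuous 2-h value at gestational weeks 30-32 is grouped into seven
ordered, left-closed/right-open intervals (reference: the broad middle
interval); a multinomial logit with that categorical response is fitted
with BMI plus either the three FPC scores (model ``fpc_scores``) or one
simple summary measure at a time (``fasting``, ``two_hour``, ``auc``,
``shape_index``).  Odds ratios are per unit of the covariate, with Wald
confidence intervals and p-values; adjacent non-reference categories are
compared by Wald contrasts on the corresponding coefficients using the
joint estimated covariance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

logger = logging.getLogger("ogttfda")

DEFAULT_CUTPOINTS = (3.27, 3.89, 6.39, 6.90, 7.8, 8.84)

MODEL_COVARIATES = {
    "fpc_scores": ("fpc1", "fpc2", "fpc3"),
    "fasting": ("fasting",),
    "two_hour": ("v120",),
    "auc": ("auc",),
    "shape_index": ("shape_index",),
}


@dataclass(frozen=True)
class OutcomeCategories:
    """Seven ordered glucose intervals with a designated reference.

    Intervals are left-closed, right-open and partition the real line;
    a boundary value falls in the upper interval.
    """

    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS
    reference_index: int = 2  # [3.89, 6.39): the broad middle interval

    def __post_init__(self) -> None:
        if list(self.cutpoints) != sorted(set(self.cutpoints)):
            raise ValueError("cutpoints must be strictly increasing")
        if not 0 <= self.reference_index < len(self.cutpoints) + 1:
            raise ValueError("reference_index out of range")

    @property
    def labels(self) -> tuple[str, ...]:
        cp = self.cutpoints
        out = [f"<{cp[0]}"]
        out += [f"[{a},{b})" for a, b in zip(cp[:-1], cp[1:])]
        out.append(f">={cp[-1]}")
        return tuple(out)

    @property
    def reference_label(self) -> str:
        return self.labels[self.reference_index]


def categorize_outcome(
    values, categories: OutcomeCategories | None = None
) -> pd.Series:
    """Map 2-h glucose values to interval labels; missing stays missing."""
    categories = categories or OutcomeCategories()
    v = pd.Series(values, dtype=float)
    idx = np.digitize(v.to_numpy(), categories.cutpoints, right=False)
    labels = pd.Series(
        pd.Categorical.from_codes(
            idx, categories=list(categories.labels), ordered=True
        ),
        index=v.index,
    )
    labels[v.isna()] = None
    n_missing = int(v.isna().sum())
    if n_missing:
        logger.info("outcome categorization: %d missing values left unlabelled", n_missing)
    return labels


@dataclass
class MultinomFit:
    """A fitted multinomial logit with Table-style reporting helpers."""

    model_id: str
    categories: OutcomeCategories
    covariate_names: tuple[str, ...]  # excludes the intercept
    category_order: tuple[str, ...]  # reference first; matches param columns
    result: object  # statsmodels MNLogitResults
    n_used: int
    n_dropped: int
    converged: bool
    separation_flag: bool
    category_stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def reference(self) -> str:
        return self.category_order[0]

    def coefficient(self, covariate: str, category: str) -> float:
        return float(self._params().loc[covariate, category])

    def _params(self) -> pd.DataFrame:
        """k_exog x (G - 1) coefficient table (intercept row included)."""
        params = np.asarray(self.result.params)
        names = ["intercept", *self.covariate_names, "bmi"][: params.shape[0]]
        return pd.DataFrame(params, index=names, columns=list(self.category_order[1:]))

    def odds_ratio_table(self) -> pd.DataFrame:
        """Per category and covariate: OR, 95% Wald CI, p."""
        params = self._params()
        bse = pd.DataFrame(
            np.asarray(self.result.bse), index=params.index, columns=params.columns
        )
        rows = []
        for cat in params.columns:
            for cov in params.index:
                if cov == "intercept":
                    continue
                b, se = params.loc[cov, cat], bse.loc[cov, cat]
                z = b / se if se > 0 else math.nan
                rows.append(
                    {
                        "category": cat,
                        "covariate": cov,
                        "coef": b,
                        "or": math.exp(b),
                        "or_ci_low": math.exp(b - 1.959963984540054 * se),
                        "or_ci_high": math.exp(b + 1.959963984540054 * se),
                        "wald_p": 2 * stats.norm.sf(abs(z)) if se > 0 else math.nan,
                    }
                )
        return pd.DataFrame(rows)

    def predicted_probabilities(self) -> np.ndarray:
        return np.asarray(self.result.predict())

    def table3_style(self, covariate: str) -> pd.DataFrame:
        """Category, n, covariate mean (SD), OR (CI), p — one covariate."""
        ors = self.odds_ratio_table()
        ors = ors[ors["covariate"] == covariate].set_index("category")
        rows = []
        for cat in self.category_order:
            stats_row = self.category_stats.loc[cat]
            if cat == self.reference:
                rows.append(
                    {
                        "category": cat,
                        "n": int(stats_row["n"]),
                        "mean": stats_row[f"{covariate}_mean"],
                        "sd": stats_row[f"{covariate}_sd"],
                        "or": 1.0,
                        "or_ci_low": math.nan,
                        "or_ci_high": math.nan,
                        "wald_p": math.nan,
                    }
                )
            else:
                r = ors.loc[cat]
                rows.append(
                    {
                        "category": cat,
                        "n": int(stats_row["n"]),
                        "mean": stats_row[f"{covariate}_mean"],
                        "sd": stats_row[f"{covariate}_sd"],
                        "or": r["or"],
                        "or_ci_low": r["or_ci_low"],
                        "or_ci_high": r["or_ci_high"],
                        "wald_p": r["wald_p"],
                    }
                )
        return pd.DataFrame(rows)


def fit_multinomial(
    labels: pd.Series,
    covariates: pd.DataFrame,
    categories: OutcomeCategories | None = None,
    model_id: str = "custom",
    include_bmi: bool = True,
    maxiter: int = 200,
) -> MultinomFit:
    """Maximum-likelihood multinomial logit with the reference first.

    ``labels`` are interval labels (from :func:`categorize_outcome`);
    ``covariates`` a per-subject frame aligned with ``labels`` containing
    the model covariates (and ``bmi`` when ``include_bmi``).  Complete-case:
    rows with a missing label or covariate are dropped with a logged count.
    Separation (|standardized coefficient| > 20) is flagged, not fatal.
    """
    categories = categories or OutcomeCategories()
    cov_names = tuple(c for c in covariates.columns if c != "bmi")
    if include_bmi:
        if "bmi" not in covariates.columns:
            raise ValueError("covariates must contain 'bmi' when include_bmi=True")
        design_cols = [*cov_names, "bmi"]
    else:
        design_cols = list(cov_names)

    df = covariates[design_cols].copy()
    df["_label"] = pd.Series(labels).astype(object)
    n_input = len(df)
    df = df.dropna()
    n_dropped = n_input - len(df)
    if n_dropped:
        logger.info("multinomial fit (%s): %d incomplete rows dropped", model_id, n_dropped)

    present = [l for l in categories.labels if (df["_label"] == l).any()]
    if categories.reference_label not in present:
        raise ValueError("reference category empty after complete-case filtering")
    dropped_cats = [l for l in categories.labels if l not in present]
    if dropped_cats:
        logger.warning("empty outcome categories dropped: %s", dropped_cats)
    order = [categories.reference_label] + [
        l for l in present if l != categories.reference_label
    ]
    code_of = {l: i for i, l in enumerate(order)}
    endog = df["_label"].map(code_of).to_numpy(dtype=int)
    exog = sm.add_constant(df[design_cols].to_numpy(dtype=float), has_constant="add")

    model = sm.MNLogit(endog, exog)
    res = model.fit(method="newton", maxiter=maxiter, disp=False)
    score_norm = float(np.max(np.abs(model.score(res.params.ravel(order="F")))))
    converged = bool(res.mle_retvals.get("converged", True)) and score_norm <= 1e-4

    scale = np.r_[1.0, df[design_cols].std(ddof=1).to_numpy()]
    standardized = np.asarray(res.params) * scale[:, None]
    separation = bool(np.any(np.abs(standardized) > 20))
    if separation:
        logger.warning("possible separation in model %s: extreme coefficients", model_id)

    stats_rows = []
    for cat in order:
        sub = df[df["_label"] == cat]
        row: dict = {"category": cat, "n": len(sub)}
        for c in design_cols:
            row[f"{c}_mean"] = sub[c].mean()
            row[f"{c}_sd"] = sub[c].std(ddof=1)
        stats_rows.append(row)

    return MultinomFit(
        model_id=model_id,
        categories=categories,
        covariate_names=cov_names,
        category_order=tuple(order),
        result=res,
        n_used=len(df),
        n_dropped=n_dropped,
        converged=converged,
        separation_flag=separation,
        category_stats=pd.DataFrame(stats_rows).set_index("category"),
    )


def compare_categories(
    fit: MultinomFit, covariate: str, category_a: str, category_b: str
) -> float:
    """Wald p for equality of a covariate's coefficients in two categories.

    Uses the joint estimated covariance of the stacked coefficient vector;
    the reference category's coefficient is identically zero.  Comparing a
    category with itself gives p = 1.
    """
    for cat in (category_a, category_b):
        if cat not in fit.category_order:
            raise ValueError(f"category {cat!r} absent from fit")
    if category_a == category_b:
        return 1.0
    params = fit._params()
    if covariate not in params.index:
        raise ValueError(f"covariate {covariate!r} absent from fit")
    k_exog = params.shape[0]
    row_idx = params.index.get_loc(covariate)
    # statsmodels stacks MNLogit parameters equation by equation
    # (column-major over the k_exog x (G-1) matrix).
    contrast = np.zeros(k_exog * params.shape[1])
    noref = list(fit.category_order[1:])
    if category_a != fit.reference:
        contrast[noref.index(category_a) * k_exog + row_idx] = 1.0
    if category_b != fit.reference:
        contrast[noref.index(category_b) * k_exog + row_idx] -= 1.0
    flat = np.asarray(fit.result.params).ravel(order="F")
    cov = np.asarray(fit.result.cov_params())
    est = float(contrast @ flat)
    var = float(contrast @ cov @ contrast)
    if var <= 0:
        return math.nan
    z = est / math.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def adjacent_comparisons(fit: MultinomFit, covariate: str) -> pd.DataFrame:
    """Wald p for each adjacent pair of non-reference categories.

    Pairs follow the glucose ordering of the intervals (not the fitting
    order), mirroring between-category columns of clinical tables.
    """
    ordered = [l for l in fit.categories.labels if l in fit.category_order]
    rows = []
    for a, b in zip(ordered[:-1], ordered[1:]):
        if fit.reference in (a, b):
            continue
        rows.append(
            {
                "category_a": a,
                "category_b": b,
                "covariate": covariate,
                "p": compare_categories(fit, covariate, a, b),
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "DEFAULT_CUTPOINTS",
    "MODEL_COVARIATES",
    "OutcomeCategories",
    "MultinomFit",
    "categorize_outcome",
    "fit_multinomial",
    "compare_categories",
    "adjacent_comparisons",
]
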