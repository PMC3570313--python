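import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import ogttfda as og
from ogttfda import regression as rg


@pytest.fixture(scope="module")
def cats():
    return rg.OutcomeCategories()


def simulate_multinomial(coefs, n, rng, categories):
    """Draw labels from a known multinomial logit with one covariate.

    ``coefs``: dict label -> (intercept, slope) for non-reference labels.
    Returns (labels Series, covariate DataFrame, x).
    """
    x = rng.standard_normal(n)
    order = [categories.reference_label] + list(coefs)
    eta = np.zeros((n, len(order)))
    for j, lab in enumerate(order[1:], start=1):
        a, b = coefs[lab]
        eta[:, j] = a + b * x
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cum = np.cumsum(p, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    labels = pd.Series([order[i] for i in idx])
    cov = pd.DataFrame({"x": x})
    return labels, cov, x


class TestCategorizeOutcome:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (7.8, "[7.8,8.84)"),  # boundary goes to the upper interval
            (2.0, "<3.27"),
            (5.0, "[3.89,6.39)"),
            (3.89, "[3.89,6.39)"),
            (8.84, ">=8.84"),
            (6.39, "[6.39,6.9)"),
        ],
    )
    def test_boundaries_half_open(self, cats, value, expected):
        got = rg.categorize_outcome([value], cats)
        assert got.iloc[0] == expected

    def test_reference_is_middle_interval(self, cats):
        assert cats.reference_label == "[3.89,6.39)"
        assert len(cats.labels) == 7

    def test_missing_value_unlabelled(self, cats):
        got = rg.categorize_outcome([5.0, math.nan], cats)
        assert got.iloc[0] == "[3.89,6.39)"
        assert pd.isna(got.iloc[1])

    def test_partition(self, cats, rng):
        v = rng.uniform(0, 12, size=500)
        got = rg.categorize_outcome(v, cats)
        assert got.notna().all()


@pytest.fixture(scope="module")
def fitted_model(cats):
    rng = np.random.default_rng(42)
    coefs = {
        lab: (a, b)
        for lab, a, b in zip(
            [l for l in cats.labels if l != cats.reference_label],
            [-2.0, -1.5, -1.0, -1.2, -2.0, -2.5],
            [-1.0, -0.5, 0.3, 0.6, 1.0, 1.4],
        )
    }
    labels, cov, x = simulate_multinomial(coefs, 5000, rng, cats)
    fit = rg.fit_multinomial(labels, cov, cats, model_id="sim", include_bmi=False)
    return coefs, labels, cov, fit


class TestFitMultinomial:
    def test_probabilities_sum_to_one(self, fitted_model):
        _, _, _, fit = fitted_model
        probs = fit.predicted_probabilities()
        assert np.abs(probs.sum(axis=1) - 1).max() < 1e-10

    def test_parameter_recovery_within_2se(self, fitted_model):
        coefs, _, _, fit = fitted_model
        params = fit._params()
        bse = pd.DataFrame(
            np.asarray(fit.result.bse), index=params.index, columns=params.columns
        )
        within = []
        for lab, (a, b) in coefs.items():
            if lab not in params.columns:
                continue
            within.append(abs(params.loc["intercept", lab] - a) <= 2 * bse.loc["intercept", lab])
            within.append(abs(params.loc["x", lab] - b) <= 2 * bse.loc["x", lab])
        assert np.mean(within) >= 0.9

    def test_loglik_matches_independent_optimizer(self, cats):
        """The Newton fit attains the same maximum as a generic optimizer
        run on a from-scratch multinomial log-likelihood."""
        rng = np.random.default_rng(3)
        coefs = {
            "[6.39,6.9)": (-0.5, 0.8),
            "[6.9,7.8)": (-1.0, -0.6),
        }
        labels, cov, x = simulate_multinomial(coefs, 400, rng, cats)
        fit = rg.fit_multinomial(labels, cov, cats, model_id="x", include_bmi=False)
        order = list(fit.category_order)
        y = labels.map({l: i for i, l in enumerate(order)}).to_numpy()
        X = np.column_stack([np.ones_like(x), x])

        def negll(theta):
            th = theta.reshape(2, len(order) - 1, order="F")
            eta = np.column_stack([np.zeros(len(x)), X @ th])
            eta -= eta.max(axis=1, keepdims=True)
            logp = eta - np.log(np.exp(eta).sum(axis=1, keepdims=True))
            return -logp[np.arange(len(y)), y].sum()

        res = optimize.minimize(negll, np.zeros(2 * (len(order) - 1)), method="BFGS")
        assert -res.fun == pytest.approx(float(fit.result.llf), abs=1e-6)

    def test_null_covariate_ci_covers_one(self, cats):
        """With a covariate unrelated to the outcome, the 95% CI for its OR
        covers 1 in roughly 95% of replicates."""
        rng = np.random.default_rng(11)
        covered = 0
        n_rep = 60
        for _ in range(n_rep):
            # outcome independent of x: intercept-only multinomial
            coefs = {"[6.39,6.9)": (-0.5, 0.0), "<3.27": (-1.0, 0.0)}
            labels, cov, _ = simulate_multinomial(coefs, 600, rng, cats)
            fit = rg.fit_multinomial(labels, cov, cats, model_id="null", include_bmi=False)
            ors = fit.odds_ratio_table()
            row = ors[(ors["covariate"] == "x")].iloc[0]
            covered += row["or_ci_low"] <= 1.0 <= row["or_ci_high"]
        assert covered / n_rep >= 0.85

    def test_relabelled_categories_same_ors(self, fitted_model, cats):
        coefs, labels, cov, fit = fitted_model
        shifted = rg.OutcomeCategories(
            cutpoints=tuple(c + 100 for c in cats.cutpoints)
        )
        mapping = dict(zip(cats.labels, shifted.labels))
        fit2 = rg.fit_multinomial(
            labels.map(mapping), cov, shifted, model_id="relabel", include_bmi=False
        )
        a = fit.odds_ratio_table()["or"].to_numpy()
        b = fit2.odds_ratio_table()["or"].to_numpy()
        assert np.allclose(a, b, rtol=1e-6)


class TestCompareCategories:
    def test_same_category_p_one(self, fitted_model):
        _, _, _, fit = fitted_model
        lab = fit.category_order[1]
        assert rg.compare_categories(fit, "x", lab, lab) == 1.0

    def test_absent_category_rejected(self, fitted_model):
        _, _, _, fit = fitted_model
        with pytest.raises(ValueError, match="absent"):
            rg.compare_categories(fit, "x", "nope", fit.category_order[1])

    def test_identical_effects_uniform_p(self, cats):
        """Under equal true coefficients the comparison p-value is uniform
        (KS test across replicates does not reject)."""
        rng = np.random.default_rng(23)
        ps = []
        for _ in range(200):
            coefs = {"[6.39,6.9)": (-0.8, 0.5), "[6.9,7.8)": (-0.8, 0.5)}
            labels, cov, _ = simulate_multinomial(coefs, 500, rng, cats)
            try:
                fit = rg.fit_multinomial(labels, cov, cats, model_id="eq", include_bmi=False)
            except ValueError:
                continue
            ps.append(rg.compare_categories(fit, "x", "[6.39,6.9)", "[6.9,7.8)"))
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.05

    def test_separated_effects_detected(self, cats):
        rng = np.random.default_rng(29)
        coefs = {"[6.39,6.9)": (-0.5, 1.2), "[6.9,7.8)": (-0.5, -1.2)}
        labels, cov, _ = simulate_multinomial(coefs, 2000, rng, cats)
        fit = rg.fit_multinomial(labels, cov, cats, model_id="sep", include_bmi=False)
        assert rg.compare_categories(fit, "x", "[6.39,6.9)", "[6.9,7.8)") < 0.01

    def test_reference_comparison_equals_wald_p(self, fitted_model):
        _, _, _, fit = fitted_model
        lab = fit.category_order[1]
        p_contrast = rg.compare_categories(fit, "x", lab, fit.reference)
        ors = fit.odds_ratio_table()
        row = ors[(ors["category"] == lab) & (ors["covariate"] == "x")].iloc[0]
        assert p_contrast == pytest.approx(row["wald_p"], rel=1e-8)


def test_curve_shape_signal_seen_only_by_scores(basis):
    """When the later outcome depends on the time-to-peak score, the score
    model detects between-category differences that the shape-index model
    cannot (the directional contrast of information content)."""
    from ogttfda import fpca as fp
    from ogttfda import simulate as sim_mod
    from ogttfda import smoothing as sm
    from ogttfda import summaries as sms

    cfg = og.GeneratorConfig(
        n_subjects=1000,
        seed=405,
        outcome_model=(5.5, 0.0, 0.8, 1.0),  # outcome driven by score 2 only
        missing_fraction=0.0,
    )
    cohort = sim_mod.simulate_cohort(cfg)
    fit = sm.fit_with_gcv(
        cohort.glucose_matrix(), basis, subject_ids=cohort.subject_ids
    )
    fp_res = fp.run_fpca(fit)
    scores = fp.scores_frame(fp_res, 3)
    summaries = sms.summarize_cohort(cohort)
    frame = cohort.covariate_frame()
    cats = rg.OutcomeCategories()
    labels = rg.categorize_outcome(frame["outcome_2h_late"], cats)
    labels.index = scores.index

    design_scores = scores.join(frame[["bmi"]])
    fit_scores = rg.fit_multinomial(labels, design_scores, cats, model_id="fpc_scores")
    design_shape = summaries[["shape_index"]].join(frame[["bmi"]])
    fit_shape = rg.fit_multinomial(labels, design_shape, cats, model_id="shape_index")

    high = [l for l in cats.labels if l in fit_scores.category_order][-2:]
    p_fpc2 = rg.compare_categories(fit_scores, "fpc2", *high)
    high_s = [l for l in cats.labels if l in fit_shape.category_order][-2:]
    p_shape = rg.compare_categories(fit_shape, "shape_index", *high_s)
    assert p_fpc2 < 0.05
    assert p_shape > 0.05
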