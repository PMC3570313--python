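import math

import numpy as np
import pytest

import ogttfda as og
from ogttfda import fpca as fp
from ogttfda import simulate as sim_mod
from ogttfda import smoothing as sm


def simpson_weights(grid):
    """Composite Simpson quadrature weights (odd-length uniform grid)."""
    n = len(grid)
    assert n % 2 == 1
    h = grid[1] - grid[0]
    w = np.full(n, 2.0)
    w[1::2] = 4.0
    w[0] = w[-1] = 1.0
    return w * h / 3.0


def grid_pca_oracle(curves, grid, n_components):
    """Brute-force FPCA: quadrature-weighted PCA of densely evaluated curves.

    Discretizes the covariance operator eigenproblem with Simpson
    quadrature weights; independent of the basis-space eigenproblem it
    checks.
    """
    w = simpson_weights(grid)
    Xc = curves - curves.mean(axis=0)
    K = (Xc.T @ Xc) / (curves.shape[0] - 1)  # covariance at grid points
    sw = np.sqrt(w)
    A = sw[:, None] * K * sw[None, :]
    evals, vecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1][:n_components]
    eigvals = np.clip(evals[order], 0, None)
    xi = (vecs[:, order] / sw[:, None]).T  # rows: eigenfunctions on grid
    return eigvals, xi


def _fit_from_coefficients(basis, C):
    return sm.FittedCurveSet(
        basis=basis, coefficients=C, lambda_=1.0, gcv_value=np.nan, dof=np.nan
    )


class TestRunFpca:
    def test_identical_curves_zero_eigenvalues(self, basis, rng):
        c = rng.uniform(3, 8, size=basis.n_basis)
        fit = _fit_from_coefficients(basis, np.tile(c[:, None], 10))
        res = fp.run_fpca(fit)
        assert np.abs(res.eigenvalues).max() < 1e-10

    def test_rank_one_two_curve_sample(self, basis, rng):
        mu = rng.uniform(4, 6, size=basis.n_basis)
        delta = rng.standard_normal(basis.n_basis)
        fit = _fit_from_coefficients(basis, np.column_stack([mu + delta, mu - delta]))
        res = fp.run_fpca(fit)
        assert res.eigenvalues[0] > 1e-8
        assert np.abs(res.eigenvalues[1:]).max() < 1e-10
        # xi_1 proportional to the delta-direction curve
        grid = sm.default_grid(5.0)
        xi = res.eigenfunctions(grid)[0]
        d = basis.design_matrix(grid) @ delta
        cos = abs(xi @ d) / (np.linalg.norm(xi) * np.linalg.norm(d))
        assert cos >= 1 - 1e-8
        assert np.allclose(fp.variance_table(res)["proportion"].iloc[0], 1.0)

    def test_matches_dense_grid_oracle(self, basis, rng):
        C = rng.standard_normal((basis.n_basis, 40)) + 5.0
        fit = _fit_from_coefficients(basis, C)
        res = fp.run_fpca(fit, n_components=4)
        grid = np.linspace(0, 120, 2001)
        curves = sm.evaluate_curves(fit, grid)
        oracle_vals, oracle_xi = grid_pca_oracle(curves, grid, 4)
        assert np.abs(res.eigenvalues[:4] - oracle_vals).max() < 1e-6
        ours_xi = res.eigenfunctions(grid)
        w = simpson_weights(grid)
        for k in range(4):
            cos = abs(np.sum(w * ours_xi[k] * oracle_xi[k]))
            assert cos == pytest.approx(1.0, abs=1e-6)

    def test_errors(self, basis, rng):
        C = rng.standard_normal((basis.n_basis, 5))
        fit = _fit_from_coefficients(basis, C)
        with pytest.raises(ValueError, match="n_components"):
            fp.run_fpca(fit, n_components=8)
        with pytest.raises(ValueError, match="at least 2"):
            fp.run_fpca(_fit_from_coefficients(basis, C[:, :1]))


@pytest.fixture()
def result_and_fit(default_pipeline):
    return default_pipeline["fpca"], default_pipeline["fit"]


class TestInvariants:
    def test_eigenfunction_orthonormality(self, result_and_fit):
        res, _ = result_and_fit
        B = res.eigenfunction_coefficients
        G = B.T @ res.basis.gram @ B
        assert np.abs(G - np.eye(G.shape[0])).max() < 1e-8

    def test_score_variance_equals_eigenvalue(self, result_and_fit):
        res, _ = result_and_fit
        var = res.scores.var(axis=0, ddof=1)
        pos = res.eigenvalues > 1e-10
        assert np.abs(var[pos] / res.eigenvalues[pos] - 1).max() < 1e-6

    def test_eigenvalues_descending_nonnegative(self, result_and_fit):
        res, _ = result_and_fit
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.all(res.eigenvalues >= 0)

    def test_total_variance_conservation(self, result_and_fit):
        res, fit = result_and_fit
        assert res.eigenvalues.sum() == pytest.approx(res.total_variance, rel=1e-10)
        # trace of the covariance operator = integral of the pointwise variance
        grid = np.linspace(0, 120, 2001)
        curves = sm.evaluate_curves(fit, grid)
        integral = np.trapezoid(curves.var(axis=0, ddof=1), grid)
        assert integral == pytest.approx(res.total_variance, rel=1e-6)

    def test_score_columns_uncorrelated(self, result_and_fit):
        res, _ = result_and_fit
        Z = res.scores[:, :3]
        corr = np.corrcoef(Z.T)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 1e-8


class TestComputeScores:
    def test_mean_curve_scores_zero(self, basis, rng):
        C = rng.standard_normal((basis.n_basis, 20)) + 5
        fit = _fit_from_coefficients(basis, C)
        res = fp.run_fpca(fit)
        mean_fit = _fit_from_coefficients(basis, res.mean_coefficients[:, None])
        assert np.abs(fp.compute_scores(res, mean_fit)).max() < 1e-10

    def test_adding_eigenfunction_shifts_single_score(self, basis, rng):
        C = rng.standard_normal((basis.n_basis, 20)) + 5
        fit = _fit_from_coefficients(basis, C)
        res = fp.run_fpca(fit, n_components=3)
        c_amount = 1.7
        C2 = C.copy()
        C2[:, 0] += c_amount * res.eigenfunction_coefficients[:, 1]
        shifted = fp.compute_scores(res, _fit_from_coefficients(basis, C2))
        base = fp.compute_scores(res, fit)
        delta = shifted - base
        assert delta[0, 1] == pytest.approx(c_amount, abs=1e-8)
        assert abs(delta[0, 0]) < 1e-8 and abs(delta[0, 2]) < 1e-8
        assert np.abs(delta[1:]).max() < 1e-10

    def test_basis_mismatch_rejected(self, basis, rng):
        C = rng.standard_normal((basis.n_basis, 5)) + 5
        res = fp.run_fpca(_fit_from_coefficients(basis, C))
        other = og.build_basis(order=3)
        bad = sm.FittedCurveSet(
            basis=other,
            coefficients=rng.standard_normal((other.n_basis, 5)),
            lambda_=1.0,
            gcv_value=np.nan,
            dof=np.nan,
        )
        with pytest.raises(ValueError, match="basis"):
            fp.compute_scores(res, bad)

    def test_scores_track_generator_truth(self, default_pipeline):
        """Estimated scores are strongly correlated with the generating
        mode scores on the default (noisy) cohort."""
        cfg = default_pipeline["config"]
        truth = sim_mod.truth_bundle(cfg, default_pipeline["cohort"])
        keep = [i for i, r in enumerate(default_pipeline["cohort"]) if r.is_complete]
        z = truth.scores[keep]
        z1_true = z[:, 0] + math.sqrt(120.0) * truth.bmi_shifts[keep]
        got = default_pipeline["fpca"].scores
        # components 1-2 are exactly representable in the spline space and
        # dominate the noise; the small third component is checked via its
        # noiseless attenuation oracle below
        assert abs(np.corrcoef(got[:, 0], z1_true)[0, 1]) > 0.9
        assert abs(np.corrcoef(got[:, 1], z[:, 1])[0, 1]) > 0.9

    def test_score_sds_recover_generator_truth_noiseless(self, basis):
        """Without measurement noise, score SDs reproduce the generating
        mode-score SDs within 5% relative at n = 1000, after accounting for
        how much of each mode the minimum-roughness interpolant of its
        five-point trace retains (the natural cubic spline, an independent
        scipy oracle; modes 1-2 are retained exactly)."""
        from scipy.interpolate import CubicSpline

        cfg = og.GeneratorConfig(
            n_subjects=1000,
            seed=314,
            noise_sd=0.0,
            bmi_level_shifts=(0.0, 0.0, 0.0, 0.0),
            missing_fraction=0.0,
        )
        cohort = sim_mod.simulate_cohort(cfg)
        fit = sm.fit_curves(cohort.glucose_matrix(), basis, 1e-8)
        res = fp.run_fpca(fit, n_components=3)
        got = res.scores.std(axis=0, ddof=1)
        t5 = np.asarray(og.CANONICAL_TIMES)
        dense = np.linspace(0, 120, 4001)
        attenuation = np.array(
            [
                math.sqrt(
                    np.trapezoid(
                        CubicSpline(t5, m(t5), bc_type="natural")(dense) ** 2, dense
                    )
                )
                for m in sim_mod.default_modes()
            ]
        )
        expected = attenuation * np.asarray(cfg.score_sds)
        assert np.abs(got / expected - 1).max() < 0.05


class TestVarianceTable:
    def test_proportions_sum_to_one_cumulative_monotone(self, default_pipeline):
        tab = fp.variance_table(default_pipeline["fpca"])
        assert tab["proportion"].sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(tab["cumulative"]) >= -1e-12)


class TestModeCurves:
    def test_zero_multiple_collapses_to_mean(self, default_pipeline):
        df = fp.mode_curves(default_pipeline["fpca"], 1, multiple=0.0)
        assert np.allclose(df["plus"], df["mean"])
        assert np.allclose(df["minus"], df["mean"])

    def test_mirror_symmetry(self, default_pipeline):
        df = fp.mode_curves(default_pipeline["fpca"], 2)
        assert np.allclose(df["plus"] - df["mean"], df["mean"] - df["minus"])

    def test_component1_is_level_shift(self, default_pipeline):
        """The first mode of the default cohort is a nearly uniform shift."""
        df = fp.mode_curves(default_pipeline["fpca"], 1)
        offset = (df["plus"] - df["mean"]).to_numpy()
        assert offset.min() > 0
        assert offset.max() / offset.min() <= 1.2


class TestRecovery:
    def test_noiseless_modes_recovered(self, basis):
        """Noiseless curves built from the three known orthonormal modes are
        recovered with |cosine| >= 0.99 and matching variance shares."""
        cfg = og.GeneratorConfig(
            n_subjects=1000,
            seed=77,
            noise_sd=0.0,
            bmi_level_shifts=(0.0, 0.0, 0.0, 0.0),
            missing_fraction=0.0,
        )
        cohort = sim_mod.simulate_cohort(cfg)
        truth = sim_mod.truth_bundle(cfg, cohort)
        Y = cohort.glucose_matrix()
        fit = sm.fit_curves(Y, basis, 1e-6, subject_ids=cohort.subject_ids)
        res = fp.run_fpca(fit, n_components=3)
        grid = np.linspace(0, 120, 1201)
        w = np.gradient(grid)
        ours = res.eigenfunctions(grid)
        for k, mode in enumerate(sim_mod.default_modes()):
            cos = abs(np.sum(w * ours[k] * mode(grid)))
            assert cos >= 0.99
        shares = np.array(cfg.score_sds) ** 2 / np.sum(np.array(cfg.score_sds) ** 2)
        emp = truth.scores.var(axis=0, ddof=1) / truth.scores.var(axis=0, ddof=1).sum()
        # recovered proportions match the realized (Monte-Carlo) shares
        assert np.abs(res.variance_proportions[:3] - emp).max() < 0.01
        assert np.abs(res.variance_proportions[:3] - shares).max() < 0.03


def test_quartile_assignments_partition(default_pipeline):
    panels = fp.quartile_assignments(default_pipeline["fpca"])
    assert len(panels) == default_pipeline["fit"].n_curves
    assert set(panels["fpc1_band"]) <= {"low", "mid", "high"}
    counts = panels["panel"].value_counts()
    assert counts.sum() == len(panels)
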