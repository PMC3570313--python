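# Methods

`ogttfda` implements a functional-data-analysis pipeline for oral glucose
tolerance test (OGTT) curves sampled at the five canonical minutes
{0, 30, 60, 90, 120} after a 75 g glucose load, in mmol/l. This note
documents the statistical model behind each stage, the tunable parameters
and their defaults, the synthetic cohort the test suite relies on, and the
numerical and design choices that were genuinely open.

## Measurement model and curve fitting

Each subject's five measurements are treated as noisy evaluations of a
smooth latent curve, `y_i(t_j) = x_i(t_j) + eps_ij`, with i.i.d. Gaussian
error. The curve is expanded in a cubic B-spline basis with a knot at each
design point and boundary knots at full multiplicity, giving K = 7 basis
functions over [0, 120]. Coefficients minimize the penalized least squares
criterion

    ||Y - Phi C||^2 + lambda * tr(C' R C),    R = ∫ D²φ(s) D²φ(s)' ds,

i.e. a roughness penalty on total curvature whose null space is the linear
functions. Because K > J = 5, a strictly positive `lambda` is required; the
solver refuses `lambda = 0` with an explicit message. The solve goes
through a QR factorization of the augmented matrix `[Phi; sqrt(lambda)
R^{1/2}]` rather than the normal equations, which keeps near-interpolating
fits (`lambda -> 0`) accurate to ~1e-10; the Gram matrix `W = ∫ φφ'` and
`R` are computed by per-interval Gauss–Legendre quadrature with `order+1`
nodes, exact for the piecewise-polynomial integrands.

`lambda` is chosen by pooled generalized cross-validation,
`GCV(lambda) = Σ_i J·SSE_i / (J - dof)²` with `dof` the trace of the
smoothing hat matrix, evaluated on 25 log-spaced points in [1e-4, 1e4] and
refined by bounded golden-section search in log-lambda. One `lambda` is
shared across subjects because every subject has the identical five-point
design, which makes per-curve GCV unstable; a per-curve mode exists behind
`lambda_mode="per_curve"` for sensitivity analysis. Cubic order and the
search range are conventional choices for second-derivative penalties; all
are configurable (`spline_order`, `lambda_grid_*`).

## Functional PCA

With all curves in one K-dimensional basis, the covariance operator
eigenproblem reduces exactly to the symmetric K×K eigenproblem of
`W^{1/2} S W^{1/2}`, where S is the sample covariance of the centered
coefficient vectors. Eigenfunction coefficients are `b = W^{-1/2} u`;
subject scores are inner products of centered curves with the
eigenfunctions, `z_ki = ∫ ξ_k (x_i - μ) dt`. Scores are centered (the mean
curve scores zero on every component) — the natural choice when score
means per subgroup are reported against a reference population. Variance
proportions divide each eigenvalue by the trace, so all K proportions sum
to one. A dense-grid quadrature PCA is kept in the test suite as an
independent oracle; the basis-space route is exact and costs O(K³).

Eigenfunction signs are arbitrary; they are fixed so that ∫ξ dt > 0,
falling back to ξ(120) − ξ(0) > 0 and then ξ(0) > 0 for (near-)zero-mean
components. This orients the leading components so that a high first score
means a generally elevated curve and a high second score means a late
peak. All K components are computed; downstream stages default to the
first three, which carry essentially all between-curve variance in this
design. No eigenfunction re-smoothing is applied.

## Simple summary measures and the shape index

Fasting/30/60/90/2-h values and the trapezoid AUC are computed from the
five raw measurements, independent of the smoothing stage (an
integrate-the-fit AUC would be almost identical; keeping the clinical
convention makes the simple measures a genuinely separate information
channel). Total AUC is used, not incremental AUC above fasting.

The curve-shape classification compresses the series into significant
directional moves: a move begins when the series departs from the running
extremum of the previous accepted move by at least a glucose threshold
(default 0.25 mmol/l); sub-threshold reversals are absorbed into the
current move. Sign patterns map to labels — (+,−) monophasic, (+,−,+)
biphasic, (+,−,+,−) triphasic — and anything else (no significant move, an
initial fall, more than four moves) is unclassified. The shape index is
v(120) − v(90) for mono-/biphasic curves and v(90) − v(60) for triphasic
ones, undefined otherwise. The published clinical rule specifies only the
threshold and the index arithmetic; the turning-point formalization here
is a reconstruction and may differ from the original on edge cases, so the
threshold is configurable and the move sequence is exposed for inspection.
Unclassified subjects are dropped pairwise, only from statistics involving
the shape index.

## Functional ANOVA

Group structure (BMI categories by default: underweight / normal /
overweight / obese, normal as reference) is modelled as
`x_lg(t) = β_ref(t) + β_g(t) + ε_lg(t)`; group mean curves are formed in
coefficient space and evaluated on a 1-minute grid (121 points). The
point-wise statistic is the conventional one-way F ratio, between-group
mean square over within-group mean square. Inference permutes whole-curve
group labels (B = 1000 by default, seeded): `p(t) = (1 + #{F_b(t) ≥
F(t)})/(B+1)` and the overall p uses the permutation distribution of
`max_t F`, with the add-one convention so p is never zero. Confidence
bands are point-wise normal-theory intervals, `β_g(t) ± z·SE(t)` with the
pooled per-time residual variance — not simultaneous bands. Pairwise
category comparisons refit on the two categories' subjects only, each pair
with a deterministic sub-seed. Subjects with missing labels are excluded
from this stage only, with counts logged; categories with a single subject
are dropped by the pipeline.

## Outcome categorization and multinomial regression

The later-pregnancy 2-h value is cut into seven ordered, left-closed
right-open intervals at (3.27, 3.89, 6.39, 6.90, 7.8, 8.84) mmol/l, the
broad middle interval [3.89, 6.39) serving as the reference; a boundary
value falls in the upper interval, so 7.8 lands in the interval that
defines gestational diabetes. Five model variants are fitted by maximum
likelihood (statsmodels MNLogit, Newton iterations): BMI plus either the
three FPC scores, or one simple summary measure at a time (fasting, 2-h,
AUC, shape index), all covariates continuous and untransformed, on
complete cases with dropped counts logged. Odds ratios are per unit of the
covariate with 95% Wald intervals. Between-category comparisons are Wald
contrasts on the two categories' coefficients using the joint estimated
covariance (the reference coefficient being identically zero); the
published tables do not state which test produced their between-category
column, so this is a documented reconstruction. Suspected separation
(|standardized coefficient| > 20) is flagged, not fatal.

## Synthetic cohort generator

The generator is the study-conditions stand-in for the undeposited raw
cohort. A subject's latent curve is

    x_i(t) = μ(t) + Σ_k z_ki m_k(t) + shift(BMI_i),

with μ the natural cubic interpolant of the time-point means (4.0, 5.7,
5.0, 4.5, 4.1) mmol/l, and three orthonormal modes on [0, 120]: a
normalized constant (level), a centered linear ramp (early-vs-late
contrast, shifting the peak) and one cosine cycle (oscillation). Modes 2–3
integrate to zero, so the AUC of a simulated record carries level
information only — that is what makes the near-perfect AUC–FPC1
correlation a structural property rather than a coincidence. Scores are
independent Gaussians with SDs (6.0, 1.87, 0.99), calibrated so the
variance shares are ≈ 0.89/0.086/0.024; the constant-mode SD of 6.0
corresponds to a subject-level curve-shift SD of 6.0/√120 ≈ 0.55 mmol/l.
Measurements add i.i.d. N(0, 0.15²) noise and are floored at 0.1 mmol/l.
BMI categories are drawn with the observed study proportions (17, 588,
274, 87)/966 and add level shifts (0, 0, +0.25, +0.55) mmol/l; a numeric
BMI is drawn uniformly within the category's range. The later 2-h outcome
is `5.5 + 0.05·z1 + 0.10·z2 + N(0, 1)`, floored at 0.1, linking the top
outcome categories to high level and late peak. A fraction 0.055 of
subjects lose one randomly chosen measurement. Everything is driven by one
seed; identical seeds give bit-identical cohorts, and `truth_bundle`
re-derives the ground truth for recovery tests only.

What the generator does **not** emulate: skewed glucose distributions,
within-subject error correlation, BMI-score dependence beyond the additive
level shift, recruitment-time drift, or any physiologic (ODE) dynamics.
Passing tests therefore demonstrate correctness of the statistical
machinery under a Gaussian three-mode world, not clinical validity on real
cohorts.

## Numerical choices, problem sizes, known limitations

- Evaluation grid 1 minute (121 points) for curves, bands and p curves;
  calibration simulations in the test suite use a 10-minute grid and
  cohorts of tens of subjects, which leaves the statistics unchanged while
  keeping the suite fast (the full default pipeline on n = 1000 with
  B = 1000 runs in well under a minute).
- With noise SD 0.15, the smoother's GCV choice (λ ≈ 1e2, verified close
  to the MISE optimum against the known truth) leaves a small noise floor
  in components 4–7: the first three components carry ≈ 98.8–99.0% of the
  variance on default cohorts, a hair under the 99% seen in the real data.
- The cosine mode is not exactly representable by a five-knot cubic
  spline; its minimum-roughness interpolant retains ≈ 91% of its L2 norm,
  which attenuates third-component scores correspondingly. Tests use the
  natural-spline attenuation factor as the oracle.
- Permutation p-values are bounded below by 1/(B+1); B = 1000 resolves
  p ≈ 0.001.
- The quartile panel display cross-classifies subjects by FPC1/FPC2 score
  quartiles into 3×3 panels; ties at the quartile boundaries go to the
  middle band.
- The mono/bi/triphasic rule is a reconstruction (see above); counts of
  unclassified curves are sensitive to its edge-case conventions.
- De-trending of measurements across recruitment years and ODE-based
  glucose–insulin modelling are out of scope.
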