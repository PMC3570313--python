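# ogttfda

Functional data analysis of oral glucose tolerance test (OGTT) curves.

Clinical studies routinely summarize an OGTT — five venous glucose
measurements over two hours after a 75 g load — by a fasting value, a 2-h
value or an area under the curve. Different curve shapes can share the
same summary, so shape information with physiologic meaning is lost.
`ogttfda` treats each subject's measurements as a noisy sample from a
smooth glucose curve and analyses the curves themselves. It is written for
biostatisticians and epidemiologists working with sparse repeated glucose
measurements (OGTT series, meal tests), and is fully testable without
access to any real cohort thanks to a built-in synthetic cohort generator.

## What it computes

1. **Penalized B-spline smoothing.** Each series `y_i(t_j) = x_i(t_j) +
   ε_ij` is converted to a curve by minimizing
   `‖Y − ΦC‖² + λ tr(CᵀRC)` with `R = ∫ D²φ D²φᵀ` (cubic splines, a knot
   at each design point, K = 7 basis functions on [0, 120]); the shared
   smoothing parameter λ is selected by pooled generalized
   cross-validation.
2. **Functional PCA.** Eigenfunctions ξ_k of the sample covariance
   operator maximize the variance of the subject scores
   `z_ki = ∫ ξ_k (x_i − μ) dt` subject to `∫ξ_k² = 1` and orthogonality;
   solved exactly in the coefficient basis via `W^{1/2} S W^{1/2}`. The
   leading components are interpretable as general level, time to peak and
   oscillation.
3. **Simple summary measures.** Fasting/30/60/90/2-h values, trapezoid
   AUC, and the rule-based curve-shape index (monophasic / biphasic /
   triphasic at a 0.25 mmol/l excursion threshold), plus their Pearson
   correlation table against the FPC scores and classical one-way ANOVA
   across BMI categories with Bonferroni post hoc tests.
4. **Functional ANOVA.** Per-BMI-category mean curves
   `x_lg(t) = β_ref(t) + β_g(t) + ε_lg(t)`, point-wise F statistics,
   permutation p(t) curves and an overall permutation p from the maximal
   F (B = 1000), with point-wise 95% confidence bands.
5. **Outcome regression.** The later-pregnancy 2-h glucose is cut into
   seven clinical categories and related to the early curve information by
   multinomial logistic regression (FPC scores or one simple summary at a
   time, plus BMI), with odds ratios, Wald intervals and between-category
   Wald contrasts.
6. **Synthetic cohorts.** Curves are simulated as a smooth mean trajectory
   plus three orthonormal modes with calibrated score SDs, BMI level
   shifts, measurement noise and a linked later outcome — the statistical
   structure the analysis assumes, with ground truth exposed for recovery
   testing.

## Worked example

Run the full pipeline on a simulated 1000-subject cohort:

```
$ ogttfda all --seed 5 --out demo
pipeline done: 945/1000 retained, lambda=206.8, top-3 variance shares [0.8794, 0.0873, 0.0242]
```

55 subjects (5.5%) have an incomplete OGTT and are excluded, as in the
cohort the generator mimics. The GCV-selected smoothing parameter is
λ ≈ 207, and the variance table (`demo/variance_table.csv`) shows the
classic concentration of between-curve variance in three modes:

```
component,eigenvalue,proportion,cumulative
1,42.395,0.8794,0.8794
2,4.2105,0.0873,0.9668
3,1.1658,0.0242,0.9910
```

— ~88% level, ~9% time-to-peak, ~2% oscillation, 99.1% together.
`demo/scores.csv` holds the per-subject FPC scores used downstream;
`demo/correlations.csv` shows AUC correlating with the level score at
r > 0.999 while the shape index tracks the oscillation score. The
permutation FANOVA across BMI categories (`demo/fanova_pairwise.csv`)
finds the level shifts the generator embeds:

```
category_a,category_b,p_overall
overweight,normal,0.000999
overweight,obese,0.000999
normal,obese,0.000999
normal,underweight,0.229770
```

obese and overweight differ from normal weight (p ≈ 0.001, the resolution
of B = 1000 permutations), underweight does not — underweight carries no
generator shift and only ~17 of 1000 subjects. `demo/regression_*.csv`
hold the seven-category outcome models; `demo/figures/` contains
plot-ready CSVs (fitted curves, mode-of-variation curves, FPC1/FPC2
quartile panels, FANOVA bands and p curves, outcome-category mean
curves).

The same stages are available as a library:

```python
import ogttfda as og

cohort = og.simulate_cohort(og.GeneratorConfig(n_subjects=1000, seed=5))
retained, report = og.filter_complete(cohort)
fit = og.fit_with_gcv(retained.glucose_matrix(), og.build_basis(),
                      subject_ids=retained.subject_ids)
fpca = og.run_fpca(fit)
print(og.variance_table(fpca).head(3))
```

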