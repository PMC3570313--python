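"""End-to-end orchestration: filter -> fit -> FPCA -> summaries ->
FANOVA -> outcome regression, with every stage's output written as CSV/JSON
and a run manifest recording seeds, the chosen smoothing parameter, counts
and the configuration hash.  Re-running with an identical configuration
reproduces identical outputs; all randomness flows from one global seed
expanded into per-stage streams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fanova as fanova_mod
from . import fpca as fpca_mod
from . import io as io_mod
from . import regression as reg_mod
from . import simulate as sim_mod
from . import summaries as sum_mod
from . import smoothing as smooth_mod

logger = logging.getLogger("ogttfda")


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Either ``input_path`` (+ layout / covariates file) names an existing
    cohort CSV, or ``generator`` enables the synthetic cohort.  Stage
    parameters mirror the individual modules' defaults.
    """

    output_dir: str = "ogttfda_output"
    seed: int = 0
    log_level: str = "INFO"

    input_path: str | None = None
    input_layout: str = "wide"
    covariates_path: str | None = None
    generator: sim_mod.GeneratorConfig | None = None

    spline_order: int = smooth_mod.DEFAULT_ORDER
    spline_breakpoints: tuple[float, ...] = io_mod.CANONICAL_TIMES
    lambda_mode: str = "shared"  # shared | per_curve | fixed
    lambda_fixed: float | None = None
    lambda_grid_min: float = 1e-4
    lambda_grid_max: float = 1e4
    lambda_grid_size: int = 25
    grid_step: float = 1.0

    n_components: int = 3
    shape_threshold: float = sum_mod.DEFAULT_SHAPE_THRESHOLD
    fanova_B: int = fanova_mod.DEFAULT_PERMUTATIONS
    fanova_reference: str = "normal"
    run_fanova: bool = True
    run_regression: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            for key in ("mean_anchor_values", "score_sds", "bmi_probs",
                        "bmi_level_shifts", "outcome_model"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            cfg.generator = sim_mod.GeneratorConfig(**gen)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report bundle (also on disk).

    The bundle maps stage names to in-memory results; every table is also
    written under ``config.output_dir``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 4)
    bundle: dict = {"config": config}

    # --- input ---
    if config.input_path is not None:
        cohort = io_mod.read_cohort(
            config.input_path, layout=config.input_layout,
            covariates=config.covariates_path,
        )
    elif config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=seeds[0])
        cohort = sim_mod.simulate_cohort(gen)
        io_mod.write_cohort(cohort, out / "cohort.csv", layout="wide")
    else:
        raise ValueError("config needs input_path or generator")

    # --- completeness filter ---
    retained, report = io_mod.filter_complete(cohort)
    io_mod.write_exclusion_report(
        report, out / "exclusions.csv", out / "exclusions.json"
    )
    bundle["cohort"] = retained
    bundle["exclusion_report"] = report
    if len(retained) < 2:
        raise ValueError("fewer than 2 complete records; cannot analyse")

    # --- curve fitting ---
    Y = retained.glucose_matrix()
    basis = smooth_mod.build_basis(config.spline_breakpoints, config.spline_order)
    grid_lams = np.logspace(
        np.log10(config.lambda_grid_min),
        np.log10(config.lambda_grid_max),
        config.lambda_grid_size,
    )
    if config.lambda_mode == "fixed":
        if config.lambda_fixed is None:
            raise ValueError("lambda_mode='fixed' requires lambda_fixed")
        fit = smooth_mod.fit_curves(
            Y, basis, config.lambda_fixed, subject_ids=retained.subject_ids
        )
    else:
        fit = smooth_mod.fit_with_gcv(
            Y, basis, mode=config.lambda_mode, grid=grid_lams,
            subject_ids=retained.subject_ids,
        )
    bundle["fit"] = fit
    grid = smooth_mod.default_grid(config.grid_step)
    coef_df = pd.DataFrame(
        fit.coefficients,
        columns=retained.subject_ids,
    )
    coef_df.insert(0, "basis_fn", np.arange(1, basis.n_basis + 1))
    coef_df.to_csv(out / "coefficients.csv", index=False)

    # --- FPCA ---
    fp = fpca_mod.run_fpca(fit)
    bundle["fpca"] = fp
    var_tab = fpca_mod.variance_table(fp)
    var_tab.to_csv(out / "variance_table.csv", index=False)
    scores = fpca_mod.scores_frame(fp, config.n_components)
    scores.to_csv(out / "scores.csv")
    for k in range(1, min(config.n_components, fp.n_components) + 1):
        fpca_mod.mode_curves(fp, k, grid=grid).to_csv(
            out / f"mode_curves_fpc{k}.csv", index=False
        )
    fpca_mod.quartile_assignments(fp).to_csv(out / "quartile_panels.csv")

    # --- simple summaries + correlations + classical ANOVA ---
    summaries = sum_mod.summarize_cohort(retained, config.shape_threshold)
    summaries.to_csv(out / "summaries.csv")
    bundle["summaries"] = summaries
    corr = sum_mod.correlation_table(scores, summaries)
    corr.to_csv(out / "correlations.csv")
    bundle["correlations"] = corr

    frame = retained.covariate_frame()
    anova_results = {}
    if frame["bmi_category"].notna().sum() >= 4:
        for measure in ("fasting", "v120", "auc", "shape_index"):
            col = summaries[measure if measure != "v120" else "v120"]
            try:
                anova_results[measure] = sum_mod.anova_simple_measures(
                    col.to_numpy(), frame["bmi_category"].to_numpy()
                )
            except ValueError:
                continue
        pd.DataFrame(
            [
                {"measure": m, "f": r["f"], "p": r["p"]}
                for m, r in anova_results.items()
            ]
        ).to_csv(out / "anova_simple_measures.csv", index=False)
    bundle["anova"] = anova_results

    # --- FANOVA across BMI categories ---
    if config.run_fanova and frame["bmi_category"].notna().sum() >= 4:
        labels = frame["bmi_category"].to_numpy(dtype=object)
        # FANOVA needs >= 2 subjects per category; singletons are dropped
        counts = pd.Series(labels[labels != None]).value_counts()  # noqa: E711
        too_small = set(counts[counts < 2].index)
        if too_small:
            logger.warning("FANOVA: dropping singleton categories %s", sorted(too_small))
            labels = np.where(np.isin(labels, list(too_small)), None, labels)
        fan = fanova_mod.run_fanova(
            fit, labels, reference=config.fanova_reference,
            B=config.fanova_B, seed=seeds[1], grid=grid,
        )
        bundle["fanova"] = fan
        for name, df in fan.to_frames().items():
            safe = name.replace("/", "_")
            df.to_csv(out / f"fanova_{safe}.csv", index=False)
        pairs = fanova_mod.pairwise_comparisons(
            fit, labels, B=config.fanova_B, seed=seeds[2], grid=grid
        )
        pairs.to_csv(out / "fanova_pairwise.csv", index=False)
        bundle["fanova_pairwise"] = pairs
        (out / "fanova_overall.json").write_text(
            json.dumps(
                {
                    "p_overall": fan.p_overall,
                    "B": fan.n_permutations,
                    "seed": fan.seed,
                    "pairwise": pairs.to_dict(orient="records"),
                },
                indent=2,
            )
        )

    # --- outcome regression ---
    if config.run_regression and frame["outcome_2h_late"].notna().any():
        cats = reg_mod.OutcomeCategories()
        labels = reg_mod.categorize_outcome(frame["outcome_2h_late"], cats)
        design = scores.join(summaries).join(frame[["bmi"]])
        fits = {}
        for model_id, covs in reg_mod.MODEL_COVARIATES.items():
            cols = [c for c in covs if c in design.columns] + ["bmi"]
            try:
                mfit = reg_mod.fit_multinomial(
                    labels, design[cols], cats, model_id=model_id
                )
            except ValueError as exc:
                logger.warning("model %s not fitted: %s", model_id, exc)
                continue
            fits[model_id] = mfit
            tables = []
            for cov in covs:
                if cov not in design.columns:
                    continue
                tab = mfit.table3_style(cov)
                tab.insert(0, "covariate", cov)
                adj = reg_mod.adjacent_comparisons(mfit, cov).set_index("category_a")
                tab["between_category_p"] = [
                    adj.loc[c, "p"] if c in adj.index else np.nan
                    for c in tab["category"]
                ]
                tables.append(tab)
            pd.concat(tables).to_csv(out / f"regression_{model_id}.csv", index=False)
            (out / f"regression_{model_id}_diag.json").write_text(
                json.dumps(
                    {
                        "model": model_id,
                        "n_used": mfit.n_used,
                        "n_dropped": mfit.n_dropped,
                        "converged": mfit.converged,
                        "separation_flag": mfit.separation_flag,
                        "log_likelihood": (
                            float(mfit.result.llf)
                            if np.isfinite(mfit.result.llf)
                            else None
                        ),
                    },
                    indent=2,
                )
            )
        bundle["regression"] = fits

    # --- manifest ---
    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_input": report.n_input,
        "n_retained": report.n_retained,
        "n_excluded": report.n_excluded,
        "lambda": fit.lambda_,
        "dof": fit.dof,
        "n_components": config.n_components,
        "variance_proportions": fp.variance_proportions[: config.n_components].tolist(),
        "fanova_B": config.fanova_B,
        "config": {
            k: v for k, v in config.to_dict().items() if not isinstance(v, dict)
        },
        "generator_config_hash": (
            config.generator.config_hash() if config.generator else None
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    logger.info(
        "pipeline complete: n=%d retained, lambda=%.4g, top-3 variance %s",
        report.n_retained,
        fit.lambda_,
        np.round(fp.variance_proportions[:3], 4),
    )
    return bundle


def export_figures(bundle: dict, output_dir: str | Path | None = None) -> list[Path]:
    """Write the plot-data CSVs for the standard display set.

    Fitted curves on the grid, mode-of-variation curves, quartile panels,
    FANOVA bands and p curves and outcome-category mean curves; rendering
    is left to the caller's plotting tool of choice.
    """
    config: PipelineConfig = bundle["config"]
    out = Path(output_dir or config.output_dir) / "figures"
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    fit = bundle["fit"]
    grid = smooth_mod.default_grid(config.grid_step)

    curves = smooth_mod.evaluate_curves(fit, grid)
    df = pd.DataFrame(curves.T, columns=fit.subject_ids)
    df.insert(0, "time_min", grid)
    p = out / "fitted_curves.csv"
    df.to_csv(p, index=False)
    written.append(p)

    fp = bundle["fpca"]
    for k in range(1, min(config.n_components, fp.n_components) + 1):
        p = out / f"mode_curves_fpc{k}.csv"
        fpca_mod.mode_curves(fp, k, grid=grid).to_csv(p, index=False)
        written.append(p)
    p = out / "quartile_panels.csv"
    fpca_mod.quartile_assignments(fp).to_csv(p)
    written.append(p)

    if "fanova" in bundle:
        for name, frame in bundle["fanova"].to_frames().items():
            p = out / f"fanova_{name.replace('/', '_')}.csv"
            frame.to_csv(p, index=False)
            written.append(p)

    cohort = bundle["cohort"]
    frame = cohort.covariate_frame()
    if frame["outcome_2h_late"].notna().any():
        labels = reg_mod.categorize_outcome(frame["outcome_2h_late"])
        rows = []
        for cat in labels.dropna().unique():
            mask = (labels == cat).to_numpy()
            mean_curve = curves[mask].mean(axis=0)
            rows.append(
                pd.DataFrame(
                    {"category": cat, "time_min": grid, "mean_glucose": mean_curve}
                )
            )
        p = out / "category_mean_curves.csv"
        pd.concat(rows).to_csv(p, index=False)
        written.append(p)
    return written


__all__ = ["PipelineConfig", "run_pipeline", "export_figures"]
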