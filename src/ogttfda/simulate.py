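"""Synthetic OGTT cohort generator.

Emulates the statistical structure the analysis pipeline assumes: a smooth
population mean glucose trajectory through the canonical time-point means,
three dominant orthonormal modes of between-subject variation, additive
BMI-category level shifts, independent measurement noise, a later-pregnancy
2-h outcome linked to the first two mode scores, and a small fraction of
subjects with one missing measurement.

The default modes are interpretable stand-ins for the empirically observed
components: a normalized constant (overall level), a centered linear ramp
(early-vs-late contrast, shifting the time of the peak) and one cosine
cycle (oscillation).  They are mutually orthonormal in L2[0, 120] and the
latter two integrate to zero, so the area under a simulated curve carries
level information only.  Default score SDs (6.0, 1.87, 0.99) make the three
modes' variance shares approximately 0.89 / 0.086 / 0.024.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .io import BMI_CATEGORIES, CANONICAL_TIMES, Cohort, GlucoseRecord

logger = logging.getLogger("ogttfda")

_T0, _T1 = 0.0, 120.0

#: BMI numeric ranges (kg/m^2) used to draw a value within a category.
_BMI_RANGES = {
    "underweight": (17.0, 18.5),
    "normal": (18.5, 25.0),
    "overweight": (25.0, 30.0),
    "obese": (30.0, 40.0),
}


def default_modes() -> tuple[Callable, Callable, Callable]:
    """Three orthonormal modes on [0, 120].

    mode1: constant level, ``1/sqrt(120)``;
    mode2: centered ramp, ``(t - 60)/sqrt(144000)``;
    mode3: one cosine cycle, ``cos(2 pi t / 120)/sqrt(60)``.
    Orthogonality follows from parity/symmetry; modes 2 and 3 integrate to
    zero over the test.
    """

    def mode1(t):
        return np.full_like(np.asarray(t, dtype=float), 1.0 / math.sqrt(120.0))

    def mode2(t):
        return (np.asarray(t, dtype=float) - 60.0) / math.sqrt(144000.0)

    def mode3(t):
        return np.cos(2.0 * np.pi * np.asarray(t, dtype=float) / 120.0) / math.sqrt(60.0)

    return mode1, mode2, mode3


# Observed BMI-category proportions in the study population (17, 588, 274,
# 87 of 966 women with known BMI).
DEFAULT_BMI_PROBS = (17 / 966, 588 / 966, 274 / 966, 87 / 966)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    ``mean_anchor_values`` are the canonical time-point means (mmol/l);
    ``score_sds`` the SDs of the three mode scores; ``noise_sd`` the
    measurement error SD (mmol/l); ``bmi_level_shifts`` additive curve
    shifts per BMI category (mmol/l); ``outcome_model`` the coefficients
    (a0, a1, a2, noise_sd) of the linear link from the first two scores to
    the later 2-h value; ``missing_fraction`` the share of subjects losing
    one random measurement.
    """

    n_subjects: int = 1000
    mean_anchor_values: tuple[float, ...] = (4.0, 5.7, 5.0, 4.5, 4.1)
    score_sds: tuple[float, float, float] = (6.0, 1.87, 0.99)
    noise_sd: float = 0.15
    bmi_probs: tuple[float, ...] = DEFAULT_BMI_PROBS
    bmi_level_shifts: tuple[float, ...] = (0.0, 0.0, 0.25, 0.55)
    outcome_model: tuple[float, float, float, float] = (5.5, 0.05, 0.10, 1.0)
    missing_fraction: float = 0.055
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(self.mean_anchor_values) != len(CANONICAL_TIMES):
            raise ValueError("need one mean anchor per canonical time")
        if any(s < 0 for s in self.score_sds):
            raise ValueError("score SDs must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.bmi_probs) != len(BMI_CATEGORIES) or not math.isclose(
            sum(self.bmi_probs), 1.0, abs_tol=1e-9
        ):
            raise ValueError("bmi_probs must have 4 entries summing to 1")
        if any(p < 0 for p in self.bmi_probs):
            raise ValueError("bmi_probs must be non-negative")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")

    def mean_curve(self) -> CubicSpline:
        """Natural cubic interpolant through the anchor values."""
        return CubicSpline(
            np.asarray(CANONICAL_TIMES), np.asarray(self.mean_anchor_values),
            bc_type="natural",
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass(frozen=True)
class TruthBundle:
    """Generator ground truth, for recovery tests only.

    Holds per-subject mode scores, BMI level shifts and the noiseless curve
    machinery; analysis stages must never consume this.
    """

    config: GeneratorConfig
    subject_ids: tuple[str, ...]
    scores: np.ndarray  # n x 3
    bmi_shifts: np.ndarray  # n
    bmi_categories: tuple[str, ...]

    def true_curves(self, grid: np.ndarray | Sequence[float]) -> np.ndarray:
        """n x |grid| noiseless curves (mean + modes + BMI shift)."""
        grid = np.asarray(grid, dtype=float)
        mean = self.config.mean_curve()(grid)
        modes = np.vstack([m(grid) for m in default_modes()])  # 3 x T
        return mean[None, :] + self.scores @ modes + self.bmi_shifts[:, None]


def _generate(config: GeneratorConfig) -> tuple[Cohort, TruthBundle]:
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    z = rng.standard_normal((n, 3)) * np.asarray(config.score_sds)
    cat_idx = rng.choice(len(BMI_CATEGORIES), size=n, p=np.asarray(config.bmi_probs))
    cats = tuple(BMI_CATEGORIES[i] for i in cat_idx)
    shifts = np.asarray(config.bmi_level_shifts)[cat_idx]
    bmi_lo = np.asarray([_BMI_RANGES[c][0] for c in cats])
    bmi_hi = np.asarray([_BMI_RANGES[c][1] for c in cats])
    bmi = rng.uniform(bmi_lo, bmi_hi)

    t = np.asarray(CANONICAL_TIMES)
    mean = config.mean_curve()(t)
    modes = np.vstack([m(t) for m in default_modes()])
    truth_at_design = mean[None, :] + z @ modes + shifts[:, None]
    obs = truth_at_design + rng.normal(0.0, config.noise_sd, size=(n, len(t)))
    obs = np.maximum(obs, 0.1)  # glucose is physically positive

    a0, a1, a2, out_sd = config.outcome_model
    outcome = a0 + a1 * z[:, 0] + a2 * z[:, 1] + rng.normal(0.0, out_sd, size=n)
    outcome = np.maximum(outcome, 0.1)

    n_missing = int(round(config.missing_fraction * n))
    missing_subjects = rng.choice(n, size=n_missing, replace=False)
    missing_time = rng.integers(0, len(t), size=n_missing)
    drop = {int(s): int(j) for s, j in zip(missing_subjects, missing_time)}

    width = max(4, len(str(n)))
    ids = tuple(f"S{i:0{width}d}" for i in range(1, n + 1))
    records = []
    for i in range(n):
        keep = [j for j in range(len(t)) if drop.get(i) != j]
        records.append(
            GlucoseRecord(
                subject_id=ids[i],
                times=tuple(t[keep]),
                values=tuple(obs[i, keep]),
                bmi=float(bmi[i]),
                bmi_category=cats[i],
                outcome_2h_late=float(outcome[i]),
            )
        )
    cohort = Cohort(
        records=records,
        metadata={
            "generator": "ogttfda.simulate",
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_subjects": n,
            "n_incomplete": n_missing,
        },
    )
    truth = TruthBundle(
        config=config,
        subject_ids=ids,
        scores=z,
        bmi_shifts=shifts,
        bmi_categories=cats,
    )
    return cohort, truth


def simulate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a cohort under ``config``; fixed seed gives identical output."""
    cohort, _ = _generate(config)
    logger.info(
        "simulated cohort: n=%d, %d incomplete, seed=%d",
        len(cohort),
        cohort.metadata["n_incomplete"],
        config.seed,
    )
    return cohort


def truth_bundle(config: GeneratorConfig, cohort: Cohort) -> TruthBundle:
    """Recover the generator truth for a cohort produced under ``config``.

    Regenerates deterministically and verifies the cohort matches; raises
    on config/cohort mismatch.
    """
    regenerated, truth = _generate(config)
    if len(regenerated) != len(cohort) or any(
        a.subject_id != b.subject_id
        or a.times != b.times
        or not np.allclose(a.values, b.values)
        for a, b in zip(regenerated, cohort)
    ):
        raise ValueError("cohort does not match the given generator config/seed")
    return truth


__all__ = [
    "GeneratorConfig",
    "TruthBundle",
    "DEFAULT_BMI_PROBS",
    "default_modes",
    "simulate_cohort",
    "truth_bundle",
]
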