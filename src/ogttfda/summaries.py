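"""Simple summary measures of the OGTT series and their comparison with
FPC scores.

Covers the traditional per-subject measures — fasting, 30/60/90-min and 2-h
values, trapezoid AUC — plus the rule-based curve-shape index: the series
is compressed into significant directional moves (an excursion counts only
when it exceeds a glucose threshold, 0.25 mmol/l by default) and the sign
pattern labels the curve monophasic (+,-), biphasic (+,-,+) or triphasic
(+,-,+,-); anything else, including curves with no significant excursion or
an initial fall, is unclassified and carries no index.  The index itself is
the 2-h minus 90-min value for mono-/biphasic curves and the 90-min minus
60-min value for triphasic ones.

The exact published decision rule for accumulating sub-threshold moves is
not fully specified in the clinical literature; the formalization here
(track the running extremum of the current move, accept a reversal only
when it exceeds the threshold from that extremum) is documented in the
methods note.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CANONICAL_TIMES, Cohort, GlucoseRecord

logger = logging.getLogger("ogttfda")

DEFAULT_SHAPE_THRESHOLD = 0.25  # mmol/l

_PATTERNS = {
    (1, -1): "monophasic",
    (1, -1, 1): "biphasic",
    (1, -1, 1, -1): "triphasic",
}


@dataclass(frozen=True)
class ShapeClassification:
    """Curve-shape label, significant-move sign sequence and shape index."""

    label: str
    shape_index: float
    significant_moves: tuple[int, ...]

    @property
    def is_classified(self) -> bool:
        return self.label != "unclassified"


def _require_complete(record: GlucoseRecord) -> np.ndarray:
    if not record.is_complete:
        missing = sorted(set(CANONICAL_TIMES) - set(record.times))
        raise ValueError(
            f"{record.subject_id}: incomplete record (missing minutes "
            f"{[int(t) for t in missing]})"
        )
    return np.array([record.value_at(t) for t in CANONICAL_TIMES])


def auc_trapezoid(record: GlucoseRecord) -> float:
    """Trapezoid-rule area under the five raw measurements (mmol*min/l)."""
    v = _require_complete(record)
    return float(np.trapezoid(v, np.asarray(CANONICAL_TIMES)))


def significant_moves(
    values: np.ndarray, threshold: float = DEFAULT_SHAPE_THRESHOLD
) -> tuple[int, ...]:
    """Signs of the threshold-passing excursions of a short series.

    A move starts when the series departs from the running extremum of the
    previous accepted move (initially the fasting value) by at least
    ``threshold``; while a move is in progress its extremum tracks the
    series, and sub-threshold reversals are absorbed.
    """
    moves: list[int] = []
    anchor = float(values[0])
    direction = 0
    for v in map(float, values[1:]):
        d = v - anchor
        if direction == 0:
            if abs(d) >= threshold:
                direction = 1 if d > 0 else -1
                moves.append(direction)
                anchor = v
        elif d * direction > 0:
            anchor = v  # extend the current move to its new extremum
        elif abs(d) >= threshold:
            direction = -direction
            moves.append(direction)
            anchor = v
    return tuple(moves)


def classify_shape(
    record: GlucoseRecord, threshold: float = DEFAULT_SHAPE_THRESHOLD
) -> ShapeClassification:
    """Label a complete record mono-/bi-/triphasic or unclassified.

    The shape index is value(120) - value(90) for monophasic and biphasic
    curves and value(90) - value(60) for triphasic curves; unclassified
    curves have an undefined (NaN) index.
    """
    v = _require_complete(record)
    moves = significant_moves(v, threshold)
    label = _PATTERNS.get(moves, "unclassified")
    if label in ("monophasic", "biphasic"):
        index = float(v[4] - v[3])
    elif label == "triphasic":
        index = float(v[3] - v[2])
    else:
        index = math.nan
    return ShapeClassification(label=label, shape_index=index, significant_moves=moves)


def summarize_cohort(
    cohort: Cohort, threshold: float = DEFAULT_SHAPE_THRESHOLD
) -> pd.DataFrame:
    """Per-subject table of simple summary measures.

    Columns: fasting, v30, v60, v90, v120 (mmol/l), auc (mmol*min/l),
    shape_label, shape_index.  Requires complete records.
    """
    rows = []
    for r in cohort:
        v = _require_complete(r)
        shape = classify_shape(r, threshold)
        rows.append(
            {
                "subject_id": r.subject_id,
                "fasting": v[0],
                "v30": v[1],
                "v60": v[2],
                "v90": v[3],
                "v120": v[4],
                "auc": auc_trapezoid(r),
                "shape_label": shape.label,
                "shape_index": shape.shape_index,
            }
        )
    df = pd.DataFrame(rows).set_index("subject_id")
    counts = df["shape_label"].value_counts()
    logger.info("shape classification counts: %s", counts.to_dict())
    return df


def correlation_table(
    scores: pd.DataFrame, measures: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlations of measurements, summaries and FPC scores.

    Unclassified subjects contribute NaN shape indices and are dropped
    pairwise, i.e. only from correlations involving the shape index.
    Zero-variance columns yield NaN (flagged in the log), not an error.
    """
    joined = measures.join(scores, how="inner")
    numeric = joined.select_dtypes(include=[np.number])
    if len(numeric) < 3:
        raise ValueError("need at least 3 subjects for a correlation table")
    zero_var = [c for c in numeric.columns if numeric[c].std(skipna=True) == 0]
    if zero_var:
        logger.warning("zero-variance columns, correlations undefined: %s", zero_var)
    return numeric.corr(method="pearson", min_periods=3)


def anova_simple_measures(
    values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray
) -> dict:
    """One-way ANOVA across groups with Bonferroni-corrected post hoc tests.

    Returns ``{"f": F, "p": p, "pairwise": DataFrame}`` where the pairwise
    table holds the two-sample t p-values multiplied by the number of
    comparisons (capped at 1); pairs with a group of fewer than 2 members
    are reported as undefined (NaN).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = np.isfinite(values) & (groups != None)  # noqa: E711
    values, groups = values[keep], groups[keep]
    levels = [g for g in pd.unique(groups)]
    samples = {g: values[groups == g] for g in levels}
    usable = [g for g in levels if len(samples[g]) >= 2]
    if len(usable) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")

    if all(np.var(samples[g]) == 0 for g in usable) and len(
        {samples[g][0] for g in usable}
    ) == 1:
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*[samples[g] for g in usable])

    pairs = list(itertools.combinations(levels, 2))
    n_comp = len(pairs)
    rows = []
    for ga, gb in pairs:
        if len(samples[ga]) < 2 or len(samples[gb]) < 2:
            t, p_adj = math.nan, math.nan
        else:
            t, p_raw = stats.ttest_ind(samples[ga], samples[gb], equal_var=True)
            p_adj = min(1.0, p_raw * n_comp)
        rows.append(
            {"group_a": ga, "group_b": gb, "t": t, "p_bonferroni": p_adj}
        )
    return {
        "f": float(f_stat),
        "p": float(p_val),
        "pairwise": pd.DataFrame(rows),
        "group_sizes": {g: int(len(samples[g])) for g in levels},
    }


__all__ = [
    "ShapeClassification",
    "DEFAULT_SHAPE_THRESHOLD",
    "auc_trapezoid",
    "significant_moves",
    "classify_shape",
    "summarize_cohort",
    "correlation_table",
    "anova_simple_measures",
]
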