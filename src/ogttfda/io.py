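"""Cohort input/output and descriptive statistics.

Subject-level OGTT data live in :class:`GlucoseRecord` objects: timed glucose
measurements (mmol/l) at minutes within [0, 120] plus optional covariates
(BMI, BMI category, late-pregnancy 2-h glucose).  A :class:`Cohort` is a
collection of records with unique subject ids and free-form provenance
metadata.

Files are plain CSV in one of two layouts:

* ``long``: columns ``subject_id, time_min, glucose_mmol_l`` (one row per
  measurement); covariates come from a separate file keyed by ``subject_id``.
* ``wide``: one row per subject with columns ``glucose_0, glucose_30,
  glucose_60, glucose_90, glucose_120`` plus any covariate columns.

Missing measurements are absent cells (or the tokens NA/NaN/empty), never
sentinel numbers.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("ogttfda")

#: The study's sampling design: five measurements over the 2-h test.
CANONICAL_TIMES: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0)

#: WHO BMI classes used throughout (reference category = normal weight).
BMI_CATEGORIES: tuple[str, ...] = ("underweight", "normal", "overweight", "obese")

_WIDE_GLUCOSE_COLS = tuple(f"glucose_{int(t)}" for t in CANONICAL_TIMES)
_COVARIATE_COLS = ("bmi", "bmi_category", "outcome_2h_late")
_MISSING_TOKENS = {"", "na", "nan", "none", "null", "."}


class CohortFormatError(ValueError):
    """Malformed cohort file (missing/ill-named columns)."""


class CohortParseError(ValueError):
    """Unparseable cell content, with the offending row index."""


@dataclass(frozen=True)
class GlucoseRecord:
    """One subject's timed glucose measurements with covariates.

    ``times`` are minutes after the glucose load, strictly increasing within
    [0, 120]; ``values`` are the aligned glucose concentrations in mmol/l.
    Only present measurements are stored; a complete record has all five
    canonical times.
    """

    subject_id: str
    times: tuple[float, ...]
    values: tuple[float, ...]
    bmi: float | None = None
    bmi_category: str | None = None
    outcome_2h_late: float | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError(
                f"{self.subject_id}: {len(self.times)} times vs "
                f"{len(self.values)} values"
            )
        t = np.asarray(self.times, dtype=float)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > 120):
            raise ValueError(
                f"{self.subject_id}: times must be strictly increasing within [0, 120]"
            )
        v = np.asarray(self.values, dtype=float)
        if v.size and (not np.all(np.isfinite(v)) or np.any(v <= 0)):
            raise ValueError(f"{self.subject_id}: glucose values must be finite and > 0")
        if self.bmi_category is not None and self.bmi_category not in BMI_CATEGORIES:
            raise ValueError(
                f"{self.subject_id}: unknown BMI category {self.bmi_category!r}"
            )

    @property
    def is_complete(self) -> bool:
        """True iff all five canonical times are present."""
        return set(self.times) == set(CANONICAL_TIMES)

    @property
    def has_extra_times(self) -> bool:
        return bool(set(self.times) - set(CANONICAL_TIMES))

    def value_at(self, time: float) -> float:
        """Measurement at ``time`` in minutes; NaN when absent."""
        for t, v in zip(self.times, self.values):
            if t == time:
                return v
        return math.nan


@dataclass
class Cohort:
    """A collection of :class:`GlucoseRecord` with provenance metadata."""

    records: list[GlucoseRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def glucose_matrix(self) -> np.ndarray:
        """J x n matrix of the canonical measurements (rows = times).

        Requires every record to be complete; raises otherwise.
        """
        cols = []
        for r in self.records:
            if not r.is_complete:
                missing = sorted(set(CANONICAL_TIMES) - set(r.times))
                raise ValueError(
                    f"{r.subject_id}: incomplete record (missing minutes {missing})"
                )
            cols.append([r.value_at(t) for t in CANONICAL_TIMES])
        return np.asarray(cols, dtype=float).T

    def covariate_frame(self) -> pd.DataFrame:
        """Per-subject table of glucose values and covariates.

        Glucose columns are NaN where the measurement is missing.
        """
        rows = []
        for r in self.records:
            row: dict = {"subject_id": r.subject_id}
            for t, col in zip(CANONICAL_TIMES, _WIDE_GLUCOSE_COLS):
                row[col] = r.value_at(t)
            row["bmi"] = math.nan if r.bmi is None else r.bmi
            row["bmi_category"] = r.bmi_category
            row["outcome_2h_late"] = (
                math.nan if r.outcome_2h_late is None else r.outcome_2h_late
            )
            rows.append(row)
        return pd.DataFrame(rows).set_index("subject_id")


@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping of the completeness filter."""

    n_input: int
    n_retained: int
    excluded_ids: tuple[str, ...]
    reasons: Mapping[str, str]

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": list(self.excluded_ids),
                "reason": [self.reasons[i] for i in self.excluded_ids],
            }
        )

    def to_metadata(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
            "excluded_fraction_pct": percent(self.n_excluded, self.n_input),
        }


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage rounded half-away-from-zero to ``decimals`` places.

    Matches the rounding convention of clinical tables (e.g. 57/1031 -> 5.5).
    """
    if denominator == 0:
        return math.nan
    x = 100.0 * numerator / denominator
    factor = 10.0**decimals
    return math.floor(x * factor + 0.5) / factor


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


def _parse_glucose(raw: object, row_index: int, column: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    s = str(raw).strip()
    if s.lower() in _MISSING_TOKENS:
        return math.nan
    try:
        return float(s)
    except ValueError:
        raise CohortParseError(
            f"non-numeric glucose value {raw!r} in column {column!r} at row {row_index}"
        ) from None


def _covariates_from_row(row: Mapping) -> dict:
    out: dict = {}
    if "bmi" in row and not pd.isna(row["bmi"]):
        out["bmi"] = float(row["bmi"])
    if "bmi_category" in row and not pd.isna(row["bmi_category"]):
        out["bmi_category"] = str(row["bmi_category"])
    if "outcome_2h_late" in row and not pd.isna(row["outcome_2h_late"]):
        out["outcome_2h_late"] = float(row["outcome_2h_late"])
    return out


def read_cohort(
    path: str | Path,
    layout: str = "wide",
    covariates: str | Path | None = None,
) -> Cohort:
    """Read a cohort CSV in ``long`` or ``wide`` layout.

    Missing cells (empty or NA-like tokens) become missing measurements.
    ``covariates`` optionally names a second CSV keyed by ``subject_id``
    carrying bmi / bmi_category / outcome_2h_late.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout not in ("long", "wide"):
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)

    cov_map: dict[str, dict] = {}
    if covariates is not None:
        cov_df = pd.read_csv(covariates)
        if "subject_id" not in cov_df.columns:
            raise CohortFormatError("covariates file lacks column 'subject_id'")
        for _, row in cov_df.iterrows():
            cov_map[str(row["subject_id"])] = _covariates_from_row(row)

    records: list[GlucoseRecord] = []
    if layout == "long":
        required = ("subject_id", "time_min", "glucose_mmol_l")
        for col in required:
            if col not in df.columns:
                raise CohortFormatError(f"long layout requires column {col!r}")
        for sid, grp in df.groupby("subject_id", sort=False):
            times, values = [], []
            for idx, row in grp.iterrows():
                v = _parse_glucose(row["glucose_mmol_l"], int(idx), "glucose_mmol_l")
                if math.isnan(v):
                    continue
                times.append(float(row["time_min"]))
                values.append(v)
            order = np.argsort(times)
            records.append(
                GlucoseRecord(
                    subject_id=str(sid),
                    times=tuple(np.asarray(times)[order]),
                    values=tuple(np.asarray(values)[order]),
                    **cov_map.get(str(sid), {}),
                )
            )
    else:
        if "subject_id" not in df.columns:
            raise CohortFormatError("wide layout requires column 'subject_id'")
        for col in _WIDE_GLUCOSE_COLS:
            if col not in df.columns:
                raise CohortFormatError(f"wide layout requires column {col!r}")
        for idx, row in df.iterrows():
            times, values = [], []
            for t, col in zip(CANONICAL_TIMES, _WIDE_GLUCOSE_COLS):
                v = _parse_glucose(row[col], int(idx), col)
                if not math.isnan(v):
                    times.append(t)
                    values.append(v)
            cov = _covariates_from_row(
                {k: (row[k] if row[k] != "" else math.nan) for k in _COVARIATE_COLS if k in df.columns}
            )
            cov.update(cov_map.get(str(row["subject_id"]), {}))
            records.append(
                GlucoseRecord(
                    subject_id=str(row["subject_id"]),
                    times=tuple(times),
                    values=tuple(values),
                    **cov,
                )
            )
    return Cohort(records=records, metadata={"source": str(path), "layout": layout})


def write_cohort(cohort: Cohort, path: str | Path, layout: str = "wide") -> None:
    """Write a cohort back to CSV in the requested layout."""
    path = Path(path)
    if layout == "long":
        rows = [
            {"subject_id": r.subject_id, "time_min": t, "glucose_mmol_l": v}
            for r in cohort
            for t, v in zip(r.times, r.values)
        ]
        pd.DataFrame(rows, columns=["subject_id", "time_min", "glucose_mmol_l"]).to_csv(
            path, index=False
        )
    elif layout == "wide":
        frame = cohort.covariate_frame().reset_index()
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")


# ---------------------------------------------------------------------------
# Completeness filter and group comparison
# ---------------------------------------------------------------------------


def filter_complete(cohort: Cohort) -> tuple[Cohort, ExclusionReport]:
    """Split a cohort into complete records and an exclusion report.

    A record is retained iff it carries non-missing values at exactly the
    five canonical minutes {0, 30, 60, 90, 120}; records with measurements
    at non-canonical times are rejected as protocol deviations.
    """
    retained: list[GlucoseRecord] = []
    reasons: dict[str, str] = {}
    for r in cohort:
        if r.has_extra_times:
            reasons[r.subject_id] = "non-canonical measurement times"
        elif not r.is_complete:
            missing = sorted(set(CANONICAL_TIMES) - set(r.times))
            reasons[r.subject_id] = "missing minutes " + ",".join(
                str(int(t)) for t in missing
            )
        else:
            retained.append(r)
    report = ExclusionReport(
        n_input=len(cohort),
        n_retained=len(retained),
        excluded_ids=tuple(reasons),
        reasons=reasons,
    )
    meta = dict(cohort.metadata)
    meta["completeness_filter"] = report.to_metadata()
    logger.info(
        "completeness filter: %d in, %d retained, %d excluded (%.1f%%)",
        report.n_input,
        report.n_retained,
        report.n_excluded,
        percent(report.n_excluded, report.n_input) if report.n_input else float("nan"),
    )
    return Cohort(records=retained, metadata=meta), report


def write_exclusion_report(
    report: ExclusionReport, csv_path: str | Path, json_path: str | Path | None = None
) -> None:
    report.to_frame().to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report.to_metadata(), indent=2))


def compare_groups(
    a: Cohort, b: Cohort, variables: Sequence[str] | None = None
) -> pd.DataFrame:
    """Descriptive comparison of two cohorts, variable by variable.

    Continuous variables get a two-sample t test (Welch), categorical ones a
    chi-square test of independence.  Zero-variance continuous variables in
    both groups are reported as undefined rather than raising.
    """
    fa, fb = a.covariate_frame(), b.covariate_frame()
    if variables is None:
        variables = [c for c in fa.columns if c in fb.columns]
    rows = []
    for var in variables:
        if var not in fa.columns or var not in fb.columns:
            raise KeyError(f"variable {var!r} not present in both cohorts")
        xa, xb = fa[var].dropna(), fb[var].dropna()
        if fa[var].dtype == object or fb[var].dtype == object:
            counts = pd.crosstab(
                pd.concat([xa, xb]).to_numpy(),
                np.repeat(["a", "b"], [len(xa), len(xb)]),
            )
            if counts.shape[0] < 2 or counts.shape[1] < 2:
                stat, p, test = math.nan, math.nan, "undefined"
            else:
                stat, p, _, _ = stats.chi2_contingency(
                    counts.to_numpy(), correction=False
                )
                test = "chi2"
        else:
            if len(xa) < 2 or len(xb) < 2 or (xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0):
                stat, p, test = math.nan, math.nan, "undefined"
            else:
                stat, p = stats.ttest_ind(xa, xb, equal_var=False)
                test = "t"
        rows.append(
            {
                "variable": var,
                "test": test,
                "statistic": stat,
                "p_value": p,
                "n_a": len(xa),
                "n_b": len(xb),
                "mean_a": xa.mean() if test == "t" else math.nan,
                "mean_b": xb.mean() if test == "t" else math.nan,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "CANONICAL_TIMES",
    "BMI_CATEGORIES",
    "GlucoseRecord",
    "Cohort",
    "ExclusionReport",
    "CohortFormatError",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "filter_complete",
    "write_exclusion_report",
    "compare_groups",
    "percent",
]
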