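"""Outcome derivation and predictor preparation.

Thirteen outcome measures are derived from raw clinical columns of a
long-format visit table:

* four gait *overall speeds* (dual-task speed + single-task speed) and four
  *dual-task costs* (dual-task speed - single-task speed), one pair per
  dual-task condition (walking while subtracting serial 7s, subtracting
  while walking, walking while checking boxes, checking boxes while
  walking);
* CERAD total score, word-list learning and word-list recall;
* Trail Making Test composites: overall speed TMT A + TMT B and cognitive
  flexibility TMT B - TMT A.

All outcomes are then oriented so that *higher = worse*: speeds and
correct-item counts are negated, completion times kept.  Predictors are
imputed per subject by forward- then backward-filling (predictors are
assumed to change only when re-measured); subjects missing a predictor
entirely are excluded.  Outcomes are never imputed here - the Bayesian
model handles missing outcome cells through its likelihood instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OUTCOME_NAMES",
    "OUTCOME_ORIENTATION",
    "GAIT_PAIRS",
    "RAW_GAIT_COLUMNS",
    "RAW_COGNITIVE_COLUMNS",
    "TMT_A_CAP",
    "TMT_B_CAP",
    "derive_gait_outcomes",
    "derive_cognitive_outcomes",
    "derive_outcomes",
    "orient_outcomes",
    "impute_predictors",
    "Standardizer",
    "select_visits",
    "DesignMatrix",
    "build_design",
]

TMT_A_CAP = 180.0  # administration discontinued after 180 s
TMT_B_CAP = 300.0  # administration discontinued after 300 s

#: dual-task condition -> (dual-task speed column, single-task speed column)
GAIT_PAIRS: dict[str, tuple[str, str]] = {
    "walk_subtract": ("gait_dual_walk_while_subtract", "gait_single_walk_max"),
    "subtract_walk": ("gait_dual_subtract_while_walk", "gait_single_subtract"),
    "walk_box": ("gait_dual_walk_while_box", "gait_single_walk_max"),
    "box_walk": ("gait_dual_box_while_walk", "gait_single_box"),
}

RAW_GAIT_COLUMNS = [
    "gait_single_walk_habitual",
    "gait_single_walk_max",
    "gait_single_box",
    "gait_single_subtract",
    "gait_dual_walk_while_subtract",
    "gait_dual_subtract_while_walk",
    "gait_dual_walk_while_box",
    "gait_dual_box_while_walk",
]

RAW_COGNITIVE_COLUMNS = [
    "cerad_total",
    "wordlist_learning",
    "wordlist_recall",
    "tmt_a",
    "tmt_b",
]

#: canonical outcome order: 4 overall speeds, 4 dual-task costs, 5 cognitive
OUTCOME_NAMES = [
    "overall_walk_subtract",
    "overall_subtract_walk",
    "overall_walk_box",
    "overall_box_walk",
    "cost_walk_subtract",
    "cost_subtract_walk",
    "cost_walk_box",
    "cost_box_walk",
    "cerad_total",
    "wordlist_learning",
    "wordlist_recall",
    "tmt_sum",
    "tmt_diff",
]

#: +1: higher already means worse (times); -1: flip (speeds, counts)
OUTCOME_ORIENTATION = {name: -1.0 for name in OUTCOME_NAMES}
OUTCOME_ORIENTATION["tmt_sum"] = 1.0
OUTCOME_ORIENTATION["tmt_diff"] = 1.0


def _clean_speed(value):
    """Negative raw speeds are physically impossible -> invalid cell."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if value < 0:
        return np.nan
    return float(value)


def derive_gait_outcomes(row) -> dict[str, float]:
    """Derive the 8 gait composites from one visit's raw speeds.

    For each dual-task condition: overall speed = dual + single and
    dual-task cost = dual - single.  Missing or invalid (negative) inputs
    propagate to missing composites.
    """
    out: dict[str, float] = {}
    for condition, (dual_col, single_col) in GAIT_PAIRS.items():
        dual = _clean_speed(row.get(dual_col, np.nan))
        single = _clean_speed(row.get(single_col, np.nan))
        out[f"overall_{condition}"] = dual + single
        out[f"cost_{condition}"] = dual - single
    return out


def derive_cognitive_outcomes(row) -> dict[str, float]:
    """Derive the 5 cognitive outcomes from one visit's raw scores.

    TMT times above the administration caps (180 s part A, 300 s part B)
    are invalid cells; missingness propagates to the two TMT composites.
    """
    tmt_a = row.get("tmt_a", np.nan)
    tmt_b = row.get("tmt_b", np.nan)
    if tmt_a is not None and not np.isnan(tmt_a) and (tmt_a > TMT_A_CAP or tmt_a < 0):
        tmt_a = np.nan
    if tmt_b is not None and not np.isnan(tmt_b) and (tmt_b > TMT_B_CAP or tmt_b < 0):
        tmt_b = np.nan
    return {
        "cerad_total": float(row.get("cerad_total", np.nan)),
        "wordlist_learning": float(row.get("wordlist_learning", np.nan)),
        "wordlist_recall": float(row.get("wordlist_recall", np.nan)),
        "tmt_sum": tmt_a + tmt_b,
        "tmt_diff": tmt_b - tmt_a,
    }


def derive_outcomes(table: pd.DataFrame) -> pd.DataFrame:
    """Derive all 13 outcome measures for every row of a visit table.

    Returns a DataFrame indexed like ``table`` with the canonical outcome
    columns; missing raw inputs yield NaN cells, never errors.
    """
    records = [
        {**derive_gait_outcomes(row), **derive_cognitive_outcomes(row)}
        for row in table.to_dict("records")
    ]
    out = pd.DataFrame.from_records(records, index=table.index)
    return out[OUTCOME_NAMES]


def orient_outcomes(outcomes: pd.DataFrame, already_oriented: bool = False) -> pd.DataFrame:
    """Flip outcome scales so that higher values mean worse performance.

    Speeds and correct-item counts are negated; completion times are kept.
    Applying the flip twice restores the original values.
    """
    unknown = set(outcomes.columns) - set(OUTCOME_ORIENTATION)
    if unknown:
        raise KeyError(f"unknown outcome column(s): {sorted(unknown)}")
    oriented = outcomes.copy()
    for name in outcomes.columns:
        oriented[name] = outcomes[name] * OUTCOME_ORIENTATION[name]
    oriented.attrs["oriented"] = not already_oriented
    return oriented


def impute_predictors(
    table: pd.DataFrame,
    predictor_columns: list[str],
    subject_col: str = "subject_id",
    visit_col: str = "visit_index",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward- then backward-fill predictors within each subject.

    Assumes predictors only change when a new value is recorded.  Subjects
    with a predictor entirely missing cannot be filled and are excluded.

    Returns
    -------
    (imputed table, exclusion report) where the report has columns
    ``subject_id`` and ``reason``.
    """
    for _, grp in table.groupby(subject_col, sort=False):
        v = grp[visit_col].to_numpy()
        if np.any(np.diff(v) < 0):
            raise ValueError("visits must be ordered by visit_index within subject")

    filled = table.copy()
    grouped = filled.groupby(subject_col, sort=False)[predictor_columns]
    filled[predictor_columns] = grouped.ffill()
    filled[predictor_columns] = filled.groupby(subject_col, sort=False)[
        predictor_columns
    ].bfill()

    exclusions = []
    drop_subjects = set()
    for subject, grp in filled.groupby(subject_col, sort=False):
        for col in predictor_columns:
            if grp[col].isna().all():
                exclusions.append(
                    {"subject_id": subject, "reason": f"no value for predictor {col!r}"}
                )
                drop_subjects.add(subject)
    if drop_subjects:
        filled = filled[~filled[subject_col].isin(drop_subjects)]
    report = pd.DataFrame(exclusions, columns=["subject_id", "reason"])
    return filled, report


@dataclass
class Standardizer:
    """Train-set mean/SD standardization for real-valued columns.

    Parameters are fit on training rows only and applied unchanged to test
    rows.  Zero-variance columns are excluded with a warning.
    """

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def fit(self, train: pd.DataFrame, columns: list[str]) -> "Standardizer":
        if len(train) == 0:
            raise ValueError("cannot fit a standardizer on empty training data")
        self.means, self.sds, self.excluded = {}, {}, []
        for col in columns:
            x = train[col].to_numpy(dtype=float)
            obs = x[np.isfinite(x)]
            if obs.size == 0:
                raise ValueError(f"column {col!r} has no observed training values")
            mu, sd = float(obs.mean()), float(obs.std(ddof=0))
            if sd == 0.0:
                warnings.warn(
                    f"column {col!r} has zero training variance; excluded from standardization"
                )
                self.excluded.append(col)
                continue
            self.means[col] = mu
            self.sds[col] = sd
        return self

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        out = rows.copy()
        for col, mu in self.means.items():
            if col in out.columns:
                out[col] = (out[col] - mu) / self.sds[col]
        return out

    def center(self, rows: pd.DataFrame) -> pd.DataFrame:
        """Subtract training means only (used for centered responses)."""
        out = rows.copy()
        for col, mu in self.means.items():
            if col in out.columns:
                out[col] = out[col] - mu
        return out

    def inverse_transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        out = rows.copy()
        for col, mu in self.means.items():
            if col in out.columns:
                out[col] = out[col] * self.sds[col] + mu
        return out


def select_visits(outcomes: pd.DataFrame, which: str = "union") -> pd.Index:
    """Row sets used for training: per-outcome or the union.

    Each per-outcome OLS model keeps every row where its own outcome is
    observed; the multi-outcome Bayesian model trains on the union of those
    sets (rows with at least one observed outcome).
    """
    if which == "union":
        mask = outcomes[OUTCOME_NAMES].notna().any(axis=1)
    elif which in OUTCOME_NAMES:
        mask = outcomes[which].notna()
    else:
        raise KeyError(f"unknown outcome {which!r}")
    return outcomes.index[mask]


@dataclass
class DesignMatrix:
    """Encoded predictor matrix plus per-column encoding provenance.

    ``values`` holds one column per predictor: standardized continuous
    columns, 0/1 binaries, and raw integer codes for ordinals (the
    cumulative monotonic transform of ordinal codes happens inside the
    Bayesian model, jointly with the spacing simplexes).
    """

    values: pd.DataFrame
    encodings: dict[str, str]            # column -> encoding kind
    n_levels: dict[str, int]             # ordinal column -> category count
    standardizer: Standardizer

    @property
    def ordinal_columns(self) -> list[str]:
        return [c for c, e in self.encodings.items() if e == "ordinal-raw-code"]

    @property
    def fixed_columns(self) -> list[str]:
        return [c for c, e in self.encodings.items() if e != "ordinal-raw-code"]


def build_design(
    table: pd.DataFrame,
    predictor_specs,
    standardizer: Standardizer | None = None,
) -> DesignMatrix:
    """Encode predictors for the reduced-rank model.

    ``predictor_specs`` is an iterable of objects with ``name``, ``kind``
    (continuous | binary | ordinal) and, for ordinals, ``n_levels``.  When
    ``standardizer`` is None a new one is fit on ``table`` (training rows);
    otherwise the given (training) parameters are applied unchanged.
    """
    cont = [s.name for s in predictor_specs if s.kind == "continuous"]
    if standardizer is None:
        standardizer = Standardizer().fit(table, cont)
    values = pd.DataFrame(index=table.index)
    encodings: dict[str, str] = {}
    n_levels: dict[str, int] = {}
    std = standardizer.transform(table[cont]) if cont else pd.DataFrame(index=table.index)
    for spec in predictor_specs:
        if spec.kind == "continuous":
            if spec.name in standardizer.excluded:
                continue
            values[spec.name] = std[spec.name]
            encodings[spec.name] = "standardized-continuous"
        elif spec.kind == "binary":
            values[spec.name] = table[spec.name].astype(float)
            encodings[spec.name] = "binary"
        elif spec.kind == "ordinal":
            codes = table[spec.name].to_numpy(dtype=float)
            if np.any(~np.isfinite(codes)):
                raise ValueError(f"ordinal predictor {spec.name!r} has missing codes")
            if np.any(codes != np.floor(codes)):
                raise ValueError(f"ordinal predictor {spec.name!r} has non-integer codes")
            if np.any(codes < 0) or np.any(codes > spec.n_levels - 1):
                raise ValueError(f"ordinal predictor {spec.name!r} out of 0..{spec.n_levels - 1}")
            values[spec.name] = codes.astype(int)
            encodings[spec.name] = "ordinal-raw-code"
            n_levels[spec.name] = spec.n_levels
        else:
            raise ValueError(f"unknown predictor kind {spec.kind!r}")
    return DesignMatrix(values=values, encodings=encodings, n_levels=n_levels,
                        standardizer=standardizer)
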