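"""CSV input/output for cohort and outcome tables, with validation.

The cohort CSV carries one row per exam with columns ``exam_id, woman_id,
age, truth, ai_score, reader1, reader2, arbitration, subgroup``; an empty
``arbitration`` field means absent (never 0).  Loading validates the cohort
invariants and reports the first offending data row by number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import SCORE_MAX
from .reference import NONE, SUBGROUPS

COHORT_COLUMNS = ["exam_id", "woman_id", "age", "truth", "ai_score",
                  "reader1", "reader2", "arbitration", "subgroup"]


class CohortValidationError(ValueError):
    """A cohort table violates a structural invariant."""


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV (UTF-8, header row, empty field for no arbitration)."""
    out = cohort[COHORT_COLUMNS]
    out.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path, validate: bool = True) -> pd.DataFrame:
    """Read a cohort CSV and (by default) validate its invariants."""
    try:
        df = pd.read_csv(
            path,
            dtype={"exam_id": "int64", "woman_id": "int64", "truth": "int64",
                   "reader1": "int64", "reader2": "int64",
                   "arbitration": "Int64", "subgroup": "object"},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise CohortValidationError(f"malformed cohort CSV {path}: {exc}") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"cohort CSV missing columns: {missing}")
    df = df[COHORT_COLUMNS]
    if validate:
        validate_cohort(df)
    return df


def _first_bad_row(mask: np.ndarray) -> int:
    # 1-based data row number (header excluded)
    return int(np.flatnonzero(mask)[0]) + 1


def validate_cohort(df: pd.DataFrame) -> None:
    """Raise :class:`CohortValidationError` on the first invariant violation."""
    for col in ("truth", "reader1", "reader2"):
        bad = ~df[col].isin([0, 1]).to_numpy()
        if bad.any():
            raise CohortValidationError(
                f"row {_first_bad_row(bad)}: {col} must be 0 or 1")
    score = df["ai_score"].to_numpy(dtype=float)
    bad = ~((score >= 0) & (score <= SCORE_MAX))
    if bad.any():
        raise CohortValidationError(
            f"row {_first_bad_row(bad)}: ai_score outside [0, {SCORE_MAX}]")
    arb = df["arbitration"]
    bad = (arb.notna() & ~arb.isin([0, 1])).to_numpy()
    if bad.any():
        raise CohortValidationError(
            f"row {_first_bad_row(bad)}: arbitration must be empty, 0, or 1")
    disagree = (df["reader1"] != df["reader2"]).to_numpy()
    present = arb.notna().to_numpy()
    bad = disagree != present
    if bad.any():
        row = _first_bad_row(bad)
        what = ("readers disagree but arbitration is missing" if disagree[bad][0]
                else "readers agree but arbitration is present")
        raise CohortValidationError(f"row {row}: {what}")
    bad = ~df["subgroup"].isin(SUBGROUPS).to_numpy()
    if bad.any():
        raise CohortValidationError(
            f"row {_first_bad_row(bad)}: unknown subgroup label")
    none_label = (df["subgroup"] == NONE).to_numpy()
    noncancer = (df["truth"] == 0).to_numpy()
    bad = none_label != noncancer
    if bad.any():
        raise CohortValidationError(
            f"row {_first_bad_row(bad)}: subgroup 'none' must coincide with "
            "truth 0")
    if df["exam_id"].duplicated().any():
        raise CohortValidationError("duplicate exam_id values")


def write_outcomes(outcomes: pd.DataFrame, path) -> None:
    outcomes.to_csv(path, index=False, encoding="utf-8")


def read_outcomes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"exam_id": "int64", "final_recall": "int64",
                                  "human_reads": "int64",
                                  "arbitration_used": "bool",
                                  "arbitration_source": "object",
                                  "scenario": "object"})
    return df
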