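"""Reading-workflow engine: combined double reading and the AI scenarios.

Four workflows produce a final recall decision per exam:

* ``combined``  — both readers; a third (arbitration) read on disagreement.
* ``ai_first``  — AI replaces the first reader; the second reader is retained.
* ``ai_second`` — AI replaces the second reader; the first reader is retained.
* ``ai_triage`` — AI alone triages exams into low / moderate / high risk;
  only the moderate band is routed to the combined reading.

In the replacement scenarios an AI-vs-reader disagreement reuses the original
arbitration when one exists and simulates one otherwise, at the accuracy level
of the original arbitrator; when AI agrees with the retained reader any
original arbitration is disregarded.  Arbitration reads count as one human
read each.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import SCORE_MAX, Exam

COMBINED = "combined"
AI_FIRST = "ai_first"
AI_SECOND = "ai_second"
AI_TRIAGE = "ai_triage"
SCENARIOS = (COMBINED, AI_FIRST, AI_SECOND, AI_TRIAGE)

ARB_NONE = "none"
ARB_ORIGINAL = "original"
ARB_SIMULATED = "simulated"

OUTCOME_COLUMNS = ["exam_id", "scenario", "final_recall", "human_reads",
                   "arbitration_used", "arbitration_source"]

__all__ = [
    "ScenarioOutcome", "ArbitratorProfile", "WorkloadTally",
    "dichotomize_ai", "combined_reading", "estimate_arbitrator_profile",
    "simulate_arbitration", "scenario_reader_replacement", "scenario_triage",
    "run_combined", "run_reader_replacement", "run_triage", "tally_workload",
] + [n for n in ("COMBINED", "AI_FIRST", "AI_SECOND", "AI_TRIAGE",
                 "ARB_NONE", "ARB_ORIGINAL", "ARB_SIMULATED")]


@dataclass(frozen=True)
class ScenarioOutcome:
    """Final decision for one exam under one workflow."""

    exam_id: int
    scenario: str
    final_recall: int
    human_reads: int
    arbitration_used: bool
    arbitration_source: str

    def __post_init__(self) -> None:
        if (self.arbitration_source == ARB_NONE) == self.arbitration_used:
            raise ValueError("arbitration_source must be 'none' exactly when "
                             "no arbitration was used")


@dataclass(frozen=True)
class ArbitratorProfile:
    """Operating point of the (original or simulated) arbitrator."""

    sens: float
    spec: float
    n_cancer_est: int = 0
    n_noncancer_est: int = 0

    def __post_init__(self) -> None:
        for name in ("sens", "spec"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"arbitrator {name} must lie in [0, 1]")


@dataclass(frozen=True)
class WorkloadTally:
    total_reads_scenario: int
    total_reads_combined: int
    relative_reduction: float  # percent


def dichotomize_ai(score, threshold):
    """Binary recall decision: recall iff score strictly exceeds threshold."""
    s = np.asarray(score, dtype=float)
    t = float(threshold)
    if np.any(s < 0) or np.any(s > SCORE_MAX):
        raise ValueError("AI score outside [0, 100]")
    if not 0.0 <= t <= SCORE_MAX:
        raise ValueError("threshold outside [0, 100]")
    out = (s > t).astype(np.int8)
    if np.ndim(score) == 0:
        return int(out)
    return out


def combined_reading(exam: Exam) -> ScenarioOutcome:
    """Standard double reading with arbitration for disagreements."""
    if exam.reader1 == exam.reader2:
        return ScenarioOutcome(exam.exam_id, COMBINED, int(exam.reader1), 2,
                               False, ARB_NONE)
    if exam.original_arbitration is None:
        raise ValueError(
            f"exam {exam.exam_id}: readers disagree but no arbitration present"
        )
    return ScenarioOutcome(exam.exam_id, COMBINED,
                           int(exam.original_arbitration), 3, True, ARB_ORIGINAL)


def estimate_arbitrator_profile(cohort: pd.DataFrame) -> ArbitratorProfile:
    """Estimate the original arbitrator's operating point from a cohort.

    Sensitivity: fraction of arbitrated cancers given recall; specificity:
    fraction of arbitrated non-cancers given no-recall.  Raises when either
    stratum is empty — supply a profile explicitly in that case.
    """
    arb = cohort["arbitration"]
    mask = arb.notna()
    truth = cohort["truth"].to_numpy().astype(bool)
    cancers = mask & truth
    noncancers = mask & ~truth
    n_c = int(cancers.sum())
    n_n = int(noncancers.sum())
    if n_c == 0 or n_n == 0:
        missing = "cancers" if n_c == 0 else "non-cancers"
        raise ValueError(
            f"no arbitrated {missing} in cohort; supply an ArbitratorProfile "
            "explicitly instead of estimating one"
        )
    sens = float(arb[cancers].astype(float).mean())
    spec = float(1.0 - arb[noncancers].astype(float).mean())
    return ArbitratorProfile(sens=sens, spec=spec,
                             n_cancer_est=n_c, n_noncancer_est=n_n)


def simulate_arbitration(truth, profile: ArbitratorProfile,
                         rng: np.random.Generator):
    """Draw an arbitration decision matching the profile's accuracy level.

    Conditions on truth only: recall probability is ``sens`` for cancers and
    ``1 - spec`` for non-cancers.
    """
    t = np.asarray(truth)
    scalar = t.ndim == 0
    t1 = np.atleast_1d(t).astype(bool)
    p = np.where(t1, profile.sens, 1.0 - profile.spec)
    out = (rng.random(t1.size) < p).astype(np.int8)
    if scalar:
        return int(out[0])
    return out


def scenario_reader_replacement(exam: Exam, ai_recall: int, replaced: str,
                                profile: ArbitratorProfile,
                                rng: np.random.Generator) -> ScenarioOutcome:
    """One exam through a reader-replacement workflow.

    ``replaced`` names the reader the AI stands in for; the other reader is
    retained.  Agreement between AI and the retained reader is final (one
    human read, original arbitration disregarded).  Disagreement triggers an
    arbitration: the original one when present, otherwise a simulated one.
    """
    if replaced not in ("first", "second"):
        raise ValueError("replaced must be 'first' or 'second'")
    scenario = AI_FIRST if replaced == "first" else AI_SECOND
    retained = exam.reader2 if replaced == "first" else exam.reader1
    if int(ai_recall) == int(retained):
        return ScenarioOutcome(exam.exam_id, scenario, int(ai_recall), 1,
                               False, ARB_NONE)
    if exam.original_arbitration is not None:
        return ScenarioOutcome(exam.exam_id, scenario,
                               int(exam.original_arbitration), 2, True,
                               ARB_ORIGINAL)
    decision = simulate_arbitration(exam.truth, profile, rng)
    return ScenarioOutcome(exam.exam_id, scenario, int(decision), 2, True,
                           ARB_SIMULATED)


def scenario_triage(exam: Exam, low: float, high: float,
                    combined: ScenarioOutcome) -> ScenarioOutcome:
    """One exam through the stand-alone triage workflow.

    Bands: score >= high -> recall with zero human reads; score < low -> no
    recall with zero human reads; otherwise the combined reading's decision
    and read count are passed through unchanged.
    """
    _validate_triage_thresholds(low, high)
    if exam.ai_score >= high:
        return ScenarioOutcome(exam.exam_id, AI_TRIAGE, 1, 0, False, ARB_NONE)
    if exam.ai_score < low:
        return ScenarioOutcome(exam.exam_id, AI_TRIAGE, 0, 0, False, ARB_NONE)
    return ScenarioOutcome(exam.exam_id, AI_TRIAGE, combined.final_recall,
                           combined.human_reads, combined.arbitration_used,
                           combined.arbitration_source)


def _validate_triage_thresholds(low: float, high: float) -> None:
    if not (0.0 <= low <= SCORE_MAX and 0.0 <= high <= SCORE_MAX + 1.0):
        raise ValueError("triage thresholds outside the score range")
    if low >= high:
        raise ValueError(f"triage low threshold ({low}) must be below high "
                         f"threshold ({high})")


# ---------------------------------------------------------------------------
# vectorized engine over cohort tables

def _outcome_frame(exam_id, scenario, final, reads, used, source) -> pd.DataFrame:
    return pd.DataFrame({
        "exam_id": np.asarray(exam_id, dtype=np.int64),
        "scenario": scenario,
        "final_recall": np.asarray(final, dtype=np.int8),
        "human_reads": np.asarray(reads, dtype=np.int8),
        "arbitration_used": np.asarray(used, dtype=bool),
        "arbitration_source": np.asarray(source, dtype=object),
    })


def run_combined(cohort: pd.DataFrame) -> pd.DataFrame:
    """Combined double reading for every exam in the cohort."""
    r1 = cohort["reader1"].to_numpy()
    r2 = cohort["reader2"].to_numpy()
    agree = r1 == r2
    arb = cohort["arbitration"]
    missing = ~agree & arb.isna().to_numpy()
    if missing.any():
        bad = int(cohort.loc[missing, "exam_id"].iloc[0])
        raise ValueError(f"exam {bad}: readers disagree but no arbitration "
                         "present in cohort")
    arb_filled = arb.fillna(0).to_numpy(dtype=np.int64)
    final = np.where(agree, r1, arb_filled)
    reads = np.where(agree, 2, 3)
    source = np.where(agree, ARB_NONE, ARB_ORIGINAL)
    return _outcome_frame(cohort["exam_id"], COMBINED, final, reads, ~agree,
                          source)


def run_reader_replacement(cohort: pd.DataFrame, threshold: float,
                           replaced: str, profile: ArbitratorProfile,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Reader-replacement scenario over a whole cohort.

    Simulated arbitration draws are made for every exam (in cohort order) and
    used only where needed, so the realized decisions do not depend on the
    threshold through the RNG stream layout.
    """
    if replaced not in ("first", "second"):
        raise ValueError("replaced must be 'first' or 'second'")
    scenario = AI_FIRST if replaced == "first" else AI_SECOND
    ai = dichotomize_ai(cohort["ai_score"].to_numpy(), threshold)
    retained = cohort["reader2" if replaced == "first" else "reader1"].to_numpy()
    arb = cohort["arbitration"]
    have_orig = arb.notna().to_numpy()
    arb_filled = arb.fillna(0).to_numpy(dtype=np.int64)

    sim_draws = simulate_arbitration(cohort["truth"].to_numpy(), profile, rng)

    agree = ai == retained
    final = np.where(agree, ai,
                     np.where(have_orig, arb_filled, sim_draws))
    used = ~agree
    reads = 1 + used.astype(int)
    source = np.where(agree, ARB_NONE,
                      np.where(have_orig, ARB_ORIGINAL, ARB_SIMULATED))
    return _outcome_frame(cohort["exam_id"], scenario, final, reads, used,
                          source)


def run_triage(cohort: pd.DataFrame, low: float, high: float,
               combined_outcomes: pd.DataFrame) -> pd.DataFrame:
    """Triage scenario over a whole cohort given the combined outcomes."""
    _validate_triage_thresholds(low, high)
    _check_same_exams(combined_outcomes, cohort, "combined outcomes", "cohort")
    co = _aligned(combined_outcomes, cohort["exam_id"].to_numpy())
    s = cohort["ai_score"].to_numpy()
    high_band = s >= high
    low_band = s < low
    moderate = ~high_band & ~low_band
    final = np.where(high_band, 1,
                     np.where(low_band, 0, co["final_recall"].to_numpy()))
    reads = np.where(moderate, co["human_reads"].to_numpy(), 0)
    used = moderate & co["arbitration_used"].to_numpy()
    source = np.where(used, co["arbitration_source"].to_numpy(), ARB_NONE)
    return _outcome_frame(cohort["exam_id"], AI_TRIAGE, final, reads, used,
                          source)


def _check_same_exams(a: pd.DataFrame, b: pd.DataFrame,
                      name_a: str, name_b: str) -> None:
    ids_a = np.sort(a["exam_id"].to_numpy())
    ids_b = np.sort(b["exam_id"].to_numpy())
    if len(ids_a) == 0 or len(ids_a) != len(ids_b) or not np.array_equal(ids_a, ids_b):
        raise ValueError(f"{name_a} and {name_b} must cover the same nonempty "
                         "exam set")


def _aligned(outcomes: pd.DataFrame, exam_ids: np.ndarray) -> pd.DataFrame:
    if np.array_equal(outcomes["exam_id"].to_numpy(), exam_ids):
        return outcomes
    return outcomes.set_index("exam_id").loc[exam_ids].reset_index()


def tally_workload(outcomes_scenario: pd.DataFrame,
                   outcomes_combined: pd.DataFrame) -> WorkloadTally:
    """Total human reads per workflow and the relative reduction in percent.

    Arbitration reads count as one read each (they are already folded into
    ``human_reads``).
    """
    _check_same_exams(outcomes_scenario, outcomes_combined,
                      "scenario outcomes", "combined outcomes")
    reads_s = int(outcomes_scenario["human_reads"].sum())
    reads_c = int(outcomes_combined["human_reads"].sum())
    reduction = 100.0 * (1.0 - reads_s / reads_c)
    return WorkloadTally(reads_s, reads_c, reduction)
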