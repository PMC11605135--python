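"""Empirical selection of AI dichotomization thresholds.

Two procedures:

* specificity matching — the single cutoff whose strict-exceedance recall
  rule attains at least a target specificity on non-cancer scores (used when
  the AI replaces one reader);
* dual-constraint triage search — the (low, high) cutoff pair that places a
  target fraction of screenings in the moderate band while matching the
  triage scenario's recall rate to the combined reading's.

All selection is empirical: candidate cutoffs are the observed score values
(plus a sentinel above the maximum), which exhaust the achievable operating
points.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["ThresholdSet", "threshold_at_specificity", "select_triage_thresholds"]


@dataclass(frozen=True)
class ThresholdSet:
    """Selected cutoffs plus the realized operating quantities."""

    scenario_threshold: Optional[float] = None
    triage_low: Optional[float] = None
    triage_high: Optional[float] = None
    realized_specificity: Optional[float] = None
    realized_moderate_fraction: Optional[float] = None
    realized_recall_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.triage_low is not None and self.triage_high is not None:
            if not self.triage_low < self.triage_high:
                raise ValueError("triage_low must be below triage_high")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)
        return None

    @classmethod
    def from_json(cls, path) -> "ThresholdSet":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def merged(self, other: "ThresholdSet") -> "ThresholdSet":
        data = asdict(self)
        for k, v in asdict(other).items():
            if v is not None:
                data[k] = v
        return ThresholdSet(**data)


def threshold_at_specificity(noncancer_scores, target_spec: float):
    """Smallest observed score ``t`` with ``frac(score <= t) >= target_spec``.

    Under the strict-exceedance recall rule the realized specificity is the
    fraction of non-cancer scores at or below the returned cutoff; it is
    always >= the target and equals it whenever the target is attainable on
    the empirical distribution.

    Returns ``(threshold, realized_specificity)``.
    """
    scores = np.asarray(noncancer_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one non-cancer score")
    if not 0.0 <= target_spec <= 1.0:
        raise ValueError("target specificity must lie in [0, 1]")
    uniq, counts = np.unique(scores, return_counts=True)
    cumfrac = np.cumsum(counts) / scores.size
    idx = int(np.searchsorted(cumfrac, target_spec, side="left"))
    idx = min(idx, uniq.size - 1)
    # searchsorted('left') can land one short of the target under float
    # round-off; advance until the defining inequality actually holds.
    while cumfrac[idx] < target_spec and idx < uniq.size - 1:
        idx += 1
    return float(uniq[idx]), float(cumfrac[idx])


def select_triage_thresholds(cohort: pd.DataFrame,
                             combined_outcomes: pd.DataFrame,
                             moderate_target: float,
                             recall_target: float) -> ThresholdSet:
    """Grid-search the (low, high) triage cutoff pair.

    For every high candidate the low candidate bringing the moderate-band
    fraction nearest ``moderate_target`` is paired with it; among these pairs
    the one minimizing the absolute gap between the triage recall rate and
    ``recall_target`` wins, with ties broken by the moderate-fraction gap and
    then by the smaller high cutoff.  The result does not depend on input
    row order.
    """
    if not 0.0 < moderate_target <= 1.0:
        raise ValueError("moderate_target must lie in (0, 1]")
    merged = cohort[["exam_id", "ai_score"]].merge(
        combined_outcomes[["exam_id", "final_recall"]], on="exam_id",
        validate="one_to_one")
    if len(merged) != len(cohort):
        raise ValueError("cohort and combined outcomes must cover the same exams")
    order = np.argsort(merged["ai_score"].to_numpy(), kind="stable")
    s = merged["ai_score"].to_numpy()[order]
    recall_c = merged["final_recall"].to_numpy()[order]
    n = s.size
    # prefix[i] = number of combined recalls among the i lowest-score exams
    prefix = np.concatenate([[0], np.cumsum(recall_c)])

    uniq = np.unique(s)
    low_cands = uniq
    low_idx = np.searchsorted(s, low_cands, side="left")  # count(score < l)
    sentinel = float(uniq[-1]) + 1.0
    high_cands = np.concatenate([uniq, [sentinel]])
    high_idx = np.searchsorted(s, high_cands, side="left")  # count(score < h)

    # For each high candidate pick the single low candidate whose moderate
    # fraction is nearest the target: count(l <= score < h) = ih - il, so the
    # wanted il is nearest ih - target_count (low_idx strictly increases),
    # i.e. one of the two searchsorted brackets.  Per-h ties on the moderate
    # gap break toward the smaller low cutoff.
    k = low_cands.size
    target_count = moderate_target * n
    j = np.searchsorted(low_idx, high_idx - target_count, side="left")

    best_gap = np.full(high_cands.size, np.inf)
    best_l = np.full(high_cands.size, np.nan)
    best_il = np.zeros(high_cands.size, dtype=np.int64)
    for off in (j - 1, j):
        idx = np.clip(off, 0, k - 1)
        l_opt = low_cands[idx]
        il_opt = low_idx[idx]
        valid = (off >= 0) & (off < k) & (l_opt < high_cands) & (high_idx > 0)
        gap = np.abs((high_idx - il_opt) / n - moderate_target)
        better = valid & ((gap < best_gap)
                          | ((gap == best_gap) & (l_opt < best_l)))
        best_gap = np.where(better, gap, best_gap)
        best_l = np.where(better, l_opt, best_l)
        best_il = np.where(better, il_opt, best_il)

    feasible = np.isfinite(best_gap)
    if not feasible.any():
        raise ValueError(
            "no feasible (low, high) pair with low < high; candidate cutoffs: "
            f"{uniq[:5]} ... {uniq[-5:]}"
        )
    recall_rate = (n - high_idx + prefix[high_idx] - prefix[best_il]) / n
    recall_gap = np.where(feasible, np.abs(recall_rate - recall_target), np.inf)
    # lexicographic minimum over (recall gap, moderate gap, h, l)
    winner = np.lexsort((best_l, high_cands, best_gap, recall_gap))[0]
    h = float(high_cands[winner])
    l = float(best_l[winner])
    mod_frac = (high_idx[winner] - best_il[winner]) / n
    recall = float(recall_rate[winner])
    return ThresholdSet(triage_low=float(l), triage_high=float(h),
                        realized_moderate_fraction=float(mod_frac),
                        realized_recall_rate=float(recall))
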