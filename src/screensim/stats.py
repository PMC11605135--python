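"""Accuracy metrics, exact binomial intervals, and paired comparisons.

Per-workflow summaries report sensitivity and specificity (coprimary
endpoints), PPV, NPV, recall rate and arbitration rate (secondary), the
cancer detection rate per 1000 screens, and a single-operating-point AUC.
Paired workflow-vs-comparator tests use McNemar for the binary endpoints and
a generalized score test with a cluster-robust (sandwich) variance for the
predictive values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reference import INTERVAL, SCREEN_DETECTED

DEFAULT_ALPHA_COPRIMARY = 0.00833  # 0.05 / 6: two coprimary endpoints x three scenarios
DEFAULT_ALPHA_SECONDARY = 0.05
DEFAULT_MCNEMAR_EXACT_CUTOFF = 25

COPRIMARY_ENDPOINTS = ("sensitivity", "specificity")
SECONDARY_ENDPOINTS = ("ppv", "npv", "recall_rate", "arbitration_rate")

__all__ = [
    "ConfusionCounts", "Estimate", "AccuracySummary", "PairedComparison",
    "confusion_counts", "accuracy_summary", "clopper_pearson", "mcnemar_test",
    "paired_pv_score_test", "operating_point_auc", "empirical_auc",
    "welch_t_test", "compare_scenarios", "subgroup_sensitivity",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Estimate:
    """A proportion (or rate) with its confidence bounds.

    Undefined quantities (zero denominators) carry NaN everywhere and report
    ``defined`` False; they are never silently coerced to zero.
    """

    value: float
    lower: float
    upper: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


@dataclass(frozen=True)
class AccuracySummary:
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    recall_rate: Estimate
    arbitration_rate: Estimate
    cdr_per_1000: Estimate
    auc: float


@dataclass(frozen=True)
class PairedComparison:
    """One endpoint's scenario-vs-comparator contrast."""

    endpoint: str
    delta: float  # percentage points, scenario minus comparator
    statistic: float
    p_value: float
    discordant_counts: Optional[tuple[int, int]]
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def confusion_counts(final_recalls, truths) -> ConfusionCounts:
    """Standard 2x2 tally of decisions against truth."""
    r = np.asarray(final_recalls).astype(bool)
    t = np.asarray(truths).astype(bool)
    if r.shape != t.shape:
        raise ValueError("final_recalls and truths must be aligned")
    return ConfusionCounts(
        tp=int((r & t).sum()), fp=int((r & ~t).sum()),
        fn=int((~r & t).sum()), tn=int((~r & ~t).sum()),
    )


def clopper_pearson(successes: int, n: int, level: float = 0.95):
    """Exact (Clopper-Pearson) binomial confidence interval."""
    if n <= 0 or not 0 <= successes <= n:
        raise ValueError(f"need 0 <= successes <= n with n > 0, "
                         f"got successes={successes}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(
        sps.beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(
        sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


def _proportion(successes: int, n: int, level: float) -> Estimate:
    if n == 0:
        return Estimate(float("nan"), float("nan"), float("nan"))
    lo, hi = clopper_pearson(successes, n, level)
    return Estimate(successes / n, lo, hi)


def accuracy_summary(counts: ConfusionCounts, arbitration_flags,
                     ci_level: float = 0.95) -> AccuracySummary:
    """All accuracy endpoints with exact binomial CIs."""
    if counts.n == 0:
        raise ValueError("empty confusion table")
    flags = np.asarray(arbitration_flags).astype(bool)
    if flags.size != counts.n:
        raise ValueError("arbitration flags must cover every exam")
    sens = _proportion(counts.tp, counts.tp + counts.fn, ci_level)
    spec = _proportion(counts.tn, counts.tn + counts.fp, ci_level)
    cdr = _proportion(counts.tp, counts.n, ci_level)
    auc = ((sens.value + spec.value) / 2.0
           if sens.defined and spec.defined else float("nan"))
    return AccuracySummary(
        sensitivity=sens,
        specificity=spec,
        ppv=_proportion(counts.tp, counts.tp + counts.fp, ci_level),
        npv=_proportion(counts.tn, counts.tn + counts.fn, ci_level),
        recall_rate=_proportion(counts.tp + counts.fp, counts.n, ci_level),
        arbitration_rate=_proportion(int(flags.sum()), counts.n, ci_level),
        cdr_per_1000=Estimate(1000.0 * cdr.value, 1000.0 * cdr.lower,
                              1000.0 * cdr.upper),
        auc=auc,
    )


def mcnemar_test(b: int, c: int,
                 exact_cutoff: int = DEFAULT_MCNEMAR_EXACT_CUTOFF):
    """McNemar test on the discordant-pair counts (b, c).

    Chi-square statistic (b - c)^2 / (b + c) without continuity correction;
    the p-value switches to the exact two-sided binomial when b + c falls
    below ``exact_cutoff``.  Returns ``(statistic, p_value)``.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    m = b + c
    if m == 0:
        return 0.0, 1.0
    statistic = (b - c) ** 2 / m
    if m < exact_cutoff:
        p = float(sps.binomtest(b, m, 0.5).pvalue)
    else:
        p = float(sps.chi2.sf(statistic, df=1))
    return float(statistic), min(p, 1.0)


def paired_pv_score_test(truths, recalls_a, recalls_b, which: str):
    """Generalized score test for equality of paired predictive values.

    For PPV the positive calls of both arms are stacked into one record set
    (one record per positive call, clustered by subject), the cancer
    probability is modelled as common under the null, and the score for the
    arm contrast is studentized with an empirical sandwich variance that
    respects within-subject pairing.  NPV mirrors this on negative calls with
    the complemented outcome.  The statistic is asymptotically chi-square
    with one degree of freedom.  Returns ``(statistic, p_value)``.
    """
    if which not in ("ppv", "npv"):
        raise ValueError("which must be 'ppv' or 'npv'")
    t = np.asarray(truths).astype(int)
    ra = np.asarray(recalls_a).astype(int)
    rb = np.asarray(recalls_b).astype(int)
    if not (t.shape == ra.shape == rb.shape):
        raise ValueError("inputs must be aligned")
    if which == "ppv":
        in_a, in_b, y = ra == 1, rb == 1, t
    else:
        in_a, in_b, y = ra == 0, rb == 0, 1 - t
    na, nb = int(in_a.sum()), int(in_b.sum())
    if na == 0 or nb == 0:
        empty = "a" if na == 0 else "b"
        raise ValueError(f"arm {empty} has no "
                         f"{'positive' if which == 'ppv' else 'negative'} calls")
    n_records = na + nb
    xbar = nb / n_records
    p_hat = (y[in_a].sum() + y[in_b].sum()) / n_records
    resid = y - p_hat
    # per-subject cluster score contribution for the arm-indicator coefficient
    cluster = (np.where(in_a, (0.0 - xbar) * resid, 0.0)
               + np.where(in_b, (1.0 - xbar) * resid, 0.0))
    u = float(cluster.sum())
    v = float((cluster ** 2).sum())
    if v == 0.0:
        return 0.0, 1.0
    statistic = u * u / v
    return float(statistic), float(sps.chi2.sf(statistic, df=1))


def operating_point_auc(sens: float, spec: float) -> float:
    """Trapezoidal AUC through (0,0), (1-spec, sens), (1,1)."""
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sens and spec must lie in [0, 1]")
    return (sens + spec) / 2.0


def empirical_auc(scores, truths) -> float:
    """Rank-based two-sample AUC of a continuous score, ties counted half."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truths).astype(bool)
    n1 = int(t.sum())
    n0 = t.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    return float((ranks[t].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def welch_t_test(values_a, values_b):
    """Two-sample t test with unequal variances (Welch-Satterthwaite df)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _aligned_arrays(cohort: pd.DataFrame, outcomes_scenario: pd.DataFrame,
                    outcomes_combined: pd.DataFrame):
    ids = cohort["exam_id"].to_numpy()

    def align(df: pd.DataFrame) -> pd.DataFrame:
        if np.array_equal(df["exam_id"].to_numpy(), ids):
            return df
        out = df.set_index("exam_id").reindex(ids)
        if out["final_recall"].isna().any():
            raise ValueError("outcomes do not cover the cohort's exam set")
        return out.reset_index()

    return align(outcomes_scenario), align(outcomes_combined)


def compare_scenarios(cohort: pd.DataFrame, outcomes_scenario: pd.DataFrame,
                      outcomes_combined: pd.DataFrame,
                      alpha_coprimary: float = DEFAULT_ALPHA_COPRIMARY,
                      alpha_secondary: float = DEFAULT_ALPHA_SECONDARY,
                      mcnemar_exact_cutoff: int = DEFAULT_MCNEMAR_EXACT_CUTOFF,
                      ) -> list[PairedComparison]:
    """Paired endpoint-by-endpoint comparison of a scenario vs its comparator.

    Sensitivity / specificity / recall rate / arbitration rate use McNemar on
    the appropriate stratum; PPV and NPV use the paired predictive-value
    score test.  Deltas are percentage points, scenario minus comparator.
    """
    osc, oco = _aligned_arrays(cohort, outcomes_scenario, outcomes_combined)
    truth = cohort["truth"].to_numpy().astype(bool)
    rs = osc["final_recall"].to_numpy().astype(bool)
    rc = oco["final_recall"].to_numpy().astype(bool)
    arb_s = osc["arbitration_used"].to_numpy().astype(bool)
    arb_c = oco["arbitration_used"].to_numpy().astype(bool)

    def mcnemar_entry(endpoint: str, flags_s, flags_c, mask, alpha):
        fs, fc = flags_s[mask], flags_c[mask]
        b = int((fs & ~fc).sum())
        c = int((~fs & fc).sum())
        stat, p = mcnemar_test(b, c, exact_cutoff=mcnemar_exact_cutoff)
        delta = 100.0 * (fs.mean() - fc.mean())
        return PairedComparison(endpoint, float(delta), stat, p, (b, c), alpha)

    everything = np.ones_like(truth, dtype=bool)
    out = [
        mcnemar_entry("sensitivity", rs, rc, truth, alpha_coprimary),
        mcnemar_entry("specificity", ~rs, ~rc, ~truth, alpha_coprimary),
    ]

    for which in ("ppv", "npv"):
        stat, p = paired_pv_score_test(truth.astype(int), rs.astype(int),
                                       rc.astype(int), which)
        if which == "ppv":
            pv_s = truth[rs].mean()
            pv_c = truth[rc].mean()
        else:
            pv_s = (~truth[~rs]).mean()
            pv_c = (~truth[~rc]).mean()
        out.append(PairedComparison(which, float(100.0 * (pv_s - pv_c)),
                                    stat, p, None, alpha_secondary))

    out.append(mcnemar_entry("recall_rate", rs, rc, everything,
                             alpha_secondary))
    out.append(mcnemar_entry("arbitration_rate", arb_s, arb_c, everything,
                             alpha_secondary))
    return out


def subgroup_sensitivity(outcomes: pd.DataFrame, cohort: pd.DataFrame,
                         subgroup: str, ci_level: float = 0.95) -> Estimate:
    """Sensitivity restricted to cancers with the given subgroup label."""
    if subgroup not in (SCREEN_DETECTED, INTERVAL):
        raise ValueError(f"unknown cancer subgroup {subgroup!r}")
    merged = cohort[["exam_id", "truth", "subgroup"]].merge(
        outcomes[["exam_id", "final_recall"]], on="exam_id",
        validate="one_to_one")
    mask = (merged["truth"] == 1) & (merged["subgroup"] == subgroup)
    n = int(mask.sum())
    return _proportion(int(merged.loc[mask, "final_recall"].sum()), n, ci_level)
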