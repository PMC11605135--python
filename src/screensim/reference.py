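"""Ground-truth outcome semantics and cancer subgroup labels.

A cancer is *screen detected* when the original combined double reading
recalled the exam, and an *interval* cancer otherwise.  Non-cancers carry the
``none`` label.  Subgroup labels are fixed to the original combined reading,
so every workflow scenario shares one labeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

SCREEN_DETECTED = "screen_detected"
INTERVAL = "interval"
NONE = "none"

SUBGROUPS = (SCREEN_DETECTED, INTERVAL, NONE)


def classify_subgroup(truth: int, combined_recall: int) -> str:
    """Label one exam given its truth and the original combined decision."""
    if truth not in (0, 1) or combined_recall not in (0, 1):
        raise ValueError("truth and combined_recall must be 0 or 1")
    if truth == 0:
        return NONE
    return SCREEN_DETECTED if combined_recall == 1 else INTERVAL


def assign_subgroups(truth, combined_recall) -> np.ndarray:
    """Vectorized :func:`classify_subgroup` over aligned arrays."""
    t = np.asarray(truth).astype(int)
    c = np.asarray(combined_recall).astype(int)
    if t.shape != c.shape:
        raise ValueError("truth and combined_recall must be aligned")
    out = np.where(t == 0, NONE, np.where(c == 1, SCREEN_DETECTED, INTERVAL))
    return out.astype(object)


@dataclass(frozen=True)
class SubgroupComposition:
    """Counts and percentages of cancer subgroups in a cohort.

    ``defined`` is False (and the percentages NaN) when the cohort contains
    no cancers at all.
    """

    n_cancers: int
    n_screen_detected: int
    n_interval: int
    pct_screen_detected: float
    pct_interval: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.pct_screen_detected)


def subgroup_composition(cohort: pd.DataFrame) -> SubgroupComposition:
    """Fractions of screen-detected and interval cancers among all cancers."""
    cancers = cohort[cohort["truth"] == 1]
    n = len(cancers)
    n_sd = int((cancers["subgroup"] == SCREEN_DETECTED).sum())
    n_iv = int((cancers["subgroup"] == INTERVAL).sum())
    if n_sd + n_iv != n:
        raise ValueError("cancers carry subgroup labels other than "
                         f"{SCREEN_DETECTED!r}/{INTERVAL!r}")
    if n == 0:
        return SubgroupComposition(0, 0, 0, float("nan"), float("nan"))
    return SubgroupComposition(n, n_sd, n_iv, 100.0 * n_sd / n, 100.0 * n_iv / n)
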