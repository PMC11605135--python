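from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import screensim as ss
from screensim.reference import assign_subgroups


def build_cohort(truth, reader1, reader2, arbitration=None, ai_score=None,
                 age=None):
    """Assemble a valid cohort frame from decision arrays.

    ``arbitration`` entries are ignored (set missing) wherever the readers
    agree; where they disagree a value must be supplied.
    """
    truth = np.asarray(truth, dtype=np.int64)
    r1 = np.asarray(reader1, dtype=np.int64)
    r2 = np.asarray(reader2, dtype=np.int64)
    n = truth.size
    if ai_score is None:
        ai_score = np.where(truth == 1, 90.0, 10.0)
    if age is None:
        age = np.full(n, 60.0)
    disagree = r1 != r2
    arb = pd.array([pd.NA] * n, dtype="Int64")
    if disagree.any():
        if arbitration is None:
            raise ValueError("fixture needs arbitration values for disagreements")
        arbitration = np.asarray(arbitration)
        arb[disagree] = arbitration[disagree].astype(np.int64)
    combined = np.where(~disagree, r1,
                        np.asarray(arb.fillna(0), dtype=np.int64))
    return pd.DataFrame({
        "exam_id": np.arange(1, n + 1, dtype=np.int64),
        "woman_id": np.arange(1, n + 1, dtype=np.int64),
        "age": np.asarray(age, dtype=float),
        "truth": truth,
        "ai_score": np.asarray(ai_score, dtype=float),
        "reader1": r1,
        "reader2": r2,
        "arbitration": arb,
        "subgroup": assign_subgroups(truth, combined),
    })


@pytest.fixture(scope="session")
def default_cohort_100k():
    params = ss.default_params(100_000, seed=1)
    cohort = ss.generate_cohort(params)
    combined = ss.run_combined(cohort)
    return params, cohort, combined


@pytest.fixture(scope="session")
def small_cohort():
    params = ss.default_params(5_000, seed=7)
    return params, ss.generate_cohort(params)
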