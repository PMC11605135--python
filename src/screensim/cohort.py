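"""Synthetic screening-cohort generator.

Produces exam-level tables with the statistical structure a double-reading
screening program exhibits: a rare cancer class, two readers with distinct
operating points whose decisions are correlated through a shared latent
Gaussian variable per truth class, an arbitrator resolving disagreements,
and a continuous abnormality score in [0, 100] drawn from truth-conditional
mixtures of scaled beta densities (point masses allowed for degenerate
configurations).

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rng import substream
from .reference import NONE, assign_subgroups

SCORE_MAX = 100.0

__all__ = [
    "ScoreComponent",
    "ScoreMixture",
    "CohortParams",
    "Exam",
    "default_params",
    "generate_cohort",
    "draw_reader_decisions",
    "draw_ai_score",
    "attach_original_arbitrations",
    "cohort_to_exams",
]


@dataclass(frozen=True)
class ScoreComponent:
    """One mixture component for the abnormality-score distribution.

    Either a Beta(a, b) density rescaled to [0, 100] (``a``/``b`` given) or a
    degenerate point mass at ``value``.
    """

    weight: float
    a: Optional[float] = None
    b: Optional[float] = None
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight) or self.weight < 0:
            raise ValueError(f"component weight must be >= 0, got {self.weight}")
        if self.value is not None:
            if self.a is not None or self.b is not None:
                raise ValueError("give either (a, b) or value, not both")
            if not 0.0 <= self.value <= SCORE_MAX:
                raise ValueError(f"point mass must lie in [0, {SCORE_MAX}]")
        else:
            if self.a is None or self.b is None:
                raise ValueError("beta component needs both a and b")
            if self.a <= 0 or self.b <= 0:
                raise ValueError("beta shape parameters must be positive")

    @property
    def is_point(self) -> bool:
        return self.value is not None

    @property
    def mean(self) -> float:
        if self.is_point:
            return float(self.value)  # type: ignore[arg-type]
        return SCORE_MAX * self.a / (self.a + self.b)  # type: ignore[operator]


@dataclass(frozen=True)
class ScoreMixture:
    """A finite mixture of :class:`ScoreComponent` densities on [0, 100]."""

    components: tuple[ScoreComponent, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {total}")

    @property
    def mean(self) -> float:
        return sum(c.weight * c.mean for c in self.components)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        weights = np.array([c.weight for c in self.components])
        idx = rng.choice(len(self.components), size=n, p=weights)
        out = np.empty(n, dtype=float)
        for k, comp in enumerate(self.components):
            mask = idx == k
            m = int(mask.sum())
            if m == 0:
                continue
            if comp.is_point:
                out[mask] = comp.value
            else:
                out[mask] = SCORE_MAX * rng.beta(comp.a, comp.b, size=m)
        return out

    @classmethod
    def from_spec(cls, items: Sequence[Mapping[str, float]]) -> "ScoreMixture":
        """Build from a list of mappings, e.g. parsed YAML.

        Each item carries ``weight`` plus either ``a``/``b`` or ``value``.
        """
        comps = tuple(
            ScoreComponent(
                weight=float(item["weight"]),
                a=float(item["a"]) if "a" in item else None,
                b=float(item["b"]) if "b" in item else None,
                value=float(item["value"]) if "value" in item else None,
            )
            for item in items
        )
        return cls(comps)

    def to_spec(self) -> list[dict[str, float]]:
        out = []
        for c in self.components:
            if c.is_point:
                out.append({"weight": c.weight, "value": c.value})
            else:
                out.append({"weight": c.weight, "a": c.a, "b": c.b})
        return out


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters for one synthetic screening cohort."""

    n_exams: int
    cancer_prevalence: float
    reader1_sens: float
    reader1_spec: float
    reader2_sens: float
    reader2_spec: float
    reader_dependence_cancer: float
    reader_dependence_noncancer: float
    arbitrator_sens: float
    arbitrator_spec: float
    ai_cancer_mixture: ScoreMixture
    ai_noncancer_mixture: ScoreMixture
    age_mean: float = 59.3
    age_sd: float = 5.9
    age_min: float = 50.0
    age_max: float = 70.0
    exams_per_woman_mean: float = 1.67
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exams < 1:
            raise ValueError("n_exams must be >= 1")
        _check_prob("cancer_prevalence", self.cancer_prevalence)
        for name in ("reader1_sens", "reader1_spec", "reader2_sens",
                     "reader2_spec", "arbitrator_sens", "arbitrator_spec"):
            _check_prob(name, getattr(self, name))
        for name in ("reader_dependence_cancer", "reader_dependence_noncancer"):
            rho = getattr(self, name)
            # Gaussian-copula feasibility: any rho in [0, 1] yields a valid
            # joint; negative or >1 correlations are rejected here.
            if not 0.0 <= rho <= 1.0:
                raise ValueError(
                    f"{name} must lie in [0, 1] for a feasible latent "
                    f"Gaussian joint distribution, got {rho}"
                )
        if self.exams_per_woman_mean < 1.0:
            raise ValueError("exams_per_woman_mean must be >= 1")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be below age_max")

    def with_seed(self, seed: int) -> "CohortParams":
        return replace(self, seed=seed)

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "CohortParams":
        """Build from a plain mapping (YAML ``cohort:`` block)."""
        kwargs = dict(data)
        for key in ("ai_cancer_mixture", "ai_noncancer_mixture"):
            if key in kwargs and not isinstance(kwargs[key], ScoreMixture):
                kwargs[key] = ScoreMixture.from_spec(kwargs[key])  # type: ignore[arg-type]
        return cls(**kwargs)  # type: ignore[arg-type]

    def to_dict(self) -> dict[str, object]:
        out: dict[str, object] = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k not in ("ai_cancer_mixture", "ai_noncancer_mixture")
        }
        out["ai_cancer_mixture"] = self.ai_cancer_mixture.to_spec()
        out["ai_noncancer_mixture"] = self.ai_noncancer_mixture.to_spec()
        return out


@dataclass(frozen=True)
class Exam:
    """One screening event."""

    exam_id: int
    woman_id: int
    age: float
    truth: int
    ai_score: float
    reader1: int
    reader2: int
    original_arbitration: Optional[int]
    subgroup: str = NONE

    def __post_init__(self) -> None:
        if (self.reader1 != self.reader2) != (self.original_arbitration is not None):
            raise ValueError(
                f"exam {self.exam_id}: arbitration must be present exactly "
                "when the readers disagree"
            )
        if (self.subgroup == NONE) != (self.truth == 0):
            raise ValueError(
                f"exam {self.exam_id}: subgroup 'none' must coincide with truth 0"
            )
        if not 0.0 <= self.ai_score <= SCORE_MAX:
            raise ValueError(f"exam {self.exam_id}: ai_score outside [0, 100]")


def default_params(n_exams: int = 100_000, seed: int = 0) -> CohortParams:
    """Default cohort emulating a Danish-style biennial screening program.

    Prevalence matches 2033 cancers per 249 402 screens; the second reader is
    the more accurate one; the cancer score mixture is bimodal (a detectable
    high-score mode plus a low-score interval-like mode) so that roughly a
    quarter of cancers are missed by the combined reading.
    """
    return CohortParams(
        n_exams=n_exams,
        cancer_prevalence=2033 / 249_402,
        reader1_sens=0.63,
        reader1_spec=0.971,
        reader2_sens=0.68,
        reader2_spec=0.975,
        reader_dependence_cancer=0.40,
        reader_dependence_noncancer=0.30,
        arbitrator_sens=0.70,
        arbitrator_spec=0.85,
        ai_cancer_mixture=ScoreMixture((
            ScoreComponent(weight=0.72, a=6.0, b=1.2),
            ScoreComponent(weight=0.28, a=1.3, b=6.0),
        )),
        ai_noncancer_mixture=ScoreMixture((
            ScoreComponent(weight=1.0, a=1.1, b=12.0),
        )),
        seed=seed,
    )


def draw_reader_decisions(truth, params: CohortParams, rng: np.random.Generator):
    """Draw both readers' recall decisions for exams with the given truths.

    Marginals: reader *k* recalls with probability ``sens_k`` for cancers and
    ``1 - spec_k`` for non-cancers.  Within an exam the two decisions share a
    latent Gaussian with the class-specific correlation; correlation 1 with
    identical operating points makes the readers comonotone.
    """
    t = np.asarray(truth)
    scalar = t.ndim == 0
    t1 = np.atleast_1d(t).astype(bool)
    n = t1.size
    rho = np.where(t1, params.reader_dependence_cancer,
                   params.reader_dependence_noncancer)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    p1 = np.where(t1, params.reader1_sens, 1.0 - params.reader1_spec)
    p2 = np.where(t1, params.reader2_sens, 1.0 - params.reader2_spec)
    with np.errstate(invalid="ignore"):
        r1 = (z1 < sps.norm.ppf(p1)).astype(np.int8)
        r2 = (z2 < sps.norm.ppf(p2)).astype(np.int8)
    if scalar:
        return int(r1[0]), int(r2[0])
    return r1, r2


def draw_ai_score(truth, params: CohortParams, rng: np.random.Generator):
    """Draw abnormality scores from the truth-conditional mixtures."""
    t = np.asarray(truth)
    scalar = t.ndim == 0
    t1 = np.atleast_1d(t).astype(bool)
    out = np.empty(t1.size, dtype=float)
    n_cancer = int(t1.sum())
    # fixed draw order (cancers first) keeps the stream layout stable
    cancer_scores = params.ai_cancer_mixture.sample(n_cancer, rng)
    noncancer_scores = params.ai_noncancer_mixture.sample(t1.size - n_cancer, rng)
    out[t1] = cancer_scores
    out[~t1] = noncancer_scores
    if scalar:
        return float(out[0])
    return out


def attach_original_arbitrations(cohort: pd.DataFrame, params: CohortParams,
                                 rng: np.random.Generator) -> pd.DataFrame:
    """Attach an arbitration decision to every exam whose readers disagree.

    The arbitrator recalls with probability ``arbitrator_sens`` for cancers
    and ``1 - arbitrator_spec`` for non-cancers; exams with reader agreement
    get a missing value.  Returns a copy.
    """
    out = cohort.copy()
    n = len(out)
    truth = out["truth"].to_numpy().astype(bool)
    p = np.where(truth, params.arbitrator_sens, 1.0 - params.arbitrator_spec)
    draws = (rng.random(n) < p).astype(np.int64)
    disagree = (out["reader1"] != out["reader2"]).to_numpy()
    arb = pd.array(draws, dtype="Int64")
    arb[~disagree] = pd.NA
    out["arbitration"] = arb
    return out


def _woman_assignment(n: int, mean: float, rng: np.random.Generator):
    """Assign exams to women with counts ~ 1 + Poisson(mean - 1)."""
    counts: list[np.ndarray] = []
    total = 0
    while total < n:
        chunk = 1 + rng.poisson(max(mean - 1.0, 0.0),
                                size=max(int(n / mean) + 16, 64))
        counts.append(chunk)
        total += int(chunk.sum())
    all_counts = np.concatenate(counts)
    cum = np.cumsum(all_counts)
    n_women = int(np.searchsorted(cum, n)) + 1
    woman_counts = all_counts[:n_women].copy()
    woman_counts[-1] -= int(cum[n_women - 1] - n)
    woman_id = np.repeat(np.arange(1, n_women + 1), woman_counts)
    return woman_id, woman_counts


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Generate a full synthetic cohort table, reproducible from the seed.

    Columns: exam_id, woman_id, age, truth, ai_score, reader1, reader2,
    arbitration (nullable Int64), subgroup.
    """
    rng = substream(params.seed, "cohort")
    n = params.n_exams

    woman_id, woman_counts = _woman_assignment(n, params.exams_per_woman_mean, rng)
    lo = (params.age_min - params.age_mean) / params.age_sd
    hi = (params.age_max - params.age_mean) / params.age_sd
    woman_age = sps.truncnorm.rvs(lo, hi, loc=params.age_mean,
                                  scale=params.age_sd,
                                  size=len(woman_counts), random_state=rng)
    age = np.repeat(woman_age, woman_counts)

    truth = (rng.random(n) < params.cancer_prevalence).astype(np.int8)
    reader1, reader2 = draw_reader_decisions(truth, params, rng)
    ai_score = draw_ai_score(truth, params, rng)

    cohort = pd.DataFrame({
        "exam_id": np.arange(1, n + 1, dtype=np.int64),
        "woman_id": woman_id.astype(np.int64),
        "age": np.round(age, 2),
        "truth": truth,
        "ai_score": ai_score,
        "reader1": reader1,
        "reader2": reader2,
    })
    cohort = attach_original_arbitrations(cohort, params, rng)

    agree = cohort["reader1"].to_numpy() == cohort["reader2"].to_numpy()
    arb_filled = cohort["arbitration"].fillna(0).to_numpy(dtype=np.int64)
    combined = np.where(agree, cohort["reader1"].to_numpy(), arb_filled)
    cohort["subgroup"] = assign_subgroups(cohort["truth"].to_numpy(), combined)
    return cohort


def cohort_to_exams(cohort: pd.DataFrame) -> Iterator[Exam]:
    """Yield validated :class:`Exam` records row by row."""
    for row in cohort.itertuples(index=False):
        arb = row.arbitration
        yield Exam(
            exam_id=int(row.exam_id),
            woman_id=int(row.woman_id),
            age=float(row.age),
            truth=int(row.truth),
            ai_score=float(row.ai_score),
            reader1=int(row.reader1),
            reader2=int(row.reader2),
            original_arbitration=None if pd.isna(arb) else int(arb),
            subgroup=str(row.subgroup),
        )
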