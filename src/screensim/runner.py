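"""End-to-end study orchestration: generate, select thresholds, run the
scenarios, compute statistics, and write a report bundle.

The bundle written to the output directory contains the cohort CSV, a
thresholds JSON with realized operating quantities, one outcomes CSV per
workflow, per-workflow summary and cross-tabulation/workload tables (TSV),
subgroup sensitivities, paired comparisons (JSON), and a run log naming the
seed, library versions, and RNG substream labels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import STREAM_OFFSETS, substream
from .cohort import CohortParams, default_params, generate_cohort
from .io import write_cohort
from .reference import INTERVAL, SCREEN_DETECTED
from .stats import (DEFAULT_ALPHA_COPRIMARY, DEFAULT_ALPHA_SECONDARY,
                    DEFAULT_MCNEMAR_EXACT_CUTOFF, accuracy_summary,
                    compare_scenarios, confusion_counts, empirical_auc,
                    subgroup_sensitivity)
from .thresholds import (ThresholdSet, select_triage_thresholds,
                         threshold_at_specificity)
from .workflow import (AI_FIRST, AI_SECOND, AI_TRIAGE, COMBINED,
                       ArbitratorProfile, estimate_arbitrator_profile,
                       run_combined, run_reader_replacement, run_triage,
                       tally_workload)

MODE_MATCH_SPECIFICITY = "match_specificity"
MODE_FIXED = "fixed"


@dataclass(frozen=True)
class ThresholdConfig:
    mode: str = MODE_MATCH_SPECIFICITY
    fixed_scenario_threshold: Optional[float] = None
    fixed_triage_low: Optional[float] = None
    fixed_triage_high: Optional[float] = None
    moderate_target: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in (MODE_MATCH_SPECIFICITY, MODE_FIXED):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == MODE_FIXED:
            missing = [n for n in ("fixed_scenario_threshold",
                                   "fixed_triage_low", "fixed_triage_high")
                       if getattr(self, n) is None]
            if missing:
                raise ValueError(f"fixed threshold mode needs {missing}")
        if not 0.0 < self.moderate_target <= 1.0:
            raise ValueError("moderate_target must lie in (0, 1]")


@dataclass(frozen=True)
class AnalysisConfig:
    alpha_coprimary: float = DEFAULT_ALPHA_COPRIMARY
    alpha_secondary: float = DEFAULT_ALPHA_SECONDARY
    ci_level: float = 0.95
    mcnemar_exact_cutoff: int = DEFAULT_MCNEMAR_EXACT_CUTOFF

    def __post_init__(self) -> None:
        for name in ("alpha_coprimary", "alpha_secondary", "ci_level"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class StudyConfig:
    cohort: CohortParams
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    split_mode: bool = False
    output_dir: Path = Path("screensim_out")
    seed: Optional[int] = None

    @property
    def master_seed(self) -> int:
        return self.cohort.seed if self.seed is None else self.seed

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "StudyConfig":
        data = dict(data)
        cohort = data.pop("cohort", None)
        if cohort is None:
            raise ValueError("config needs a 'cohort' block")
        if not isinstance(cohort, CohortParams):
            cohort = CohortParams.from_dict(cohort)  # type: ignore[arg-type]
        thresholds = data.pop("thresholds", {})
        if not isinstance(thresholds, ThresholdConfig):
            thresholds = ThresholdConfig(**thresholds)  # type: ignore[arg-type]
        analysis = data.pop("analysis", {})
        if not isinstance(analysis, AnalysisConfig):
            analysis = AnalysisConfig(**analysis)  # type: ignore[arg-type]
        out_dir = Path(data.pop("output_dir", "screensim_out"))  # type: ignore[arg-type]
        return cls(cohort=cohort, thresholds=thresholds, analysis=analysis,
                   split_mode=bool(data.pop("split_mode", False)),
                   output_dir=out_dir,
                   seed=data.pop("seed", None))  # type: ignore[arg-type]


def load_config(path) -> StudyConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return StudyConfig.from_dict(data)


@dataclass(frozen=True)
class FlowAccounting:
    """Flowchart-style accounting of cohort exclusions."""

    initial_n: int
    exclusions: tuple[tuple[str, int], ...]
    final_n: int

    def __post_init__(self) -> None:
        if self.final_n != self.initial_n - self.exclusion_total:
            raise ValueError("flow accounting does not balance: "
                             f"{self.initial_n} - {self.exclusion_total} != "
                             f"{self.final_n}")

    @property
    def exclusion_total(self) -> int:
        return sum(count for _, count in self.exclusions)

    @property
    def exclusion_rate_percent(self) -> float:
        return 100.0 * self.exclusion_total / self.initial_n

    @classmethod
    def from_counts(cls, initial_n: int,
                    exclusions: Sequence[tuple[str, int]]) -> "FlowAccounting":
        exclusions = tuple((str(label), int(count)) for label, count in exclusions)
        return cls(initial_n, exclusions,
                   initial_n - sum(c for _, c in exclusions))


ExclusionRule = tuple[str, Callable[[pd.DataFrame], np.ndarray]]


def apply_exclusions(raw_cohort: pd.DataFrame,
                     rules: Sequence[ExclusionRule]):
    """Drop rows failing any rule, attributing each to the first failing rule.

    Returns ``(cohort, FlowAccounting)``.
    """
    remaining = np.ones(len(raw_cohort), dtype=bool)
    counts: list[tuple[str, int]] = []
    for label, predicate in rules:
        fails = np.asarray(predicate(raw_cohort), dtype=bool) & remaining
        counts.append((label, int(fails.sum())))
        remaining &= ~fails
    cohort = raw_cohort.loc[remaining].reset_index(drop=True)
    accounting = FlowAccounting(len(raw_cohort), tuple(counts), len(cohort))
    return cohort, accounting


@dataclass
class StudyReport:
    """In-memory results of one full run, plus where they were written."""

    cohort: pd.DataFrame
    thresholds: ThresholdSet
    profile: ArbitratorProfile
    outcomes: dict[str, pd.DataFrame]
    summaries: dict[str, object]
    comparisons: dict[str, list]
    workload: dict[str, object]
    subgroups: pd.DataFrame
    flow: FlowAccounting
    output_dir: Optional[Path] = None


def _select_thresholds(config: StudyConfig, cohort: pd.DataFrame,
                       combined) -> ThresholdSet:
    tc = config.thresholds
    if tc.mode == MODE_FIXED:
        return ThresholdSet(
            scenario_threshold=tc.fixed_scenario_threshold,
            triage_low=tc.fixed_triage_low, triage_high=tc.fixed_triage_high)
    truth = cohort["truth"].to_numpy().astype(bool)
    # AI cutoff matched at the first reader's empirical specificity
    target_spec = float((cohort.loc[~truth, "reader1"] == 0).mean())
    thr, realized = threshold_at_specificity(
        cohort.loc[~truth, "ai_score"].to_numpy(), target_spec)
    recall_target = float(combined["final_recall"].mean())
    triage = select_triage_thresholds(cohort, combined, tc.moderate_target,
                                      recall_target)
    return ThresholdSet(scenario_threshold=thr,
                        realized_specificity=realized).merged(triage)


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full pipeline and, when an output directory is configured,
    write the report bundle there.  Deterministic given the config."""
    seed = config.master_seed
    params = config.cohort.with_seed(seed)

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    full_cohort = stage("generate", generate_cohort, params)
    flow = FlowAccounting(len(full_cohort), (), len(full_cohort))

    if config.split_mode:
        rng = substream(seed, "split")
        perm = rng.permutation(len(full_cohort))
        half = len(full_cohort) // 2
        select_cohort = full_cohort.iloc[np.sort(perm[:half])].reset_index(drop=True)
        eval_cohort = full_cohort.iloc[np.sort(perm[half:])].reset_index(drop=True)
    else:
        select_cohort = eval_cohort = full_cohort

    combined_select = stage("combined", run_combined, select_cohort)
    thresholds = stage("thresholds", _select_thresholds, config,
                       select_cohort, combined_select)
    profile = stage("arbitrator", estimate_arbitrator_profile, select_cohort)

    combined = (combined_select if eval_cohort is select_cohort
                else stage("combined", run_combined, eval_cohort))
    outcomes = {COMBINED: combined}
    for scenario, replaced in ((AI_FIRST, "first"), (AI_SECOND, "second")):
        outcomes[scenario] = stage(
            scenario, run_reader_replacement, eval_cohort,
            thresholds.scenario_threshold, replaced, profile,
            substream(seed, scenario))
    outcomes[AI_TRIAGE] = stage(
        AI_TRIAGE, run_triage, eval_cohort, thresholds.triage_low,
        thresholds.triage_high, combined)

    truth = eval_cohort["truth"].to_numpy()
    summaries = {}
    for name, out in outcomes.items():
        counts = confusion_counts(out["final_recall"].to_numpy(), truth)
        summaries[name] = accuracy_summary(
            counts, out["arbitration_used"].to_numpy(),
            ci_level=config.analysis.ci_level)
    for reader in ("reader1", "reader2"):
        counts = confusion_counts(eval_cohort[reader].to_numpy(), truth)
        summaries[reader] = accuracy_summary(
            counts, np.zeros(len(eval_cohort), dtype=bool),
            ci_level=config.analysis.ci_level)

    comparisons = {}
    workload = {}
    for scenario in (AI_FIRST, AI_SECOND, AI_TRIAGE):
        comparisons[scenario] = stage(
            f"compare:{scenario}", compare_scenarios, eval_cohort,
            outcomes[scenario], combined,
            alpha_coprimary=config.analysis.alpha_coprimary,
            alpha_secondary=config.analysis.alpha_secondary,
            mcnemar_exact_cutoff=config.analysis.mcnemar_exact_cutoff)
        workload[scenario] = tally_workload(outcomes[scenario], combined)

    subgroup_rows = []
    for name, out in outcomes.items():
        for sub in (SCREEN_DETECTED, INTERVAL):
            est = subgroup_sensitivity(out, eval_cohort, sub,
                                       ci_level=config.analysis.ci_level)
            subgroup_rows.append({"scenario": name, "subgroup": sub,
                                  "sensitivity": est.value,
                                  "lower": est.lower, "upper": est.upper})
    subgroups = pd.DataFrame(subgroup_rows)

    report = StudyReport(cohort=eval_cohort, thresholds=thresholds,
                         profile=profile, outcomes=outcomes,
                         summaries=summaries, comparisons=comparisons,
                         workload=workload, subgroups=subgroups, flow=flow)
    if config.output_dir is not None:
        report.output_dir = Path(config.output_dir)
        stage("write", _write_bundle, report, config)
    return report


def _summary_row(name: str, summary) -> dict:
    row: dict[str, object] = {"workflow": name}
    for metric in ("sensitivity", "specificity", "ppv", "npv", "recall_rate",
                   "arbitration_rate", "cdr_per_1000"):
        est = getattr(summary, metric)
        row[metric] = est.value
        row[f"{metric}_lower"] = est.lower
        row[f"{metric}_upper"] = est.upper
    row["auc"] = summary.auc
    return row


def _write_bundle(report: StudyReport, config: StudyConfig) -> None:
    out = report.output_dir
    assert out is not None
    out.mkdir(parents=True, exist_ok=True)

    write_cohort(report.cohort, out / "cohort.csv")
    report.thresholds.to_json(out / "thresholds.json")

    for name, df in report.outcomes.items():
        df.to_csv(out / f"outcomes_{name}.csv", index=False, encoding="utf-8")

    order = ["reader1", "reader2", COMBINED, AI_FIRST, AI_SECOND, AI_TRIAGE]
    table1 = pd.DataFrame([_summary_row(n, report.summaries[n]) for n in order])
    table1.to_csv(out / "table1_summary.tsv", sep="\t", index=False)

    truth = report.cohort["truth"].to_numpy()
    rows = []
    for name in (COMBINED, AI_FIRST, AI_SECOND, AI_TRIAGE):
        cc = confusion_counts(report.outcomes[name]["final_recall"].to_numpy(),
                              truth)
        row = {"workflow": name, "tp": cc.tp, "fp": cc.fp, "fn": cc.fn,
               "tn": cc.tn,
               "total_reads": int(report.outcomes[name]["human_reads"].sum())}
        if name in report.workload:
            row["read_reduction_pct"] = report.workload[name].relative_reduction
        else:
            row["read_reduction_pct"] = 0.0
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "table2_crosstab_workload.tsv", sep="\t",
                              index=False)

    report.subgroups.to_csv(out / "table3_subgroups.tsv", sep="\t", index=False)

    comp_payload = {
        scenario: [dataclasses.asdict(c) | {"significant": c.significant}
                   for c in comps]
        for scenario, comps in report.comparisons.items()
    }
    with open(out / "comparisons.json", "w", encoding="utf-8") as fh:
        json.dump(comp_payload, fh, indent=2)

    ai_auc = empirical_auc(report.cohort["ai_score"].to_numpy(), truth)
    log_lines = [
        f"screensim {__version__}",
        f"seed {config.master_seed}",
        f"n_exams {len(report.cohort)}",
        f"split_mode {config.split_mode}",
        "rng_substreams " + ",".join(
            f"{k}:{v}" for k, v in sorted(STREAM_OFFSETS.items())),
        f"numpy {np.__version__} pandas {pd.__version__}",
        (f"arbitrator_profile sens={report.profile.sens:.6f} "
         f"spec={report.profile.spec:.6f} "
         f"n_cancer={report.profile.n_cancer_est} "
         f"n_noncancer={report.profile.n_noncancer_est}"),
        f"ai_score_auc {ai_auc:.6f}",
        (f"flow initial={report.flow.initial_n} "
         f"excluded={report.flow.exclusion_total} final={report.flow.final_n}"),
    ]
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
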