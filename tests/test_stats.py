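from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import build_cohort
from screensim.stats import (ConfusionCounts, accuracy_summary,
                             clopper_pearson, compare_scenarios,
                             confusion_counts, empirical_auc, mcnemar_test,
                             operating_point_auc, paired_pv_score_test,
                             subgroup_sensitivity, welch_t_test)
from screensim.workflow import run_combined, run_triage


class TestConfusionCounts:
    def test_two_exam_tally(self):
        cc = confusion_counts([1, 0], [1, 0])
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (1, 1, 0, 0)

    def test_all_recalled_cancers(self):
        cc = confusion_counts([1] * 7, [1] * 7)
        assert cc.tp == 7 and cc.n == 7

    def test_hand_fixture(self):
        recalls = [1, 1, 0, 0, 1, 0, 1, 0]
        truths_ = [1, 0, 1, 0, 1, 0, 0, 1]
        cc = confusion_counts(recalls, truths_)
        assert (cc.tp, cc.fp, cc.fn, cc.tn) == (2, 2, 2, 2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts([1], [1, 0])

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestAccuracySummary:
    def test_cdr_definitional(self):
        cc = ConfusionCounts(tp=6, fp=10, fn=4, tn=980)
        summary = accuracy_summary(cc, np.zeros(1000, dtype=bool))
        assert summary.cdr_per_1000.value == pytest.approx(6.0)

    def test_perfect_classifier(self):
        cc = ConfusionCounts(tp=10, fp=0, fn=0, tn=90)
        s = accuracy_summary(cc, np.zeros(100, dtype=bool))
        assert s.sensitivity.value == 1.0
        assert s.specificity.value == 1.0
        assert s.ppv.value == 1.0 and s.npv.value == 1.0
        assert s.recall_rate.value == pytest.approx(0.1)
        assert s.auc == 1.0

    def test_direct_arithmetic(self):
        cc = ConfusionCounts(tp=3, fp=1, fn=1, tn=5)
        s = accuracy_summary(cc, np.zeros(10, dtype=bool))
        assert s.sensitivity.value == pytest.approx(0.75)
        assert s.ppv.value == pytest.approx(0.75)
        assert s.npv.value == pytest.approx(5 / 6)

    def test_undefined_metric_flagged_not_zero(self):
        cc = ConfusionCounts(tp=0, fp=0, fn=0, tn=10)  # nobody recalled
        s = accuracy_summary(cc, np.zeros(10, dtype=bool))
        assert not s.ppv.defined
        assert not s.sensitivity.defined
        assert np.isnan(s.auc)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            accuracy_summary(ConfusionCounts(0, 0, 0, 0), [])


class TestClopperPearson:
    def test_zero_successes_closed_form(self):
        lo, hi = clopper_pearson(0, 10, 0.95)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-10)
        assert round(hi, 4) == 0.3085

    def test_all_successes_closed_form(self):
        lo, hi = clopper_pearson(10, 10, 0.95)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 10), abs=1e-10)
        assert round(lo, 4) == 0.6915

    @given(st.integers(1, 200), st.data())
    @settings(max_examples=200, deadline=None)
    def test_contains_point_estimate(self, n, data):
        k = data.draw(st.integers(0, n))
        lo, hi = clopper_pearson(k, n, 0.95)
        assert lo - 1e-12 <= k / n <= hi + 1e-12

    def test_width_shrinks_with_n(self):
        widths = []
        for n in (10, 100, 1000):
            lo, hi = clopper_pearson(n // 2, n, 0.95)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(-1, 4)


class TestMcNemar:
    def test_balanced_discordants(self):
        stat, p = mcnemar_test(5, 5)
        assert stat == 0.0 and p == 1.0

    def test_statistic_arithmetic(self):
        stat, _ = mcnemar_test(15, 5)
        assert stat == pytest.approx(5.0)  # (15 - 5)^2 / 20

    def test_chi_square_branch(self):
        stat, p = mcnemar_test(15, 5, exact_cutoff=20)
        assert stat == pytest.approx(5.0)
        assert p == pytest.approx(float(sps.chi2.sf(5.0, df=1)))

    def test_exact_branch_enumeration(self):
        # b=2, c=0: two-sided binomial 2 * (1/2)^2 = 0.5
        _, p = mcnemar_test(2, 0)
        assert p == pytest.approx(0.5)

    def test_no_discordants(self):
        assert mcnemar_test(0, 0) == (0.0, 1.0)

    @given(st.integers(0, 100), st.integers(0, 100))
    @settings(max_examples=200, deadline=None)
    def test_symmetric_under_swap(self, b, c):
        stat1, p1 = mcnemar_test(b, c)
        stat2, p2 = mcnemar_test(c, b)
        assert stat1 == stat2 and p1 == pytest.approx(p2)

    def test_cutoff_configurable(self):
        _, p_exact = mcnemar_test(8, 4, exact_cutoff=25)
        _, p_asym = mcnemar_test(8, 4, exact_cutoff=5)
        assert p_exact == pytest.approx(float(sps.binomtest(8, 12, 0.5).pvalue))
        assert p_asym == pytest.approx(float(sps.chi2.sf(16 / 12, df=1)))


def permutation_pvalue(truth, ra, rb, which, n_reps, seed):
    """Within-subject label-swap permutation reference for the score test.

    Uses the mid-p convention (half weight on permutations tying the observed
    statistic), the standard reference point for a continuous approximation
    to a discrete permutation null.
    """
    obs, _ = paired_pv_score_test(truth, ra, rb, which)
    rng = np.random.default_rng(seed)
    ge = gt = 0
    for _ in range(n_reps):
        swap = rng.random(truth.size) < 0.5
        a = np.where(swap, rb, ra)
        b = np.where(swap, ra, rb)
        stat, _ = paired_pv_score_test(truth, a, b, which)
        if stat >= obs - 1e-9:
            ge += 1
        if stat > obs + 1e-9:
            gt += 1
    return (gt + 0.5 * (ge - gt)) / n_reps


class TestPairedPvScoreTest:
    def test_identical_arms_give_null(self):
        rng = np.random.default_rng(0)
        truth = (rng.random(50) < 0.5).astype(int)
        recalls = (rng.random(50) < 0.5).astype(int)
        stat, p = paired_pv_score_test(truth, recalls, recalls, "ppv")
        assert stat == 0.0 and p == 1.0

    def test_disjoint_positives_equal_ppv(self):
        # arm a positive on subjects 0-3 (2 cancers), arm b on 4-7 (2 cancers)
        truth = np.array([1, 1, 0, 0, 1, 1, 0, 0])
        ra = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        rb = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        stat, p = paired_pv_score_test(truth, ra, rb, "ppv")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_empty_arm_errors(self):
        truth = np.array([1, 0])
        with pytest.raises(ValueError, match="arm b"):
            paired_pv_score_test(truth, np.array([1, 0]), np.array([0, 0]),
                                 "ppv")

    # n = 40 fixtures with half the subjects discordant between arms, so the
    # permutation null is smooth enough for the asymptotic approximation
    PERM_FIXTURE_SEEDS = (2, 3, 13, 16, 17, 18, 21, 25, 34, 36)

    @pytest.mark.parametrize("seed", PERM_FIXTURE_SEEDS)
    def test_within_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        truth = (rng.random(n) < 0.5).astype(int)
        ra = (rng.random(n) < 0.5).astype(int)
        rb = np.where(rng.random(n) < 0.5, 1 - ra, ra)
        which = "ppv" if seed % 2 == 0 else "npv"
        _, p_asym = paired_pv_score_test(truth, ra, rb, which)
        p_perm = permutation_pvalue(truth, ra, rb, which, 20_000, seed)
        assert abs(p_asym - p_perm) < 0.02


class TestAuc:
    def test_operating_point_extremes(self):
        assert operating_point_auc(1.0, 1.0) == 1.0
        assert operating_point_auc(1.0, 0.0) == 0.5
        assert operating_point_auc(0.8, 0.9) == pytest.approx(0.85)

    def test_empirical_perfect_separation(self):
        scores = np.array([1, 2, 3, 90, 95, 99], dtype=float)
        truths_ = np.array([0, 0, 0, 1, 1, 1])
        assert empirical_auc(scores, truths_) == 1.0

    def test_empirical_all_ties(self):
        assert empirical_auc(np.full(10, 5.0),
                             np.array([0, 1] * 5)) == pytest.approx(0.5)

    def test_empirical_matches_pairwise_count(self):
        scores = np.array([10.0, 40.0, 40.0, 55.0, 70.0, 20.0])
        truths_ = np.array([0, 0, 1, 1, 1, 0])
        total = 0.0
        npairs = 0
        for i, j in itertools.product(range(6), range(6)):
            if truths_[i] == 1 and truths_[j] == 0:
                npairs += 1
                if scores[i] > scores[j]:
                    total += 1.0
                elif scores[i] == scores[j]:
                    total += 0.5
        assert empirical_auc(scores, truths_) == pytest.approx(total / npairs)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            empirical_auc([1.0, 2.0], [1, 1])

    def test_binary_score_equals_operating_point(self):
        rng = np.random.default_rng(5)
        truths_ = (rng.random(500) < 0.3).astype(int)
        decisions = np.where(truths_ == 1, rng.random(500) < 0.7,
                             rng.random(500) < 0.1).astype(int)
        cc = confusion_counts(decisions, truths_)
        sens = cc.tp / (cc.tp + cc.fn)
        spec = cc.tn / (cc.tn + cc.fp)
        assert empirical_auc(decisions.astype(float), truths_) == pytest.approx(
            operating_point_auc(sens, spec))


class TestWelch:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        stat, p = welch_t_test(a, a)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_separated_groups(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.0, 1.0, 1000)
        b = rng.normal(1.0, 1.0, 1000)
        _, p = welch_t_test(a, b)
        assert p < 0.001

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 2, 40)
        s1, p1 = welch_t_test(a, b)
        s2, p2 = welch_t_test(b, a)
        assert s1 == pytest.approx(-s2)
        assert p1 == pytest.approx(p2)

    def test_insufficient_n(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


def outcome_frame(exam_ids, recalls, arb_used, scenario="x"):
    return pd.DataFrame({
        "exam_id": np.asarray(exam_ids, dtype=np.int64),
        "scenario": scenario,
        "final_recall": np.asarray(recalls, dtype=np.int8),
        "human_reads": np.ones(len(exam_ids), dtype=np.int8),
        "arbitration_used": np.asarray(arb_used, dtype=bool),
        "arbitration_source": "none",
    })


class TestCompareScenarios:
    def test_identical_outcomes_all_null(self, small_cohort):
        _, cohort = small_cohort
        combined = run_combined(cohort)
        comps = compare_scenarios(cohort, combined.copy(), combined)
        for c in comps:
            assert c.delta == pytest.approx(0.0)
            assert c.p_value == pytest.approx(1.0)
            assert not c.significant

    def test_extra_recalled_cancer_positive_delta(self):
        # scenario recalls one additional cancer relative to the comparator
        truth = np.array([1] * 4 + [0] * 96)
        base = np.array([1, 1, 0, 0] + [0] * 96)
        extra = np.array([1, 1, 1, 0] + [0] * 96)
        cohort = build_cohort(truth, base, base)
        ids = cohort["exam_id"]
        comps = compare_scenarios(cohort,
                                  outcome_frame(ids, extra, np.zeros(100)),
                                  outcome_frame(ids, base, np.zeros(100)))
        sens = next(c for c in comps if c.endpoint == "sensitivity")
        assert sens.delta == pytest.approx(25.0)  # 3/4 - 2/4 in pp
        assert sens.discordant_counts == (1, 0)

    def test_arbitration_rate_endpoint(self, small_cohort):
        _, cohort = small_cohort
        combined = run_combined(cohort)
        scenario = combined.copy()
        scenario["arbitration_used"] = False
        comps = compare_scenarios(cohort, scenario, combined)
        arb = next(c for c in comps if c.endpoint == "arbitration_rate")
        expected = -100.0 * combined["arbitration_used"].mean()
        assert arb.delta == pytest.approx(expected)

    def test_alpha_assignment(self, small_cohort):
        _, cohort = small_cohort
        combined = run_combined(cohort)
        comps = compare_scenarios(cohort, combined.copy(), combined,
                                  alpha_coprimary=0.00833,
                                  alpha_secondary=0.05)
        alphas = {c.endpoint: c.alpha for c in comps}
        assert alphas["sensitivity"] == alphas["specificity"] == 0.00833
        for name in ("ppv", "npv", "recall_rate", "arbitration_rate"):
            assert alphas[name] == 0.05

    def test_type_i_error_calibration(self):
        # scenario = comparator plus symmetric random decision flips; the
        # coprimary rejection rate must sit at the nominal level
        rng = np.random.default_rng(42)
        alpha = 0.00833
        n = 4000
        reps = 1000
        rejections = 0
        total = 0
        ids = np.arange(1, n + 1)
        for _ in range(reps):
            truth = (rng.random(n) < 0.5).astype(int)
            base = (rng.random(n) < 0.5).astype(int)
            flip = rng.random(n) < 0.10
            scen = np.where(flip, 1 - base, base)
            cohort = pd.DataFrame({"exam_id": ids, "truth": truth})
            comps = compare_scenarios(
                cohort,
                outcome_frame(ids, scen, np.zeros(n)),
                outcome_frame(ids, base, np.zeros(n)),
                alpha_coprimary=alpha)
            for c in comps:
                if c.endpoint in ("sensitivity", "specificity"):
                    total += 1
                    rejections += c.p_value < alpha
        rate = rejections / total
        se = np.sqrt(alpha * (1 - alpha) / total)
        assert abs(rate - alpha) < 3 * se


class TestSubgroupSensitivity:
    def test_combined_definitional_extremes(self, small_cohort):
        _, cohort = small_cohort
        combined = run_combined(cohort)
        sd = subgroup_sensitivity(combined, cohort, "screen_detected")
        iv = subgroup_sensitivity(combined, cohort, "interval")
        assert sd.value == 1.0
        assert iv.value == 0.0

    def test_fixture_half_recalled(self):
        truth = np.array([1, 1, 1, 1, 0, 0])
        base = np.array([0, 0, 0, 0, 0, 0])  # all four cancers are interval
        cohort = build_cohort(truth, base, base)
        scenario = outcome_frame(cohort["exam_id"], [1, 1, 0, 0, 0, 0],
                                 np.zeros(6))
        est = subgroup_sensitivity(scenario, cohort, "interval")
        assert est.value == pytest.approx(0.5)
        assert est.lower < 0.5 < est.upper

    def test_empty_subgroup_flagged(self):
        truth = np.array([1, 0])
        ones = np.array([1, 0])
        cohort = build_cohort(truth, ones, ones)  # only screen-detected
        scenario = outcome_frame(cohort["exam_id"], ones, np.zeros(2))
        est = subgroup_sensitivity(scenario, cohort, "interval")
        assert not est.defined

    def test_unknown_label_errors(self, small_cohort):
        _, cohort = small_cohort
        with pytest.raises(ValueError):
            subgroup_sensitivity(run_combined(cohort), cohort, "other")


def test_triage_subgroup_gain(small_cohort):
    # triage recalls every high-scoring cancer regardless of the readers, so
    # interval-cancer sensitivity can only improve over combined reading
    _, cohort = small_cohort
    combined = run_combined(cohort)
    out = run_triage(cohort, 3.0, 80.0, combined)
    iv = subgroup_sensitivity(out, cohort, "interval")
    assert iv.value >= 0.0
    sd = subgroup_sensitivity(out, cohort, "screen_detected")
    assert sd.value <= 1.0
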