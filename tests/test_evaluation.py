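"""NDCG, criteria compliance and cohort reporting."""

import itertools
import math

import numpy as np
import pytest

from doseret import (
    check_criteria,
    cohort_compliance,
    cohort_summary,
    confusion,
    dcg,
    load_criteria,
    ndcg,
)
from doseret.dosimetry import PlanMetrics
from doseret.evaluation import CriteriaReport, RelevanceGrades


def _metrics(plan_id="p", **overrides) -> PlanMetrics:
    base = dict(
        ptv_d2=64.0, ptv_d98=58.0, ptv_d99=57.0, ptv_dmean=62.0,
        ptv_ci=0.7, ptv_hi=0.1, lung_v5=30.0, lung_v20=15.0, mld=10.0,
        cord_dmax=40.0, heart_v30=15.0, heart_v40=10.0, heart_v45=8.0,
        heart_v60=2.0, mhd=10.0,
    )
    base.update(overrides)
    return PlanMetrics(plan_id=plan_id, **base)


class TestDCG:
    def test_zero_relevance_zero_gain(self):
        assert dcg([0, 0, 0], 3) == 0.0

    def test_single_relevant_item(self):
        assert dcg([1], 1) == pytest.approx(1.0)

    def test_term_by_term_worked_value(self):
        # (2^1-1)/log2(2) + (2^0-1)/log2(3) + (2^2-1)/log2(4) = 1 + 0 + 1.5
        assert dcg([1, 0, 2], 3) == pytest.approx(2.5)

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            dcg([1], 0)


class TestNDCG:
    def test_descending_order_is_ideal(self):
        assert ndcg([3, 2, 2, 0], 4) == pytest.approx(1.0)

    def test_all_zero_convention(self):
        assert ndcg([0, 0, 0], 3) == 0.0

    def test_worked_value(self):
        ideal = 3.0 + 1.0 / math.log2(3.0)  # grades sorted: [2, 1, 0]
        assert ndcg([1, 0, 2], 3) == pytest.approx(2.5 / ideal)
        assert ndcg([1, 0, 2], 3) == pytest.approx(0.6885, abs=5e-4)

    def test_all_permutations_bounded_with_equality_only_descending(self):
        grades = (3, 2, 1, 0)
        for perm in itertools.permutations(grades):
            v = ndcg(list(perm), 4)
            assert v <= 1.0 + 1e-12
            if list(perm) == sorted(perm, reverse=True):
                assert v == pytest.approx(1.0)
            else:
                assert v < 1.0

    def test_order_preserving_regrade_keeps_perfect_score(self):
        assert ndcg([9, 5, 5, 1], 4) == pytest.approx(1.0)


class TestGrading:
    def test_same_patient_beats_same_class_beats_other(self):
        g = RelevanceGrades()
        assert g("q", 1, "q", 1) == 3
        assert g("q", 1, "other", 1) == 2
        assert g("q", 1, "other", 2) == 0


class TestCriteria:
    def test_rule_inventories(self):
        assert len(load_criteria("rtog0623")) == 6
        assert len(load_criteria("nccn")) == 8
        assert len(load_criteria("department")) == 7

    def test_cord_46gy_fails_rtog_passes_nccn_cord_rule(self):
        m = _metrics(cord_dmax=46.0)
        rtog = check_criteria(m, load_criteria("rtog0623"))
        nccn = check_criteria(m, load_criteria("nccn"))
        cord_rtog = [o for o in rtog.outcomes if o.rule.structure == "spinal_cord"][0]
        cord_nccn = [o for o in nccn.outcomes if o.rule.structure == "spinal_cord"][0]
        assert not cord_rtog.passed and not rtog.overall_pass
        assert cord_nccn.passed

    def test_all_zero_metrics_pass_everything(self):
        m = _metrics(
            cord_dmax=0, lung_v5=0, lung_v20=0, mld=0,
            heart_v30=0, heart_v40=0, heart_v45=0, heart_v60=0, mhd=0,
        )
        for name in ("rtog0623", "nccn", "department"):
            assert check_criteria(m, load_criteria(name)).overall_pass

    def test_strict_comparator_at_department_v20_boundary(self):
        m = _metrics(lung_v20=25.0, lung_v5=0, mld=0, heart_v30=0, heart_v40=0, mhd=0)
        rep = check_criteria(m, load_criteria("department"))
        v20 = [o for o in rep.outcomes if o.rule.metric == "V20"][0]
        assert not v20.passed

    def test_lte_comparator_at_boundary_passes(self):
        m = _metrics(cord_dmax=45.0)
        rep = check_criteria(m, load_criteria("rtog0623"))
        cord = [o for o in rep.outcomes if o.rule.metric == "Dmax"][0]
        assert cord.passed

    def test_advisory_exclusion_flag(self):
        m = _metrics(mhd=30.0, lung_v5=0, lung_v20=0, mld=0, heart_v30=0, heart_v40=0)
        dept = load_criteria("department")
        assert not check_criteria(m, dept).overall_pass
        assert check_criteria(m, dept, include_advisory=False).overall_pass


def _report(pid, ok):
    return CriteriaReport(plan_id=pid, criteria_name="t", outcomes=[], overall_pass=ok)


class TestCohortReports:
    def test_compliance_worked_percentage(self):
        reports = [_report(f"p{i}", i < 52) for i in range(96)]
        n, pct = cohort_compliance(reports)
        assert n == 52
        assert pct == pytest.approx(54.17, abs=0.005)

    def test_all_pass(self):
        assert cohort_compliance([_report("a", True)] * 3) == (3, 100.0)

    def test_compliance_matches_recount(self, rng):
        flags = rng.random(40) > 0.5
        reports = [_report(f"p{i}", bool(f)) for i, f in enumerate(flags)]
        n, pct = cohort_compliance(reports)
        assert n == int(flags.sum())

    def test_confusion_identical_lists_no_disagreement(self):
        a = [_report(f"p{i}", i % 2 == 0) for i in range(6)]
        c = confusion(a, a)
        assert c.a_only == c.b_only == 0
        assert c.total == 6

    def test_confusion_disjoint_outcomes(self):
        a = [_report(f"p{i}", True) for i in range(4)]
        b = [_report(f"p{i}", False) for i in range(4)]
        c = confusion(a, b)
        assert (c.both_pass, c.a_only, c.b_only, c.both_fail) == (0, 4, 0, 0)

    def test_confusion_matches_recount(self, rng):
        fa = rng.random(30) > 0.4
        fb = rng.random(30) > 0.6
        a = [_report(f"p{i}", bool(x)) for i, x in enumerate(fa)]
        b = [_report(f"p{i}", bool(x)) for i, x in enumerate(fb)]
        c = confusion(a, b)
        assert c.both_pass == int((fa & fb).sum())
        assert c.a_only == int((fa & ~fb).sum())
        assert c.b_only == int((~fa & fb).sum())
        assert c.both_fail == int((~fa & ~fb).sum())
        assert c.total == 30

    def test_misaligned_ids_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            confusion([_report("a", True)], [_report("b", True)])


class TestCohortSummary:
    def test_two_plan_hand_arithmetic(self):
        ms = [_metrics("a", ptv_d2=65.0), _metrics("b", ptv_d2=66.0)]
        table = cohort_summary(ms)
        row = table.loc["PTV_D2"]
        assert row["mean"] == pytest.approx(65.5)
        assert row["sd"] == pytest.approx(np.std([65, 66], ddof=1))
        assert row["mean_sd"] == "65.50 ± 0.71"

    def test_single_plan_sd_rendered_zero(self):
        table = cohort_summary([_metrics("a")])
        assert table.loc["PTV_D2", "mean_sd"].endswith("± 0.00")

    def test_constant_metric_zero_sd(self):
        table = cohort_summary([_metrics("a"), _metrics("b"), _metrics("c")])
        assert table.loc["heart_MHD", "sd"] == 0.0
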