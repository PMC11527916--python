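"""Ranking quality, criteria compliance and cohort-level reporting.

Three evaluation layers:

* **NDCG** — normalized discounted cumulative gain over the top K retrieved
  plans, DCG_K = sum_i (2^r_i - 1) / log2(i + 1) with 1-based positions,
  normalized by the DCG of the descending-sorted relevance grades.
* **Criteria compliance** — named rule sets (RTOG 0623, NCCN, a
  departmental standard) of (structure, metric, comparator, threshold)
  constraints applied to a plan's metric bundle.
* **Cohort reports** — pass counts/percentages, pairwise pass/fail
  confusion matrices between two plan cohorts, and mean ± SD summary
  tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import PlanDatabase
from .dosimetry import PlanMetrics
from .encoder import EncoderWeights, encode_batch, preprocess
from .retrieval import FeatureIndex, query

__all__ = [
    "RelevanceGrades",
    "CriteriaRule",
    "CriteriaSet",
    "RuleOutcome",
    "CriteriaReport",
    "ConfusionCounts",
    "dcg",
    "ndcg",
    "default_grading",
    "retrieval_benchmark",
    "BenchmarkResult",
    "load_criteria",
    "builtin_criteria_names",
    "check_criteria",
    "cohort_compliance",
    "confusion",
    "cohort_summary",
]

# ---------------------------------------------------------------------------
# NDCG

#: default relevance grades for the synthetic benchmark: retrieving the
#: query's own plan is ideal, a plan of the same beam-geometry class is
#: useful, anything else is irrelevant.
GRADE_SAME_PATIENT = 3
GRADE_SAME_CLASS = 2
GRADE_OTHER = 0


def dcg(relevances: Sequence[float], k: int) -> float:
    """Discounted cumulative gain of the first *k* positions (1-based)."""
    if k < 1:
        raise ValueError("K must be >= 1")
    rel = np.asarray(list(relevances), dtype=float)[:k]
    if np.any(rel < 0) or not np.all(np.isfinite(rel)):
        raise ValueError("relevance grades must be finite and non-negative")
    positions = np.arange(1, rel.size + 1)
    return float(np.sum((2.0**rel - 1.0) / np.log2(positions + 1)))


def ndcg(relevances: Sequence[float], k: int) -> float:
    """NDCG_K = DCG_K / iDCG_K, in [0, 1].

    iDCG is the DCG of the same grades sorted descending.  An all-zero
    grade list has iDCG 0; NDCG is then defined as 0.
    """
    rel = list(relevances)
    actual = dcg(rel, k)
    ideal = dcg(sorted(rel, reverse=True), k)
    if ideal == 0.0:
        return 0.0
    return actual / ideal


class RelevanceGrades:
    """Grades a retrieved hit against a query by identity and class."""

    def __init__(
        self,
        same_patient: int = GRADE_SAME_PATIENT,
        same_class: int = GRADE_SAME_CLASS,
        other: int = GRADE_OTHER,
    ):
        self.same_patient = same_patient
        self.same_class = same_class
        self.other = other

    def __call__(self, query_id: str, query_class: int | None, hit_id: str, hit_class: int | None) -> int:
        if hit_id == query_id:
            return self.same_patient
        if query_class is not None and hit_class is not None and query_class == hit_class:
            return self.same_class
        return self.other


def default_grading() -> RelevanceGrades:
    return RelevanceGrades()


@dataclass
class BenchmarkResult:
    """Leave-query-out retrieval quality over a labeled cohort."""

    per_query: pd.DataFrame  # columns: query_id, ndcg, top1_id, top1_grade, top1_class_correct
    mean_ndcg: float
    sd_ndcg: float
    top1_class_accuracy: float  # fraction in [0, 1]
    k: int


def retrieval_benchmark(
    index: FeatureIndex,
    weights: EncoderWeights,
    db: PlanDatabase,
    grading: RelevanceGrades | None = None,
    k: int = 3,
) -> BenchmarkResult:
    """Query every plan's virtual dose against the others' clinical features.

    Leave-query-out: the query's own entry is removed from the index, so a
    perfect retrieval returns same-class plans.  Reports per-query NDCG@k,
    its mean ± sample SD, and top-1 class accuracy.  Deterministic given
    the weights.
    """
    grading = grading or default_grading()
    labels = {r.plan_id: r.class_label for r in db}
    if any(v is None for v in labels.values()):
        raise ValueError("retrieval_benchmark needs class labels on every record")
    vols = np.stack(
        [preprocess(r.virtual_dose, r.prescription_gy, weights.spec) for r in db]
    )
    fvs = encode_batch(weights, vols)
    rows = []
    for rec, fv in zip(db, fvs):
        sub = index.drop(rec.plan_id)
        res = query(sub, fv, k=k, query_id=rec.plan_id)
        grades = [
            grading(rec.plan_id, rec.class_label, pid, labels[pid]) for pid, _ in res.hits
        ]
        top1_id = res.hits[0][0]
        rows.append(
            {
                "query_id": rec.plan_id,
                "ndcg": ndcg(grades, k),
                "top1_id": top1_id,
                "top1_grade": grades[0],
                "top1_class_correct": labels[top1_id] == rec.class_label,
            }
        )
    df = pd.DataFrame(rows)
    return BenchmarkResult(
        per_query=df,
        mean_ndcg=float(df["ndcg"].mean()),
        sd_ndcg=float(df["ndcg"].std(ddof=1)) if len(df) > 1 else 0.0,
        top1_class_accuracy=float(df["top1_class_correct"].mean()),
        k=k,
    )


# ---------------------------------------------------------------------------
# Criteria compliance


@dataclass(frozen=True)
class CriteriaRule:
    structure: str
    metric: str
    comparator: str  # "<=" or "<"
    threshold: float
    units: str = ""
    advisory: bool = False

    def check(self, value: float) -> bool:
        if self.comparator == "<=":
            return value <= self.threshold
        if self.comparator == "<":
            return value < self.threshold
        raise ValueError(f"unknown comparator {self.comparator!r}")

    def label(self) -> str:
        return f"{self.structure} {self.metric} {self.comparator} {self.threshold:g} {self.units}"


@dataclass
class CriteriaSet:
    """A named set of dose-constraint rules."""

    name: str
    rules: list[CriteriaRule]
    version: str = "1.0"

    def __len__(self) -> int:
        return len(self.rules)


def builtin_criteria_names() -> list[str]:
    return ["RTOG0623", "NCCN", "department"]


def load_criteria(name: str) -> CriteriaSet:
    """Load one of the shipped criteria sets (case-insensitive name)."""
    fname = {
        "rtog0623": "rtog0623.json",
        "nccn": "nccn.json",
        "department": "department.json",
    }.get(name.lower())
    if fname is None:
        raise ValueError(f"unknown criteria set {name!r}; have {builtin_criteria_names()}")
    text = resources.files("doseret.criteria").joinpath(fname).read_text()
    data = json.loads(text)
    rules = [
        CriteriaRule(
            structure=r["structure"],
            metric=r["metric"],
            comparator=r["comparator"],
            threshold=float(r["threshold"]),
            units=r.get("units", ""),
            advisory=bool(r.get("advisory", False)),
        )
        for r in data["rules"]
    ]
    return CriteriaSet(name=data["name"], rules=rules, version=data.get("version", "1.0"))


@dataclass
class RuleOutcome:
    rule: CriteriaRule
    value: float
    passed: bool


@dataclass
class CriteriaReport:
    plan_id: str
    criteria_name: str
    outcomes: list[RuleOutcome]
    overall_pass: bool


def check_criteria(
    metrics: PlanMetrics, criteria: CriteriaSet, include_advisory: bool = True
) -> CriteriaReport:
    """Apply every rule literally (respecting <= vs <) to a plan's metrics.

    ``include_advisory=False`` excludes advisory rules (the departmental
    mean-heart-dose guideline) from the overall verdict while still
    reporting them.
    """
    outcomes = []
    overall = True
    for rule in criteria.rules:
        value = metrics.value(rule.structure, rule.metric)
        ok = rule.check(value)
        outcomes.append(RuleOutcome(rule=rule, value=value, passed=ok))
        if include_advisory or not rule.advisory:
            overall = overall and ok
    return CriteriaReport(
        plan_id=metrics.plan_id,
        criteria_name=criteria.name,
        outcomes=outcomes,
        overall_pass=overall,
    )


def cohort_compliance(reports: Sequence[CriteriaReport]) -> tuple[int, float]:
    """(number of passing plans, percentage) over a cohort of reports."""
    if not reports:
        raise ValueError("empty report list")
    n_pass = sum(r.overall_pass for r in reports)
    return n_pass, 100.0 * n_pass / len(reports)


@dataclass
class ConfusionCounts:
    """Joint pass/fail counts between two aligned plan cohorts."""

    both_pass: int
    a_only: int
    b_only: int
    both_fail: int

    @property
    def total(self) -> int:
        return self.both_pass + self.a_only + self.b_only + self.both_fail


def confusion(
    reports_a: Sequence[CriteriaReport], reports_b: Sequence[CriteriaReport]
) -> ConfusionCounts:
    """2x2 confusion of overall pass status between aligned cohorts."""
    if len(reports_a) != len(reports_b):
        raise ValueError("report lists differ in length")
    counts = ConfusionCounts(0, 0, 0, 0)
    for ra, rb in zip(reports_a, reports_b):
        if ra.plan_id != rb.plan_id:
            raise ValueError(f"misaligned reports: {ra.plan_id!r} vs {rb.plan_id!r}")
        if ra.overall_pass and rb.overall_pass:
            counts.both_pass += 1
        elif ra.overall_pass:
            counts.a_only += 1
        elif rb.overall_pass:
            counts.b_only += 1
        else:
            counts.both_fail += 1
    return counts


#: fixed column order of cohort summary tables
_SUMMARY_COLUMNS = [
    "PTV_D2",
    "PTV_D98",
    "PTV_D99",
    "PTV_Dmean",
    "PTV_CI",
    "PTV_HI",
    "total_lung_V5",
    "total_lung_V20",
    "total_lung_MLD",
    "spinal_cord_Dmax",
    "heart_V30",
    "heart_V40",
    "heart_V45",
    "heart_V60",
    "heart_MHD",
]


def cohort_summary(metrics_list: Sequence[PlanMetrics]) -> pd.DataFrame:
    """Mean ± sample SD per metric over a cohort, two-decimal rendering.

    Columns: ``mean``, ``sd`` (numeric) and ``mean_sd`` ("m ± s" strings);
    a single-plan cohort renders SD as 0.00.
    """
    if not metrics_list:
        raise ValueError("empty metrics list")
    df = pd.DataFrame([m.as_dict() for m in metrics_list]).drop(columns=["plan_id"])
    df = df[_SUMMARY_COLUMNS]
    mean = df.mean()
    sd = df.std(ddof=1).fillna(0.0) if len(df) > 1 else pd.Series(0.0, index=df.columns)
    out = pd.DataFrame({"mean": mean, "sd": sd})
    out["mean_sd"] = [f"{m:.2f} ± {s:.2f}" for m, s in zip(out["mean"], out["sd"])]
    return out
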