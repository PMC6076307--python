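"""Diagnostic-accuracy metrics, pre-classification tallies and cost analysis.

All statistics derive from a 2×2 disease-versus-healthy confusion table
(asthma and COPD pooled as "disease").  Metrics with a zero denominator are
reported as ``None`` (undefined), never silently 0.  Percentages are kept
at full precision internally; ``display`` offers two-decimal rounding and
an optional truncation mode matching a common convention of dropping,
rather than rounding, trailing digits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import DataValidationError, UndefinedMetricError
from .pipeline import STAGE_ANN, EdsDecision

DISEASE_CATEGORIES = frozenset({"asthma", "copd"})


@dataclass(frozen=True)
class ConfusionCounts:
    """tp/fn: diseased called diseased/healthy; fp/tn: healthy called diseased/healthy."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise DataValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_labels(
        cls,
        true_categories: Iterable[str],
        predicted_categories: Iterable[str],
    ) -> "ConfusionCounts":
        """Tally disease-vs-healthy calls; inconclusive predictions count as
        positive (disease) calls, since they trigger further work-up."""
        tp = fn = fp = tn = 0
        for truth, pred in zip(true_categories, predicted_categories, strict=True):
            true_pos = truth in DISEASE_CATEGORIES
            pred_pos = pred in DISEASE_CATEGORIES or pred == "inconclusive"
            if true_pos and pred_pos:
                tp += 1
            elif true_pos:
                fn += 1
            elif pred_pos:
                fp += 1
            else:
                tn += 1
        return cls(tp=tp, fn=fn, fp=fp, tn=tn)


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den else None


def metrics(c: ConfusionCounts) -> dict[str, Optional[float]]:
    """Full named metric set; percentages in [0, 100], likelihood ratios as ratios.

    sensitivity = tp/(tp+fn)     specificity = tn/(tn+fp)
    ppv = tp/(tp+fp)             npv = tn/(tn+fn)
    miss_rate, fpr, fdr, false_condition_rate are the respective complements;
    positive_lr = sensitivity/fpr, negative_lr = miss_rate/specificity.
    """
    if c.total < 1:
        raise UndefinedMetricError("metrics of an empty confusion table")
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    miss = _ratio(c.fn, c.tp + c.fn)
    fpr = _ratio(c.fp, c.tn + c.fp)
    out: dict[str, Optional[float]] = {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": _ratio(c.tp + c.tn, c.total),
        "ppv": _ratio(c.tp, c.tp + c.fp),
        "npv": _ratio(c.tn, c.tn + c.fn),
        "prevalence": _ratio(c.tp + c.fn, c.total),
        "miss_rate": miss,
        "fpr": fpr,
        "fdr": _ratio(c.fp, c.tp + c.fp),
        "false_condition_rate": _ratio(c.fn, c.tn + c.fn),
    }
    out = {k: (None if v is None else v * 100.0) for k, v in out.items()}
    out["positive_lr"] = None if (sens is None or not fpr) else sens / fpr
    out["negative_lr"] = None if (miss is None or not spec) else miss / spec
    return out


def display(value: float, decimals: int = 2, truncate: bool = False) -> float:
    """Round (default) or truncate a percentage for presentation."""
    scale = 10**decimals
    if truncate:
        return math.floor(value * scale) / scale
    return round(value, decimals)


@dataclass(frozen=True)
class PreclassRow:
    label: str
    total: int
    correct: int
    percent_correct: Optional[float]


@dataclass(frozen=True)
class PreclassTable:
    rows: tuple[PreclassRow, ...]
    pooled_percent: Optional[float]  # sum(correct)/sum(total)
    macro_average_percent: Optional[float]  # unweighted mean of row percentages


def preclassification_table(
    per_class_counts: Sequence[tuple[str, int, int]],
) -> PreclassTable:
    """Per-row and pooled percent-correct for (label, total, correct) rows."""
    rows = []
    for label, total, correct in per_class_counts:
        if correct > total:
            raise DataValidationError(f"{label}: correct ({correct}) > total ({total})")
        pct = None if total == 0 else correct / total * 100.0
        rows.append(PreclassRow(label, total, correct, pct))
    grand_total = sum(r.total for r in rows)
    grand_correct = sum(r.correct for r in rows)
    defined = [r.percent_correct for r in rows if r.percent_correct is not None]
    return PreclassTable(
        rows=tuple(rows),
        pooled_percent=None if grand_total == 0 else grand_correct / grand_total * 100.0,
        macro_average_percent=sum(defined) / len(defined) if defined else None,
    )


@dataclass(frozen=True)
class CostModel:
    """Per-patient cost of a full confirmatory work-up (US dollars)."""

    spir_test_cost: float = 60.0
    filter_cost: float = 1.0
    specialist_visit_cost: float = 100.0
    blood_gas_cost: float = 10.0

    def __post_init__(self) -> None:
        if min(
            self.spir_test_cost,
            self.filter_cost,
            self.specialist_visit_cost,
            self.blood_gas_cost,
        ) < 0:
            raise DataValidationError("costs must be non-negative")

    @property
    def per_patient(self) -> float:
        return (
            self.spir_test_cost
            + self.filter_cost
            + self.specialist_visit_cost
            + self.blood_gas_cost
        )


def cost_savings(
    healthy_total: int, healthy_correct: int, costs: CostModel = CostModel()
) -> dict[str, float]:
    """Testing cost avoided by correctly triaging healthy patients out.

    saved_fraction = correct/total; saved_amount = correct × per-patient cost.
    """
    if healthy_total == 0:
        raise UndefinedMetricError("cost savings undefined for zero healthy patients")
    if healthy_correct > healthy_total:
        raise DataValidationError("correct count exceeds total")
    return {
        "saved_fraction": healthy_correct / healthy_total,
        "saved_amount": healthy_correct * costs.per_patient,
    }


def bdt_avoidance(decisions: Sequence[EdsDecision]) -> float:
    """Fraction of disease diagnoses concluded from spirometry alone,
    i.e. without requesting bronchodilatation/provocation testing."""
    diseased = [d for d in decisions if d.final_category in DISEASE_CATEGORIES]
    if not diseased:
        raise UndefinedMetricError("no diseased final decisions in cohort")
    at_ann = sum(1 for d in diseased if d.stage_reached == STAGE_ANN)
    return at_ann / len(diseased)
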