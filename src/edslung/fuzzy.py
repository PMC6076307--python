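"""Mamdani fuzzy output classifier for bronchial challenge results.

Invoked when spirometry alone is inconclusive: the inputs are the
bronchodilatation/provocation (BDT/BPT) outcome, expressed as a signed
"reversibility evidence" percentage (FEV1 gain after bronchodilator, or
the negated FEV1 fall after provocation), and the two questionnaire
probabilities.  Inference is classical Mamdani: min for conjunction,
consequents clipped at the rule firing strength, max aggregation across
rules and centroid defuzzification over the output universe, whose three
terms are healthy, asthma and COPD.

The rule base is declarative and fully overridable from configuration; the
default encodes guideline logic (positive reversibility → asthma,
irreversible obstruction with a high COPD score → COPD, neither → healthy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DataValidationError

HEALTHY = "healthy"
ASTHMA_OUT = "asthma"
COPD_OUT = "copd"
#: fixed tie-break order for defuzzified decisions
OUTPUT_ORDER = (HEALTHY, ASTHMA_OUT, COPD_OUT)


@dataclass(frozen=True)
class BronchialTestResult:
    """One BDT or BPT session: signed FEV1 change in percent and millilitres."""

    test_type: str  # "BDT" | "BPT"
    fev1_change_percent: float
    fev1_change_ml: float

    def __post_init__(self) -> None:
        if self.test_type not in ("BDT", "BPT"):
            raise DataValidationError(f"unknown bronchial test type {self.test_type!r}")
        p, v = self.fev1_change_percent, self.fev1_change_ml
        if p * v < 0:
            raise DataValidationError(
                f"FEV1 percent ({p}) and volume ({v} mL) changes disagree in sign"
            )

    def reversibility_evidence(self) -> float:
        """Signed evidence for airway lability: BDT gain, or negated BPT fall."""
        if self.test_type == "BDT":
            return self.fev1_change_percent
        return -self.fev1_change_percent


def bdt_positive(
    result: BronchialTestResult,
    percent_threshold: float = 12.0,
    ml_threshold: float = 200.0,
) -> bool:
    """Bronchodilator reversibility: FEV1 gain >= 12% AND >= 200 mL (defaults)."""
    if result.test_type != "BDT":
        raise DataValidationError("bdt_positive requires a BDT result")
    return (
        result.fev1_change_percent >= percent_threshold
        and result.fev1_change_ml >= ml_threshold
    )


def bpt_positive(result: BronchialTestResult, fall_threshold_percent: float = 20.0) -> bool:
    """Provocation hyperresponsiveness: FEV1 fall of at least the threshold."""
    if result.test_type != "BPT":
        raise DataValidationError("bpt_positive requires a BPT result")
    return result.fev1_change_percent <= -fall_threshold_percent


@dataclass(frozen=True)
class MembershipFunction:
    """Trapezoid (a, b, c, d); ±inf feet make open shoulders, b == c a triangle."""

    label: str
    points: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        a, b, c, d = self.points
        if not (a <= b <= c <= d):
            raise ConfigurationError(
                f"membership {self.label!r}: points must be ordered, got {self.points}"
            )

    @classmethod
    def triangle(cls, label: str, a: float, b: float, c: float) -> "MembershipFunction":
        return cls(label, (a, b, b, c))

    @classmethod
    def left_shoulder(cls, label: str, c: float, d: float) -> "MembershipFunction":
        return cls(label, (-math.inf, -math.inf, c, d))

    @classmethod
    def right_shoulder(cls, label: str, a: float, b: float) -> "MembershipFunction":
        return cls(label, (a, b, math.inf, math.inf))

    def __call__(self, x: float) -> float:
        a, b, c, d = self.points
        if x < b:
            if a == b:  # closed vertical edge
                return 0.0
            return max(0.0, min(1.0, (x - a) / (b - a)))
        if x > c:
            if c == d:
                return 0.0
            return max(0.0, min(1.0, (d - x) / (d - c)))
        return 1.0

    def center(self) -> float:
        """Representative point of the term (apex midpoint, finite feet only)."""
        a, b, c, d = self.points
        if math.isfinite(b) and math.isfinite(c):
            return (b + c) / 2.0
        return c if math.isfinite(c) else b


def fuzzify(value: float, functions: Sequence[MembershipFunction]) -> list[tuple[str, float]]:
    """Membership degree of ``value`` in every term."""
    if not functions:
        raise ConfigurationError("no membership functions supplied")
    return [(f.label, f(value)) for f in functions]


@dataclass(frozen=True)
class FuzzyRule:
    antecedent: Mapping[str, str]  # variable -> linguistic term
    consequent: str  # output term


@dataclass(frozen=True)
class FuzzyRuleBase:
    variables: Mapping[str, tuple[MembershipFunction, ...]]
    outputs: tuple[MembershipFunction, ...]
    rules: tuple[FuzzyRule, ...]
    universe: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        out_labels = [f.label for f in self.outputs]
        if len(set(out_labels)) != len(out_labels):
            raise ConfigurationError("duplicate output term labels")
        for i, rule in enumerate(self.rules):
            for var, term in rule.antecedent.items():
                if var not in self.variables:
                    raise ConfigurationError(f"rule {i}: unknown variable {var!r}")
                if term not in {f.label for f in self.variables[var]}:
                    raise ConfigurationError(
                        f"rule {i}: variable {var!r} has no term {term!r}"
                    )
            if rule.consequent not in out_labels:
                raise ConfigurationError(
                    f"rule {i}: unknown output term {rule.consequent!r}"
                )
        fired_terms = {r.consequent for r in self.rules}
        missing = set(out_labels) - fired_terms
        if missing:
            raise ConfigurationError(f"output terms with no rule: {sorted(missing)}")

    def output_function(self, label: str) -> MembershipFunction:
        for f in self.outputs:
            if f.label == label:
                return f
        raise ConfigurationError(f"unknown output term {label!r}")


def default_rule_base() -> FuzzyRuleBase:
    """Guideline-shaped default: reversibility → asthma; irreversible +
    high/medium COPD score → COPD; no lability and low COPD score → healthy."""
    prob_terms = (
        MembershipFunction.left_shoulder("low", 0.0, 40.0),
        MembershipFunction("medium", (0.0, 40.0, 60.0, 100.0)),
        MembershipFunction.right_shoulder("high", 60.0, 100.0),
    )
    rev_terms = (
        MembershipFunction.left_shoulder("low", 0.0, 12.0),
        MembershipFunction.right_shoulder("high", 0.0, 12.0),
    )
    outputs = (
        MembershipFunction.triangle(HEALTHY, 0.0, 15.0, 35.0),
        MembershipFunction.triangle(ASTHMA_OUT, 35.0, 50.0, 65.0),
        MembershipFunction.triangle(COPD_OUT, 65.0, 85.0, 100.0),
    )
    rules = tuple(
        FuzzyRule(antecedent=a, consequent=c)
        for a, c in [
            ({"reversibility": "high", "p_asthma": "high"}, ASTHMA_OUT),
            ({"reversibility": "high", "p_asthma": "medium"}, ASTHMA_OUT),
            ({"reversibility": "high", "p_asthma": "low"}, ASTHMA_OUT),
            ({"reversibility": "low", "p_copd": "high"}, COPD_OUT),
            ({"reversibility": "low", "p_copd": "medium"}, COPD_OUT),
            ({"reversibility": "low", "p_copd": "low", "p_asthma": "low"}, HEALTHY),
            ({"reversibility": "low", "p_copd": "low", "p_asthma": "medium"}, HEALTHY),
            ({"reversibility": "low", "p_copd": "low", "p_asthma": "high"}, HEALTHY),
        ]
    )
    return FuzzyRuleBase(
        variables={"reversibility": rev_terms, "p_asthma": prob_terms, "p_copd": prob_terms},
        outputs=outputs,
        rules=rules,
    )


def infer(rule_base: FuzzyRuleBase, inputs: Mapping[str, float]) -> dict[str, float]:
    """Aggregated output degree per term: max over rules of min-antecedent strength."""
    degrees: dict[str, dict[str, float]] = {}
    for var, terms in rule_base.variables.items():
        if var not in inputs:
            raise ConfigurationError(f"missing input variable {var!r}")
        degrees[var] = dict(fuzzify(inputs[var], terms))
    aggregate = {f.label: 0.0 for f in rule_base.outputs}
    for rule in rule_base.rules:
        strength = min(degrees[var][term] for var, term in rule.antecedent.items())
        aggregate[rule.consequent] = max(aggregate[rule.consequent], strength)
    return aggregate


@dataclass(frozen=True)
class FuzzyDecision:
    category: str
    confidence: float
    centroid: float


def classify_final(
    aggregate: Mapping[str, float],
    rule_base: FuzzyRuleBase,
    resolution: int = 1001,
) -> FuzzyDecision | None:
    """Centroid defuzzification mapped to the nearest output-term center.

    Returns ``None`` (no decision) when no rule fired; ties between equally
    close terms break by the fixed order healthy < asthma < copd.
    """
    if not any(d > 0 for d in aggregate.values()):
        return None
    lo, hi = rule_base.universe
    xs = np.linspace(lo, hi, resolution)
    mu = np.zeros_like(xs)
    for label, degree in aggregate.items():
        if degree <= 0:
            continue
        f = rule_base.output_function(label)
        mu = np.maximum(mu, np.minimum(degree, np.array([f(x) for x in xs])))
    area = float(np.trapezoid(mu, xs))
    if area <= 0:
        return None
    centroid = float(np.trapezoid(mu * xs, xs)) / area
    ordered = [l for l in OUTPUT_ORDER if l in aggregate] + [
        l for l in aggregate if l not in OUTPUT_ORDER
    ]
    # only terms that actually fired compete for the centroid
    fired = [l for l in ordered if aggregate[l] > 0]
    winner = min(fired, key=lambda l: abs(rule_base.output_function(l).center() - centroid))
    return FuzzyDecision(
        category=winner, confidence=float(aggregate[winner]), centroid=centroid
    )
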