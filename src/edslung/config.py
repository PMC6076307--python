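"""YAML configuration schema and loader.

Every tunable of the system lives here: the significance-factor table and
triage threshold, staging band edges, network hyperparameters and
Levenberg–Marquardt tolerances, the fuzzy rule base and membership shapes,
and the cost model.  An empty file (or no file) yields the documented
defaults; unknown keys and out-of-range values are rejected with the
offending location.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import ann, fuzzy, preclassify, spiro
from .errors import ConfigurationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FactorsConfig(_Strict):
    asthma: list[float] = Field(default=list(preclassify.DEFAULT_TABLE.asthma))
    copd: list[float] = Field(default=list(preclassify.DEFAULT_TABLE.copd))


class PreclassificationConfig(_Strict):
    factors: FactorsConfig = Field(default_factory=FactorsConfig)
    threshold: float = Field(default=50.0, ge=0.0, le=100.0)
    asthma_inverted_questions: list[int] = Field(default=[1])

    def to_table(self) -> preclassify.SignificanceFactorTable:
        return preclassify.SignificanceFactorTable(
            asthma=tuple(self.factors.asthma),
            copd=tuple(self.factors.copd),
            asthma_inverted_questions=frozenset(self.asthma_inverted_questions),
        )


class StagingConfig(_Strict):
    tiffeneau_cutoff: float = Field(default=70.0, gt=0, lt=100)
    gold_cutoffs: list[float] = Field(default=[80.0, 50.0, 30.0])
    asthma_cutoffs: list[float] = Field(default=[80.0, 60.0])
    rare_symptom_cutoff: int = Field(default=2, ge=0, le=7)

    def to_thresholds(self) -> spiro.StagingThresholds:
        return spiro.StagingThresholds(
            tiffeneau_cutoff=self.tiffeneau_cutoff,
            gold_cutoffs=tuple(self.gold_cutoffs),
            asthma_cutoffs=tuple(self.asthma_cutoffs),
            rare_symptom_cutoff=self.rare_symptom_cutoff,
        )


class LmaConfig(_Strict):
    lambda0: float = Field(default=1e-3, gt=0)
    lambda_up: float = Field(default=10.0, gt=1)
    lambda_down: float = Field(default=10.0, gt=1)
    max_iter: int = Field(default=200, ge=1)
    mse_tol: float = Field(default=1e-8, ge=0)
    grad_tol: float = Field(default=1e-10, ge=0)
    init_scale: float = Field(default=0.5, gt=0)

    def to_settings(self) -> ann.LmaSettings:
        return ann.LmaSettings(
            lambda0=self.lambda0,
            lambda_up=self.lambda_up,
            lambda_down=self.lambda_down,
            max_iter=self.max_iter,
            mse_tol=self.mse_tol,
            grad_tol=self.grad_tol,
            init_scale=self.init_scale,
        )


class AnnConfig(_Strict):
    hidden_sizes: list[int] = Field(default=list(ann.DEFAULT_HIDDEN_SIZES))
    k: int = Field(default=10, ge=2)
    seed: int = Field(default=0, ge=0)
    restarts: int = Field(default=3, ge=1)
    parsimony_margin: float = Field(default=0.1, ge=0)
    output_encoding: Literal["index", "onehot"] = "index"
    lma: LmaConfig = Field(default_factory=LmaConfig)


class MembershipSpec(_Strict):
    label: str
    points: list[float]  # trapezoid (a, b, c, d); .inf / -.inf allowed in YAML

    @field_validator("points")
    @classmethod
    def _four_ordered(cls, v: list[float]) -> list[float]:
        if len(v) != 4:
            raise ValueError("membership needs exactly 4 trapezoid points")
        if not all(x <= y for x, y in zip(v, v[1:])):
            raise ValueError(f"trapezoid points must be non-decreasing: {v}")
        return v

    def to_function(self) -> fuzzy.MembershipFunction:
        return fuzzy.MembershipFunction(self.label, tuple(self.points))


class RuleSpec(_Strict):
    when: dict[str, str]
    then: str


def _default_fuzzy_variables() -> dict[str, list[MembershipSpec]]:
    rb = fuzzy.default_rule_base()
    return {
        var: [MembershipSpec(label=f.label, points=list(f.points)) for f in terms]
        for var, terms in rb.variables.items()
    }


def _default_fuzzy_outputs() -> list[MembershipSpec]:
    rb = fuzzy.default_rule_base()
    return [MembershipSpec(label=f.label, points=list(f.points)) for f in rb.outputs]


def _default_fuzzy_rules() -> list[RuleSpec]:
    rb = fuzzy.default_rule_base()
    return [RuleSpec(when=dict(r.antecedent), then=r.consequent) for r in rb.rules]


class FuzzyConfig(_Strict):
    variables: dict[str, list[MembershipSpec]] = Field(
        default_factory=_default_fuzzy_variables
    )
    outputs: list[MembershipSpec] = Field(default_factory=_default_fuzzy_outputs)
    rules: list[RuleSpec] = Field(default_factory=_default_fuzzy_rules)
    universe: list[float] = Field(default=[0.0, 100.0])
    bdt_percent_threshold: float = Field(default=12.0)
    bdt_ml_threshold: float = Field(default=200.0)
    bpt_fall_threshold: float = Field(default=20.0)

    def to_rule_base(self) -> fuzzy.FuzzyRuleBase:
        return fuzzy.FuzzyRuleBase(
            variables={
                var: tuple(m.to_function() for m in terms)
                for var, terms in self.variables.items()
            },
            outputs=tuple(m.to_function() for m in self.outputs),
            rules=tuple(
                fuzzy.FuzzyRule(antecedent=dict(r.when), consequent=r.then)
                for r in self.rules
            ),
            universe=tuple(self.universe),
        )


class CostConfig(_Strict):
    spir_test_cost: float = Field(default=60.0, ge=0)
    filter_cost: float = Field(default=1.0, ge=0)
    specialist_visit_cost: float = Field(default=100.0, ge=0)
    blood_gas_cost: float = Field(default=10.0, ge=0)


class EdsConfig(_Strict):
    preclassification: PreclassificationConfig = Field(
        default_factory=PreclassificationConfig
    )
    staging: StagingConfig = Field(default_factory=StagingConfig)
    ann: AnnConfig = Field(default_factory=AnnConfig)
    fuzzy: FuzzyConfig = Field(default_factory=FuzzyConfig)
    costs: CostConfig = Field(default_factory=CostConfig)
    logging_level: str = "WARNING"


def load_config(path: str | Path | None = None) -> EdsConfig:
    """Load and fully validate a YAML config; ``None``/empty → all defaults."""
    if path is None:
        return EdsConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return EdsConfig()
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    try:
        cfg = EdsConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigurationError(f"{path}: {locs}") from exc
    # cross-checks pydantic field types cannot express
    try:
        cfg.preclassification.to_table()
        cfg.staging.to_thresholds()
        cfg.fuzzy.to_rule_base()
    except ConfigurationError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc
    if not math.isfinite(cfg.preclassification.threshold):
        raise ConfigurationError(f"{path}: preclassification.threshold must be finite")
    return cfg
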