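"""Decision flow orchestration: triage → spirometry/ANN → fuzzy stage.

One record travels a fixed gauntlet: (1) questionnaire triage — if neither
disease probability exceeds the threshold the patient is healthy and the
process ends; (2) otherwise spirometry is required and the network
classifies the five normalized inputs into one of ten classes; a
conclusive class maps straight to a final category and severity;
(3) INCONCLUSIVE triggers a bronchodilatation/provocation request, and if
such a test is on record the fuzzy classifier issues the final category.

``stage_reached`` records the furthest stage a record entered; a record
terminated at triage is always healthy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from . import ann, fuzzy, preclassify, spiro
from .errors import DataValidationError, EdsError

logger = logging.getLogger("edslung")

FINAL_CATEGORIES = ("healthy", "asthma", "copd", "inconclusive")

STAGE_TRIAGE = "triage"
STAGE_ANN = "ann"
STAGE_FUZZY = "fuzzy"


@dataclass(frozen=True)
class PatientRecord:
    id: str
    answers: preclassify.QuestionnaireAnswers
    spirometry: Optional[spiro.SpirometryMeasurement] = None
    bronchial_test: Optional[fuzzy.BronchialTestResult] = None
    clinician_diagnosis: Optional[str] = None
    true_label: Optional[str] = None


@dataclass(frozen=True)
class EdsDecision:
    patient_id: str
    stage_reached: str
    preclassification: preclassify.PreclassificationResult
    ann_class: Optional[str] = None
    final_category: str = "healthy"
    severity: Optional[int] = None
    tests_requested: tuple[str, ...] = ()
    fuzzy_confidence: Optional[float] = None


@dataclass(frozen=True)
class TrainedModel:
    """A trained network plus everything needed to apply it."""

    weights: ann.NetworkWeights
    bounds: spiro.NormalizationBounds
    codebook: ann.ClassCodebook = ann.DEFAULT_CODEBOOK
    metadata: Mapping[str, object] = field(default_factory=dict)


def class_to_category(name: str) -> tuple[str, Optional[int]]:
    """Map an ANN class to (final category, severity)."""
    if name.startswith("ASTHMA"):
        return "asthma", int(name[-1])
    if name.startswith("GOLD"):
        return "copd", int(name[-1])
    if name == "NORMAL":
        return "healthy", None
    if name == "INCONCLUSIVE":
        return "inconclusive", None
    raise DataValidationError(f"unknown ANN class {name!r}")


def feature_vector(
    m: spiro.SpirometryMeasurement, pre: preclassify.PreclassificationResult
) -> np.ndarray:
    """The five raw classifier inputs: VC, FEV1, FVC, Tiffeneau, max probability."""
    return np.array([m.vc, m.fev1, m.fvc, m.tiffeneau, pre.max_probability])


def run_patient(
    record: PatientRecord,
    model: TrainedModel,
    table: preclassify.SignificanceFactorTable = preclassify.DEFAULT_TABLE,
    threshold: float = preclassify.DEFAULT_THRESHOLD,
    rule_base: fuzzy.FuzzyRuleBase | None = None,
) -> EdsDecision:
    """Run the full decision flow for one patient."""
    pre = preclassify.triage(record.answers, table, threshold)
    if not pre.tests_required:
        logger.debug("%s: triaged healthy (p=%.1f)", record.id, pre.max_probability)
        return EdsDecision(
            patient_id=record.id,
            stage_reached=STAGE_TRIAGE,
            preclassification=pre,
            final_category="healthy",
        )
    if record.spirometry is None:
        return EdsDecision(
            patient_id=record.id,
            stage_reached=STAGE_ANN,
            preclassification=pre,
            final_category="inconclusive",
            tests_requested=("SPIR",),
        )
    x = model.bounds.normalize(feature_vector(record.spirometry, pre))
    ann_class = ann.predict_class(model.weights, x, model.codebook)
    logger.debug("%s: ANN class %s", record.id, ann_class)
    if ann_class != "INCONCLUSIVE":
        category, severity = class_to_category(ann_class)
        return EdsDecision(
            patient_id=record.id,
            stage_reached=STAGE_ANN,
            preclassification=pre,
            ann_class=ann_class,
            final_category=category,
            severity=severity,
        )
    if record.bronchial_test is None:
        return EdsDecision(
            patient_id=record.id,
            stage_reached=STAGE_ANN,
            preclassification=pre,
            ann_class=ann_class,
            final_category="inconclusive",
            tests_requested=("BDT", "BPT"),
        )
    rb = rule_base if rule_base is not None else fuzzy.default_rule_base()
    aggregate = fuzzy.infer(
        rb,
        {
            "reversibility": record.bronchial_test.reversibility_evidence(),
            "p_asthma": pre.p_asthma,
            "p_copd": pre.p_copd,
        },
    )
    decision = fuzzy.classify_final(aggregate, rb)
    if decision is None:
        # no rule fired: refer to a specialist rather than force a class
        return EdsDecision(
            patient_id=record.id,
            stage_reached=STAGE_FUZZY,
            preclassification=pre,
            ann_class=ann_class,
            final_category="inconclusive",
        )
    return EdsDecision(
        patient_id=record.id,
        stage_reached=STAGE_FUZZY,
        preclassification=pre,
        ann_class=ann_class,
        final_category=decision.category,
        fuzzy_confidence=decision.confidence,
    )


def build_training_batch(
    records: Sequence[PatientRecord],
    table: preclassify.SignificanceFactorTable = preclassify.DEFAULT_TABLE,
    threshold: float = preclassify.DEFAULT_THRESHOLD,
    codebook: ann.ClassCodebook = ann.DEFAULT_CODEBOOK,
    encoding: str = "index",
) -> tuple[ann.TrainingBatch, spiro.NormalizationBounds]:
    """Assemble normalized features and encoded targets from labeled records.

    Normalization bounds are fitted on this cohort (observed per-feature
    min/max) and returned so they can be persisted with the model.
    """
    labeled = [r for r in records if r.true_label is not None]
    if not labeled:
        raise DataValidationError("no labeled records to train on")
    raw = []
    for r in labeled:
        if r.spirometry is None:
            raise DataValidationError(f"record {r.id} lacks spirometry")
        pre = preclassify.triage(r.answers, table, threshold)
        raw.append(feature_vector(r.spirometry, pre))
    X_raw = np.array(raw)
    bounds = spiro.NormalizationBounds.fit(X_raw)
    X = np.vstack([bounds.normalize(x) for x in X_raw])
    T = ann.encode_targets([r.true_label for r in labeled], codebook, encoding)
    return ann.TrainingBatch(inputs=X, targets=T), bounds


def train_model(
    records: Sequence[PatientRecord],
    hidden_size: int | None = None,
    hidden_sizes: Sequence[int] = ann.DEFAULT_HIDDEN_SIZES,
    k: int = 10,
    seed: int = 0,
    settings: ann.LmaSettings = ann.DEFAULT_LMA,
    restarts: int = 3,
    parsimony_margin: float = 0.0,
    table: preclassify.SignificanceFactorTable = preclassify.DEFAULT_TABLE,
    threshold: float = preclassify.DEFAULT_THRESHOLD,
    encoding: str = "index",
) -> TrainedModel:
    """Fit a deployable model: optional hidden-size search by k-fold CV,
    then a final fit on the full cohort with the selected width."""
    batch, bounds = build_training_batch(
        records, table, threshold, encoding=encoding
    )
    search_table = None
    if hidden_size is None:
        search = ann.hidden_size_search(
            batch, hidden_sizes, k, seed, settings, restarts, parsimony_margin
        )
        hidden_size = search.selected_size
        search_table = search.table
    weights, history = ann.lma_train(batch, hidden_size, seed, settings, restarts)
    return TrainedModel(
        weights=weights,
        bounds=bounds,
        metadata={
            "seed": seed,
            "k": k,
            "hidden_size": hidden_size,
            "search_table": search_table,
            "encoding": encoding,
            "final_training_mse": history.mse_per_iteration[-1],
            "n_training_samples": batch.n,
        },
    )


@dataclass
class CohortResult:
    decisions: list[EdsDecision]
    summary: dict[str, dict[str, int]]
    failures: list[tuple[str, str]]  # (patient id, error message)


def run_cohort(
    records: Sequence[PatientRecord],
    model: TrainedModel,
    table: preclassify.SignificanceFactorTable = preclassify.DEFAULT_TABLE,
    threshold: float = preclassify.DEFAULT_THRESHOLD,
    rule_base: fuzzy.FuzzyRuleBase | None = None,
) -> CohortResult:
    """Per-record decisions in input order plus stage/category/test tallies."""
    if not records:
        raise DataValidationError("empty cohort")
    rb = rule_base if rule_base is not None else fuzzy.default_rule_base()
    decisions: list[EdsDecision] = []
    failures: list[tuple[str, str]] = []
    stage_counts: dict[str, int] = {}
    final_counts: dict[str, int] = {}
    test_counts: dict[str, int] = {}
    for rec in records:
        try:
            d = run_patient(rec, model, table, threshold, rb)
        except EdsError as exc:
            logger.warning("%s: %s", rec.id, exc)
            failures.append((rec.id, str(exc)))
            continue
        decisions.append(d)
        stage_counts[d.stage_reached] = stage_counts.get(d.stage_reached, 0) + 1
        final_counts[d.final_category] = final_counts.get(d.final_category, 0) + 1
        for t in d.tests_requested:
            test_counts[t] = test_counts.get(t, 0) + 1
    return CohortResult(
        decisions=decisions,
        summary={
            "stage": stage_counts,
            "final": final_counts,
            "tests_requested": test_counts,
        },
        failures=failures,
    )
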