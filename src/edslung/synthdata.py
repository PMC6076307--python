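"""Seeded synthetic patient cohorts for training and end-to-end exercises.

No public dataset exists for this system, so cohorts are simulated with the
class structure of the real-time validation population: roughly 52% asthma,
39% COPD and 9% healthy, severity uniform within each disease.  For each
record the generator draws

* class-conditional Gaussian spirometry (FEV1 as percent of predicted, the
  Tiffeneau index, the predicted FEV1 volume, and a VC/FVC ratio),
* class-conditional Bernoulli answers to the seven symptom questions, and
* a class-conditional bronchodilator FEV1 change (large and positive for
  asthma, near zero otherwise),

then rejection-samples (capped) until the record re-stages to its own
ground-truth label under the guideline staging rules, so labels are
internally consistent by construction.  Everything is deterministic given
the seed.

Profiles: ``separable`` uses disjoint percent-predicted windows and nearly
deterministic symptoms (classifiers should approach 100%); ``realistic``
uses overlapping class-conditional distributions; ``hard`` widens every
spread and flattens the symptom contrast further.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from . import spiro
from .errors import ConfigurationError, RejectionLimitError
from .fuzzy import BronchialTestResult, bdt_positive
from .pipeline import PatientRecord
from .preclassify import QuestionnaireAnswers

#: ground-truth labels a synthetic record can carry (INCONCLUSIVE is an
#: ANN output, not a disease state, and is never generated)
LABELS = (
    "NORMAL",
    "ASTHMA1",
    "ASTHMA2",
    "ASTHMA3",
    "ASTHMA4",
    "GOLD1",
    "GOLD2",
    "GOLD3",
    "GOLD4",
)

ASTHMA_LABELS = ("ASTHMA1", "ASTHMA2", "ASTHMA3", "ASTHMA4")
COPD_LABELS = ("GOLD1", "GOLD2", "GOLD3", "GOLD4")

REJECTION_CAP = 1000


@dataclass(frozen=True)
class ClassSpiroModel:
    """Gaussian parameters for one class's spirometry (means, sds, and the
    acceptance window on percent-predicted FEV1)."""

    fev1_pct_pred: tuple[float, float]
    fev1_band: tuple[float, float]  # acceptance window, [lo, hi)
    tiffeneau: tuple[float, float]
    predicted_fev1_l: tuple[float, float] = (3.3, 0.15)
    vc_over_fvc: tuple[float, float] = (1.03, 0.02)


@dataclass(frozen=True)
class CohortSpec:
    n: int
    class_mix: Mapping[str, float]
    symptom_model: Mapping[str, tuple[float, ...]]
    spiro_model: Mapping[str, ClassSpiroModel]
    reversibility_model: Mapping[str, tuple[float, float]]  # FEV1 change % (mean, sd)
    noise_scale: float = 1.0
    seed: int = 0
    staging: spiro.StagingThresholds = field(default_factory=spiro.StagingThresholds)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("cohort size must be >= 1")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be >= 0")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class mix sums to {total}, expected 1")
        for label in self.class_mix:
            if label not in LABELS:
                raise ConfigurationError(f"unknown class label {label!r}")
            for model, what in (
                (self.symptom_model, "symptom"),
                (self.spiro_model, "spirometry"),
                (self.reversibility_model, "reversibility"),
            ):
                if label not in model:
                    raise ConfigurationError(f"no {what} model for class {label!r}")


# -- default parameterizations -------------------------------------------------

#: real-time cohort proportions: 859 asthma / 636 COPD / 155 healthy of 1650,
#: severity uniform within disease
_DEFAULT_MIX = {
    "NORMAL": 155 / 1650,
    **{lab: 859 / 1650 / 4 for lab in ASTHMA_LABELS},
    **{lab: 636 / 1650 / 4 for lab in COPD_LABELS},
}

# question order: age>40, exertional problems, nocturnal cough, sputum,
# morning wheeze, nocturnal/exertional wheeze, resting dyspnoea
_SYMPTOMS_REALISTIC = {
    "NORMAL": (0.45, 0.05, 0.04, 0.04, 0.03, 0.03, 0.02),
    "ASTHMA1": (0.15, 0.08, 0.35, 0.05, 0.05, 0.40, 0.08),
    "ASTHMA2": (0.20, 0.50, 0.85, 0.25, 0.30, 0.92, 0.65),
    "ASTHMA3": (0.20, 0.55, 0.85, 0.25, 0.30, 0.92, 0.70),
    "ASTHMA4": (0.20, 0.65, 0.88, 0.30, 0.35, 0.92, 0.78),
    "GOLD1": (0.85, 0.65, 0.30, 0.75, 0.65, 0.25, 0.45),
    "GOLD2": (0.85, 0.75, 0.35, 0.80, 0.70, 0.30, 0.55),
    "GOLD3": (0.85, 0.80, 0.35, 0.85, 0.75, 0.30, 0.65),
    "GOLD4": (0.85, 0.90, 0.40, 0.85, 0.80, 0.35, 0.80),
}

#: per-patient predicted FEV1 in litres; the small spread keeps measured
#: FEV1 volumes informative about percent-of-predicted severity
_PREDICTED_REALISTIC = (3.3, 0.05)

#: class-conditional acceptance windows are inset slightly from the raw
#: guideline cutoffs so that generated classes remain identifiable from
#: noisy volumes; distributions still overlap across classes
_SPIRO_REALISTIC = {
    "NORMAL": ClassSpiroModel((97, 6), (85, 120), (85, 3.0), _PREDICTED_REALISTIC),
    "ASTHMA1": ClassSpiroModel((93, 4), (88, 120), (75, 2.5), _PREDICTED_REALISTIC),
    "ASTHMA2": ClassSpiroModel((84, 3), (80, 88), (75, 2.5), _PREDICTED_REALISTIC),
    "ASTHMA3": ClassSpiroModel((70, 4), (62, 78), (74, 2.5), _PREDICTED_REALISTIC),
    "ASTHMA4": ClassSpiroModel((48, 5), (25, 58), (73, 2.0), _PREDICTED_REALISTIC),
    "GOLD1": ClassSpiroModel((88, 5), (82, 120), (63, 3.0), _PREDICTED_REALISTIC),
    "GOLD2": ClassSpiroModel((65, 6), (52, 78), (61, 3.0), _PREDICTED_REALISTIC),
    "GOLD3": ClassSpiroModel((40, 4), (32, 48), (55, 4.0), _PREDICTED_REALISTIC),
    "GOLD4": ClassSpiroModel((24, 4), (10, 28), (45, 5.0), _PREDICTED_REALISTIC),
}

#: bronchodilator FEV1 change in percent: asthma strongly reversible,
#: COPD/healthy essentially flat
_REVERSIBILITY_REALISTIC = {
    **{lab: (2.0, 3.5) for lab in ("NORMAL", *COPD_LABELS)},
    **{lab: (20.0, 5.0) for lab in ASTHMA_LABELS},
}

# separable: disjoint percent-predicted windows (pairwise non-overlapping
# across ALL classes), sharp symptoms
_SPIRO_SEPARABLE = {
    "NORMAL": ClassSpiroModel((98, 1.0), (96, 100), (84, 1.0), (3.3, 0.0)),
    "ASTHMA1": ClassSpiroModel((92, 1.0), (90, 94), (77, 1.0), (3.3, 0.0)),
    "ASTHMA2": ClassSpiroModel((86, 1.0), (84, 88), (77, 1.0), (3.3, 0.0)),
    "ASTHMA3": ClassSpiroModel((71, 1.5), (66, 76), (75, 1.0), (3.3, 0.0)),
    "ASTHMA4": ClassSpiroModel((43, 1.5), (38, 48), (73, 1.0), (3.3, 0.0)),
    "GOLD1": ClassSpiroModel((81.5, 0.5), (80, 83), (64, 1.0), (3.3, 0.0)),
    "GOLD2": ClassSpiroModel((57, 1.5), (52, 62), (61, 1.0), (3.3, 0.0)),
    "GOLD3": ClassSpiroModel((33, 1.0), (30, 36), (54, 1.0), (3.3, 0.0)),
    "GOLD4": ClassSpiroModel((20, 1.5), (14, 26), (45, 1.0), (3.3, 0.0)),
}

_SYMPTOMS_SEPARABLE = {
    "NORMAL": (0.45, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02),
    "ASTHMA1": (0.02, 0.02, 0.50, 0.02, 0.02, 0.50, 0.02),
    "ASTHMA2": (0.10, 0.90, 0.95, 0.10, 0.10, 0.98, 0.90),
    "ASTHMA3": (0.10, 0.90, 0.95, 0.10, 0.10, 0.98, 0.90),
    "ASTHMA4": (0.10, 0.90, 0.95, 0.10, 0.10, 0.98, 0.90),
    "GOLD1": (0.98, 0.90, 0.05, 0.95, 0.90, 0.05, 0.90),
    "GOLD2": (0.98, 0.90, 0.05, 0.95, 0.90, 0.05, 0.90),
    "GOLD3": (0.98, 0.90, 0.05, 0.95, 0.90, 0.05, 0.90),
    "GOLD4": (0.98, 0.90, 0.05, 0.95, 0.90, 0.05, 0.90),
}

PROFILES = ("separable", "realistic", "hard")


def default_spec(profile: str, n: int = 1000, seed: int = 0) -> CohortSpec:
    """Documented default cohort parameterization for a difficulty profile."""
    if profile == "realistic":
        return CohortSpec(
            n=n,
            class_mix=dict(_DEFAULT_MIX),
            symptom_model=dict(_SYMPTOMS_REALISTIC),
            spiro_model=dict(_SPIRO_REALISTIC),
            reversibility_model=dict(_REVERSIBILITY_REALISTIC),
            noise_scale=1.0,
            seed=seed,
        )
    if profile == "separable":
        return CohortSpec(
            n=n,
            class_mix=dict(_DEFAULT_MIX),
            symptom_model=dict(_SYMPTOMS_SEPARABLE),
            spiro_model=dict(_SPIRO_SEPARABLE),
            reversibility_model=dict(_REVERSIBILITY_REALISTIC),
            noise_scale=1.0,
            seed=seed,
        )
    if profile == "hard":
        hard_symptoms = {
            lab: tuple(0.5 + 0.5 * (p - 0.5) for p in probs)
            for lab, probs in _SYMPTOMS_REALISTIC.items()
        }
        hard_spiro = {
            lab: replace(m, predicted_fev1_l=(m.predicted_fev1_l[0], 0.35))
            for lab, m in _SPIRO_REALISTIC.items()
        }
        return CohortSpec(
            n=n,
            class_mix=dict(_DEFAULT_MIX),
            symptom_model=hard_symptoms,
            spiro_model=hard_spiro,
            reversibility_model=dict(_REVERSIBILITY_REALISTIC),
            noise_scale=1.6,
            seed=seed,
        )
    raise ConfigurationError(f"unknown profile {profile!r}; choose from {PROFILES}")


# -- generation ----------------------------------------------------------------


def _draw_record(
    label: str, spec: CohortSpec, rng: np.random.Generator, patient_id: str
) -> PatientRecord:
    sm = spec.spiro_model[label]
    probs = spec.symptom_model[label]
    rev_mean, rev_sd = spec.reversibility_model[label]
    ns = spec.noise_scale
    staging = spec.staging
    for _ in range(REJECTION_CAP):
        pct = rng.normal(sm.fev1_pct_pred[0], sm.fev1_pct_pred[1] * ns)
        if not sm.fev1_band[0] <= pct < sm.fev1_band[1]:
            continue
        tiff = rng.normal(sm.tiffeneau[0], sm.tiffeneau[1] * ns)
        if not 20.0 < tiff < 100.0:
            continue
        predicted = rng.normal(sm.predicted_fev1_l[0], sm.predicted_fev1_l[1] * ns)
        if predicted <= 0.5:
            continue
        ratio = rng.normal(sm.vc_over_fvc[0], sm.vc_over_fvc[1] * ns)
        if ratio < 1.0:
            continue
        fev1 = pct / 100.0 * predicted
        fvc = fev1 / (tiff / 100.0)
        vc = fvc * ratio
        answers = QuestionnaireAnswers(tuple(int(rng.random() < p) for p in probs))
        rev_pct = rng.normal(rev_mean, rev_sd * ns)
        rev_ml = rev_pct / 100.0 * fev1 * 1000.0
        test = BronchialTestResult("BDT", rev_pct, rev_ml)
        positive = bdt_positive(test)
        m = spiro.SpirometryMeasurement(
            vc=vc, fev1=fev1, fvc=fvc, tiffeneau=tiff, fev1_percent_predicted=pct
        )
        rare = spiro.infrequent_symptoms(answers.options, staging)
        copd_stage = spiro.stage_copd(m, staging)
        asthma_stage = spiro.stage_asthma(m, positive, rare, staging)
        if label == "NORMAL":
            ok = copd_stage == spiro.NOT_COPD and asthma_stage == spiro.NOT_ASTHMA
        elif label in ASTHMA_LABELS:
            ok = asthma_stage == label and copd_stage == spiro.NOT_COPD
        else:
            ok = copd_stage == label and not positive
        if ok:
            return PatientRecord(
                id=patient_id,
                answers=answers,
                spirometry=m,
                bronchial_test=test,
                true_label=label,
            )
    raise RejectionLimitError(
        f"could not draw a record consistent with class {label!r} "
        f"within {REJECTION_CAP} attempts (infeasible cohort spec?)"
    )


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a labeled cohort; deterministic for a given spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    labels = sorted(spec.class_mix)
    p = np.array([spec.class_mix[lab] for lab in labels])
    draws = rng.choice(len(labels), size=spec.n, p=p / p.sum())
    return [
        _draw_record(labels[int(d)], spec, rng, patient_id=f"P{i:05d}")
        for i, d in enumerate(draws)
    ]
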