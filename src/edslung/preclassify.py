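"""Symptom-questionnaire pre-classifier.

Seven yes/no questions about respiratory symptoms (age over 40, exertional
problems, nocturnal cough, sputum, morning wheeze, nocturnal/exertional
wheeze, resting dyspnoea) are scored against per-disease significance
factors derived from GINA/GOLD guidance.  For disease ``k`` the score is

    p_k = A_k * sum_j sf_jk * O'_j * 100  (%),   A_k = 1 / sum_j sf_jk,

where ``O_j`` is the binary answer to question ``j`` and ``O'_j`` is the
answer after optional logical inversion (question 1, age over 40, points
*towards* COPD when affirmative and towards asthma when negative, so its
option factor is inverted in the asthma column by default).

If neither disease probability exceeds the triage threshold (default 50%),
the patient is classed healthy and no lung-function testing is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ConfigurationError, DataValidationError, UndefinedMetricError

ASTHMA = "asthma"
COPD = "copd"
DISEASES = (ASTHMA, COPD)

N_QUESTIONS = 7


@dataclass(frozen=True)
class QuestionnaireAnswers:
    """The seven binary option factors O_1..O_7 (1 = affirmative)."""

    options: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.options) != N_QUESTIONS:
            raise DataValidationError(
                f"expected {N_QUESTIONS} questionnaire answers, got {len(self.options)}"
            )
        for j, o in enumerate(self.options, start=1):
            if o not in (0, 1):
                raise DataValidationError(f"answer q{j} must be 0 or 1, got {o!r}")

    @classmethod
    def from_iterable(cls, values: Iterable[object]) -> "QuestionnaireAnswers":
        return cls(tuple(int(v) for v in values))

    def affirmative_count(self) -> int:
        return sum(self.options)


@dataclass(frozen=True)
class SignificanceFactorTable:
    """Per-question, per-disease weights sf_jk plus the asthma inversion set.

    ``asthma_inverted_questions`` holds 1-based question indices whose option
    factor is replaced by ``1 - O_j`` when scoring the asthma column.
    """

    asthma: tuple[float, ...]
    copd: tuple[float, ...]
    asthma_inverted_questions: frozenset[int] = frozenset({1})

    def __post_init__(self) -> None:
        for disease, col in ((ASTHMA, self.asthma), (COPD, self.copd)):
            if len(col) != N_QUESTIONS:
                raise ConfigurationError(
                    f"{disease} column must have {N_QUESTIONS} weights, got {len(col)}"
                )
            if any(w < 0 for w in col):
                raise ConfigurationError(f"{disease} weights must be non-negative")
            if not any(w > 0 for w in col):
                raise ConfigurationError(f"{disease} weight column is all zero")
        bad = [j for j in self.asthma_inverted_questions if not 1 <= j <= N_QUESTIONS]
        if bad:
            raise ConfigurationError(f"inverted question indices out of range: {bad}")

    def column(self, disease: str) -> tuple[float, ...]:
        if disease == ASTHMA:
            return self.asthma
        if disease == COPD:
            return self.copd
        raise ConfigurationError(f"unknown disease {disease!r}")


#: Default weights follow the questionnaire's qualitative directionality:
#: questions pointing at COPD (age>40, exertional problems, sputum, morning
#: wheeze) weight the COPD column double; nocturnal cough and
#: nocturnal/exertional wheeze weight asthma double; resting dyspnoea
#: weights both.  Fully overridable from configuration.
DEFAULT_TABLE = SignificanceFactorTable(
    asthma=(2.0, 1.0, 2.0, 1.0, 1.0, 2.0, 2.0),
    copd=(2.0, 2.0, 1.0, 2.0, 2.0, 1.0, 2.0),
    asthma_inverted_questions=frozenset({1}),
)

DEFAULT_THRESHOLD = 50.0


def normalization_constant(table: SignificanceFactorTable, disease: str) -> float:
    """A_k = 1 / sum_j sf_jk for the requested disease column."""
    total = sum(table.column(disease))
    if total <= 0:
        raise ConfigurationError(f"all-zero weight column for disease {disease!r}")
    return 1.0 / total


def effective_options(
    answers: QuestionnaireAnswers, table: SignificanceFactorTable, disease: str
) -> tuple[int, ...]:
    """Option factors after applying the disease-specific inversion set."""
    if disease != ASTHMA:
        return answers.options
    return tuple(
        1 - o if (j in table.asthma_inverted_questions) else o
        for j, o in enumerate(answers.options, start=1)
    )


def disease_probability(
    answers: QuestionnaireAnswers, table: SignificanceFactorTable, disease: str
) -> float:
    """Weighted, normalized symptom score for one disease, in percent [0, 100]."""
    a_k = normalization_constant(table, disease)
    weights = table.column(disease)
    opts = effective_options(answers, table, disease)
    return a_k * sum(w * o for w, o in zip(weights, opts)) * 100.0


@dataclass(frozen=True)
class PreclassificationResult:
    p_asthma: float
    p_copd: float
    normalization_constants: dict[str, float] = field(repr=False)
    tests_required: bool = False
    recommended_category: str = "healthy"  # "healthy" | "suspect"

    @property
    def max_probability(self) -> float:
        return max(self.p_asthma, self.p_copd)


def triage(
    answers: QuestionnaireAnswers,
    table: SignificanceFactorTable = DEFAULT_TABLE,
    threshold: float = DEFAULT_THRESHOLD,
) -> PreclassificationResult:
    """Score both diseases and decide whether lung-function tests are needed.

    Testing is requested only when the larger probability strictly exceeds
    the threshold; at exactly the threshold the patient remains healthy.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ConfigurationError(f"threshold must be in [0, 100], got {threshold}")
    p_asthma = disease_probability(answers, table, ASTHMA)
    p_copd = disease_probability(answers, table, COPD)
    required = max(p_asthma, p_copd) > threshold
    return PreclassificationResult(
        p_asthma=p_asthma,
        p_copd=p_copd,
        normalization_constants={
            ASTHMA: normalization_constant(table, ASTHMA),
            COPD: normalization_constant(table, COPD),
        },
        tests_required=required,
        recommended_category="suspect" if required else "healthy",
    )


def preclass_error(result: float, clinician: float) -> float:
    """Signed error E_k = clinician probability − algorithm probability."""
    return clinician - result


def preclass_accuracy(result: float, clinician: float) -> float:
    """Accuracy = p_k / p_k^c × 100 (%); undefined for a zero clinician score."""
    if clinician == 0:
        raise UndefinedMetricError(
            "pre-classification accuracy is undefined for clinician probability 0"
        )
    return result / clinician * 100.0
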