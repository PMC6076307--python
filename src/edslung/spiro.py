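"""Spirometry measurements, feature normalization and severity staging.

A measurement carries the four lung-function quantities the classifier
consumes — VC, FEV1, FVC (litres) and the Tiffeneau index FEV1/FVC (%) —
plus FEV1 as percent of the predicted value, which drives guideline
severity staging (GOLD 1–4 for COPD, four asthma severity steps) and the
synthetic-data generator.

Staging conventions (configurable):

* COPD requires airflow obstruction, Tiffeneau < 70%; severity then follows
  the canonical 80/50/30 percent-predicted cutoffs (left-closed bands).
* Asthma staging is gated on a positive bronchodilator/provocation result;
  with FEV1 ≥ 80% predicted the step is 1 (intermittent) when symptoms are
  rare and 2 otherwise, 60–80% is step 3, below 60% step 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, MeasurementError

NOT_COPD = "not-copd"
NOT_ASTHMA = "not-asthma"

#: relative slack on the FEV1 <= FVC check, absorbs device rounding
FEV1_FVC_TOLERANCE = 0.01


def tiffeneau_index(fev1: float, fvc: float) -> float:
    """FEV1/FVC ratio in percent."""
    if fvc <= 0:
        raise MeasurementError(f"FVC must be positive, got {fvc}")
    return 100.0 * fev1 / fvc


@dataclass(frozen=True)
class SpirometryMeasurement:
    vc: float
    fev1: float
    fvc: float
    tiffeneau: float | None = None
    fev1_percent_predicted: float | None = None

    def __post_init__(self) -> None:
        for name, v in (("vc", self.vc), ("fev1", self.fev1), ("fvc", self.fvc)):
            if not (math.isfinite(v) and v > 0):
                raise MeasurementError(f"{name} must be a positive volume, got {v}")
        if self.fev1 > self.fvc * (1.0 + FEV1_FVC_TOLERANCE):
            raise MeasurementError(
                f"FEV1 ({self.fev1} L) exceeds FVC ({self.fvc} L) beyond tolerance"
            )
        if self.tiffeneau is None:
            object.__setattr__(self, "tiffeneau", tiffeneau_index(self.fev1, self.fvc))
        if not 0 < self.tiffeneau <= 100.0 * (1.0 + FEV1_FVC_TOLERANCE):
            raise MeasurementError(f"Tiffeneau index out of range: {self.tiffeneau}")


def min_max_normalize(value: float, bounds: tuple[float, float], clip: bool = True) -> float:
    """(value − min)/(max − min), clipped to [0, 1] unless ``clip`` is False."""
    lo, hi = bounds
    if not hi > lo:
        raise ConfigurationError(f"degenerate normalization bounds ({lo}, {hi})")
    x = (value - lo) / (hi - lo)
    if clip:
        x = min(1.0, max(0.0, x))
    return x


#: canonical order of the five classifier inputs
FEATURE_NAMES = ("vc_l", "fev1_l", "fvc_l", "fev1_ratio_pct", "disease_probability")


@dataclass(frozen=True)
class NormalizationBounds:
    """Per-feature (min, max) pairs fitted on the training cohort."""

    bounds: tuple[tuple[float, float], ...]
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.feature_names):
            raise ConfigurationError(
                f"{len(self.feature_names)} features but {len(self.bounds)} bound pairs"
            )
        for name, (lo, hi) in zip(self.feature_names, self.bounds):
            if not (math.isfinite(lo) and math.isfinite(hi) and hi > lo):
                raise ConfigurationError(f"degenerate bounds for {name}: ({lo}, {hi})")

    @classmethod
    def fit(cls, X: np.ndarray, feature_names: Sequence[str] = FEATURE_NAMES) -> "NormalizationBounds":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(feature_names):
            raise ConfigurationError(
                f"expected an (n, {len(feature_names)}) feature matrix, got {X.shape}"
            )
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        return cls(tuple(zip(lo.tolist(), hi.tolist())), tuple(feature_names))

    def normalize(self, x: Sequence[float]) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != len(self.bounds):
            raise ConfigurationError(f"expected {len(self.bounds)} features, got {x.shape}")
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip((x - lo) / (hi - lo), 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            name: {"min": lo, "max": hi}
            for name, (lo, hi) in zip(self.feature_names, self.bounds)
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[str, float]]) -> "NormalizationBounds":
        names = tuple(d.keys())
        pairs = tuple((float(v["min"]), float(v["max"])) for v in d.values())
        return cls(pairs, names)


@dataclass(frozen=True)
class StagingThresholds:
    """Band edges for guideline severity staging (all left-closed)."""

    tiffeneau_cutoff: float = 70.0
    gold_cutoffs: tuple[float, float, float] = (80.0, 50.0, 30.0)  # stages 1|2, 2|3, 3|4
    asthma_cutoffs: tuple[float, float] = (80.0, 60.0)  # steps 1-2|3, 3|4
    rare_symptom_cutoff: int = 2  # max affirmative answers still "rare"

    def __post_init__(self) -> None:
        if not (self.gold_cutoffs[0] > self.gold_cutoffs[1] > self.gold_cutoffs[2] > 0):
            raise ConfigurationError(f"GOLD cutoffs must descend: {self.gold_cutoffs}")
        if not (self.asthma_cutoffs[0] > self.asthma_cutoffs[1] > 0):
            raise ConfigurationError(f"asthma cutoffs must descend: {self.asthma_cutoffs}")


DEFAULT_STAGING = StagingThresholds()


def _require_percent_predicted(m: SpirometryMeasurement) -> float:
    if m.fev1_percent_predicted is None:
        raise MeasurementError("fev1_percent_predicted is required for severity staging")
    return m.fev1_percent_predicted


def stage_copd(
    m: SpirometryMeasurement, thresholds: StagingThresholds = DEFAULT_STAGING
) -> str:
    """GOLD stage (GOLD1..GOLD4) or ``not-copd`` when there is no obstruction."""
    if m.tiffeneau >= thresholds.tiffeneau_cutoff:
        return NOT_COPD
    pct = _require_percent_predicted(m)
    c1, c2, c3 = thresholds.gold_cutoffs
    if pct >= c1:
        return "GOLD1"
    if pct >= c2:
        return "GOLD2"
    if pct >= c3:
        return "GOLD3"
    return "GOLD4"


def stage_asthma(
    m: SpirometryMeasurement,
    reversibility_positive: bool,
    symptoms_rare: bool = False,
    thresholds: StagingThresholds = DEFAULT_STAGING,
) -> str:
    """Asthma severity step (ASTHMA1..ASTHMA4) or ``not-asthma``.

    Gated on a positive reversibility/provocation result; within the
    preserved-FEV1 band the intermittent step (1) is assigned only when
    symptoms are rare.
    """
    if not reversibility_positive:
        return NOT_ASTHMA
    pct = _require_percent_predicted(m)
    c12, c34 = thresholds.asthma_cutoffs
    if pct >= c12:
        return "ASTHMA1" if symptoms_rare else "ASTHMA2"
    if pct >= c34:
        return "ASTHMA3"
    return "ASTHMA4"


def infrequent_symptoms(
    answers: Sequence[int], thresholds: StagingThresholds = DEFAULT_STAGING
) -> bool:
    """Objective 'symptoms rare' criterion: few affirmative answers."""
    return sum(answers) <= thresholds.rare_symptom_cutoff
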