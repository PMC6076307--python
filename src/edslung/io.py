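"""Readers and writers for the package's file formats.

* Patient cohort CSV (UTF-8, comma separated, ``.`` decimal, header
  required): ``id, q1..q7`` plus optional spirometry columns ``vc_l,
  fev1_l, fvc_l, fev1_ratio_pct, fev1_pct_pred``, optional bronchial-test
  columns ``test_type, fev1_change_pct, fev1_change_ml`` and optional
  ``clinician_diagnosis`` / ``true_label``.
* Decisions CSV: one row per classified patient.
* Model JSON: weights, normalization bounds, codebook and training
  metadata, with a schema version string.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import ann, fuzzy, pipeline, preclassify, spiro
from .errors import DataValidationError, EdsError

MODEL_SCHEMA_VERSION = "1"

QUESTION_COLUMNS = tuple(f"q{j}" for j in range(1, 8))
SPIRO_COLUMNS = ("vc_l", "fev1_l", "fvc_l", "fev1_ratio_pct", "fev1_pct_pred")
BDT_COLUMNS = ("test_type", "fev1_change_pct", "fev1_change_ml")
REQUIRED_COLUMNS = ("id",) + QUESTION_COLUMNS


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def read_cohort(path: str | Path) -> list[pipeline.PatientRecord]:
    """Read a patient cohort CSV with per-row validation."""
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing required columns {missing}")
    has_spiro = all(c in df.columns for c in SPIRO_COLUMNS[:4])
    has_bdt = all(c in df.columns for c in BDT_COLUMNS)
    records: list[pipeline.PatientRecord] = []
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based, after the header
        try:
            answers = preclassify.QuestionnaireAnswers.from_iterable(
                row[c] for c in QUESTION_COLUMNS
            )
            measurement = None
            if has_spiro and not _is_missing(row["vc_l"]):
                pct_pred = None
                if "fev1_pct_pred" in df.columns and not _is_missing(row["fev1_pct_pred"]):
                    pct_pred = float(row["fev1_pct_pred"])
                measurement = spiro.SpirometryMeasurement(
                    vc=float(row["vc_l"]),
                    fev1=float(row["fev1_l"]),
                    fvc=float(row["fvc_l"]),
                    tiffeneau=float(row["fev1_ratio_pct"]),
                    fev1_percent_predicted=pct_pred,
                )
            test = None
            if has_bdt and not _is_missing(row["test_type"]):
                test = fuzzy.BronchialTestResult(
                    test_type=str(row["test_type"]),
                    fev1_change_percent=float(row["fev1_change_pct"]),
                    fev1_change_ml=float(row["fev1_change_ml"]),
                )
            clinician = None
            if "clinician_diagnosis" in df.columns and not _is_missing(
                row["clinician_diagnosis"]
            ):
                clinician = str(row["clinician_diagnosis"])
            truth = None
            if "true_label" in df.columns and not _is_missing(row["true_label"]):
                truth = str(row["true_label"])
            records.append(
                pipeline.PatientRecord(
                    id=str(row["id"]),
                    answers=answers,
                    spirometry=measurement,
                    bronchial_test=test,
                    clinician_diagnosis=clinician,
                    true_label=truth,
                )
            )
        except (EdsError, ValueError, TypeError) as exc:
            raise DataValidationError(f"{path}, row {rownum}: {exc}") from exc
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise DataValidationError(f"{path}: duplicate patient ids")
    return records


def write_cohort(records: Sequence[pipeline.PatientRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict[str, object] = {"id": r.id}
        row.update({c: o for c, o in zip(QUESTION_COLUMNS, r.answers.options)})
        if r.spirometry is not None:
            m = r.spirometry
            row.update(
                vc_l=m.vc,
                fev1_l=m.fev1,
                fvc_l=m.fvc,
                fev1_ratio_pct=m.tiffeneau,
                fev1_pct_pred=m.fev1_percent_predicted,
            )
        if r.bronchial_test is not None:
            t = r.bronchial_test
            row.update(
                test_type=t.test_type,
                fev1_change_pct=t.fev1_change_percent,
                fev1_change_ml=t.fev1_change_ml,
            )
        if r.clinician_diagnosis is not None:
            row["clinician_diagnosis"] = r.clinician_diagnosis
        if r.true_label is not None:
            row["true_label"] = r.true_label
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


DECISION_COLUMNS = (
    "id",
    "stage",
    "p_asthma",
    "p_copd",
    "ann_class",
    "final",
    "severity",
    "tests_requested",
)


def write_decisions(decisions: Sequence[pipeline.EdsDecision], path: str | Path) -> None:
    rows = [
        {
            "id": d.patient_id,
            "stage": d.stage_reached,
            "p_asthma": d.preclassification.p_asthma,
            "p_copd": d.preclassification.p_copd,
            "ann_class": d.ann_class or "",
            "final": d.final_category,
            "severity": "" if d.severity is None else d.severity,
            "tests_requested": "|".join(d.tests_requested),
        }
        for d in decisions
    ]
    pd.DataFrame(rows, columns=DECISION_COLUMNS).to_csv(path, index=False)


def read_decisions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in ("id", "stage", "final") if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing decision columns {missing}")
    return df


def save_model(model: pipeline.TrainedModel, path: str | Path) -> None:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "codebook": list(model.codebook.names),
        "bounds": model.bounds.to_dict(),
        "weights": {
            "Iw": model.weights.Iw.tolist(),
            "Hb": model.weights.Hb.tolist(),
            "Hw": model.weights.Hw.tolist(),
            "Ob": model.weights.Ob.tolist(),
        },
        "metadata": _jsonable(dict(model.metadata)),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def _jsonable(obj: object) -> object:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def load_model(path: str | Path) -> pipeline.TrainedModel:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise DataValidationError(f"cannot read model document {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise DataValidationError(
            f"{path}: unsupported model schema version {doc.get('schema_version')!r}"
            if isinstance(doc, dict)
            else f"{path}: malformed model document"
        )
    if "bounds" not in doc or not doc["bounds"]:
        raise DataValidationError(f"{path}: model lacks normalization bounds")
    try:
        weights = ann.NetworkWeights(
            Iw=np.array(doc["weights"]["Iw"], dtype=float),
            Hb=np.array(doc["weights"]["Hb"], dtype=float),
            Hw=np.array(doc["weights"]["Hw"], dtype=float),
            Ob=np.array(doc["weights"]["Ob"], dtype=float),
        )
        bounds = spiro.NormalizationBounds.from_dict(doc["bounds"])
        codebook = ann.ClassCodebook(tuple(doc["codebook"]))
    except (KeyError, TypeError, ValueError, EdsError) as exc:
        raise DataValidationError(f"{path}: corrupt model document: {exc}") from exc
    return pipeline.TrainedModel(
        weights=weights,
        bounds=bounds,
        codebook=codebook,
        metadata=doc.get("metadata", {}),
    )
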