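"""File formats: JSONL patient cohorts, YAML schemas, CSV feature tables.

Patients travel as line-delimited JSON, one object per patient::

    {"patient_id": "p1", "age": 63, "gender": 1, "died": 0,
     "comorbidities": ["hypertension"],
     "records": [{"record_id": "p1-r1", "admission_time": "2015-03-02",
                  "diagnoses": ["D12"], "medications": ["ACE-I"],
                  "lab_results": {"L03": 4.7}}]}

Feature tables are CSV with a ``# method=<name> dim=<d>`` header comment so
downstream evaluation can refuse mismatched inputs.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .schema import ClinicalRecord, EncodingSchema, LabTest, PatientHistory, build_schema


def patient_to_dict(p: PatientHistory) -> dict:
    return {
        "patient_id": p.patient_id,
        "age": p.age,
        "gender": p.gender,
        "died": p.died,
        "comorbidities": sorted(p.comorbidities),
        "records": [
            {
                "record_id": r.record_id,
                "admission_time": r.admission_time.isoformat(),
                "diagnoses": sorted(r.diagnoses),
                "medications": sorted(r.medications),
                "lab_results": {k: r.lab_results[k] for k in sorted(r.lab_results)},
            }
            for r in p.records
        ],
    }


def patient_from_dict(obj: dict) -> PatientHistory:
    records = [
        ClinicalRecord(
            record_id=r["record_id"],
            admission_time=date.fromisoformat(r["admission_time"]),
            diagnoses=frozenset(r.get("diagnoses", ())),
            medications=frozenset(r.get("medications", ())),
            lab_results=r.get("lab_results", {}),
        )
        for r in obj["records"]
    ]
    return PatientHistory(
        patient_id=obj["patient_id"],
        age=float(obj["age"]),
        gender=int(obj["gender"]),
        records=records,
        died=int(obj.get("died", 0)),
        comorbidities=frozenset(obj.get("comorbidities", ())),
    )


def write_patients(patients: Iterable[PatientHistory], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in patients:
            fh.write(json.dumps(patient_to_dict(p), separators=(",", ":")) + "\n")


def read_patients(path: str | Path) -> list[PatientHistory]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                out.append(patient_from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise ValueError(f"{path}: malformed patient on line {i}: {exc}") from exc
    return out


def save_schema(schema: EncodingSchema, path: str | Path) -> None:
    obj = {
        "diagnosis_codes": list(schema.diagnosis_codes),
        "medication_groups": list(schema.medication_groups),
        "lab_tests": [
            {"test_id": t.test_id, "ref_low": t.ref_low, "ref_high": t.ref_high}
            for t in schema.lab_tests
        ],
        "age_min": schema.age_min,
        "age_max": schema.age_max,
    }
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_schema(path: str | Path) -> EncodingSchema:
    obj = yaml.safe_load(Path(path).read_text())
    return build_schema(
        obj["diagnosis_codes"],
        obj["medication_groups"],
        [LabTest(t["test_id"], float(t["ref_low"]), float(t["ref_high"])) for t in obj["lab_tests"]],
        age_bounds=(float(obj.get("age_min", 0.0)), float(obj.get("age_max", 120.0))),
    )


def full_size_schema() -> EncodingSchema:
    """Synthetic vocabulary at the full study scale: 1232/11/22 → d = 1309."""
    return build_schema(
        [f"D{i:04d}" for i in range(1232)],
        [f"MED{i:02d}" for i in range(11)],
        [(f"L{i:02d}", 10.0 + i, 20.0 + 2 * i) for i in range(22)],
    )


def write_features(
    features: np.ndarray,
    patient_ids: Sequence[str],
    prefix_lengths: Sequence[int],
    path: str | Path,
    method: str,
) -> None:
    """Write one row per sample: patient_id, prefix_length, f0..f{d-1}."""
    d = features.shape[1]
    df = pd.DataFrame(features, columns=[f"f{i}" for i in range(d)])
    df.insert(0, "prefix_length", list(prefix_lengths))
    df.insert(0, "patient_id", list(patient_ids))
    with open(path, "w") as fh:
        fh.write(f"# method={method} dim={d}\n")
        df.to_csv(fh, index=False)


def read_features(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a feature table; returns (frame, header metadata)."""
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if "dim" in meta:
        meta["dim"] = int(meta["dim"])
        n_feat = df.shape[1] - 2
        if n_feat != meta["dim"]:
            raise ValueError(
                f"{path}: header says dim={meta['dim']} but file has {n_feat} feature columns"
            )
    return df, meta
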