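"""Clinical-event vocabulary and multi-hot encoding of inpatient records.

A patient is an ordered sequence of hospital admissions; each admission
carries diagnosis codes, medication-group codes and numeric lab results.
Every admission is encoded as a binary *multi-hot* vector whose positions
are partitioned as ``[diagnoses | medication groups | lab flags]``, with
each lab test contributing three mutually exclusive flag dimensions
(high / low / normal).  With the default vocabulary sizes (1232 diagnosis
codes, 11 medication groups, 22 lab tests) the clinical vector has
d = 1232 + 11 + 66 = 1309 dimensions, and a raw record (clinical vector
plus normalized age and gender) has 1311.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: lab flag order within each test's 3-dim block
LAB_FLAGS = ("high", "low", "normal")


class UnknownCodeError(KeyError):
    """Raised in strict mode when a record carries a code absent from the schema."""


@dataclass(frozen=True)
class LabTest:
    """A lab test with its reference interval (``ref_low`` < ``ref_high``)."""

    test_id: str
    ref_low: float
    ref_high: float

    def __post_init__(self) -> None:
        if not self.ref_low < self.ref_high:
            raise ValueError(
                f"lab test {self.test_id!r}: ref_low ({self.ref_low}) must be "
                f"< ref_high ({self.ref_high})"
            )


@dataclass(frozen=True)
class EncodingSchema:
    """Fixed vocabulary mapping clinical events to multi-hot positions.

    List order defines dimension order.  The clinical dimension is
    ``d = |diagnosis_codes| + |medication_groups| + 3 * |lab_tests|``;
    the raw record dimension (with demographics) is ``d + 2``.
    """

    diagnosis_codes: tuple[str, ...]
    medication_groups: tuple[str, ...]
    lab_tests: tuple[LabTest, ...]
    age_min: float = 0.0
    age_max: float = 120.0

    # position lookups, filled in __post_init__
    _diag_index: dict = field(default_factory=dict, repr=False, compare=False)
    _med_index: dict = field(default_factory=dict, repr=False, compare=False)
    _lab_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name, ids in (
            ("diagnosis_codes", self.diagnosis_codes),
            ("medication_groups", self.medication_groups),
            ("lab_tests", tuple(t.test_id for t in self.lab_tests)),
        ):
            seen: set[str] = set()
            for ident in ids:
                if ident in seen:
                    raise ValueError(f"duplicate identifier {ident!r} in {name}")
                seen.add(ident)
        if not self.age_max > self.age_min:
            raise ValueError("age_max must be > age_min")
        n_diag = len(self.diagnosis_codes)
        n_med = len(self.medication_groups)
        object.__setattr__(
            self, "_diag_index", {c: i for i, c in enumerate(self.diagnosis_codes)}
        )
        object.__setattr__(
            self,
            "_med_index",
            {g: n_diag + i for i, g in enumerate(self.medication_groups)},
        )
        object.__setattr__(
            self,
            "_lab_index",
            {
                t.test_id: n_diag + n_med + 3 * i
                for i, t in enumerate(self.lab_tests)
            },
        )

    @property
    def n_diagnoses(self) -> int:
        return len(self.diagnosis_codes)

    @property
    def n_medications(self) -> int:
        return len(self.medication_groups)

    @property
    def n_lab_tests(self) -> int:
        return len(self.lab_tests)

    @property
    def clinical_dim(self) -> int:
        """d: length of the clinical multi-hot vector."""
        return self.n_diagnoses + self.n_medications + 3 * self.n_lab_tests

    @property
    def raw_dim(self) -> int:
        """d + 2: clinical vector plus [normalized age, gender]."""
        return self.clinical_dim + 2

    def fingerprint(self) -> str:
        """Stable digest of the vocabulary, used to guard model/schema mismatch."""
        import hashlib

        h = hashlib.sha256()
        for part in (
            self.diagnosis_codes,
            self.medication_groups,
            tuple((t.test_id, t.ref_low, t.ref_high) for t in self.lab_tests),
            (self.age_min, self.age_max),
        ):
            h.update(repr(part).encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class ClinicalRecord:
    """One inpatient admission: diagnoses, medications and lab results."""

    record_id: str
    admission_time: date
    diagnoses: frozenset[str] = frozenset()
    medications: frozenset[str] = frozenset()
    lab_results: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "diagnoses", frozenset(self.diagnoses))
        object.__setattr__(self, "medications", frozenset(self.medications))
        object.__setattr__(self, "lab_results", dict(self.lab_results))


@dataclass
class PatientHistory:
    """A patient: demographics, chronological admissions and outcome labels."""

    patient_id: str
    age: float
    gender: int
    records: list[ClinicalRecord]
    died: int = 0
    comorbidities: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"patient {self.patient_id!r} has no records")
        self.comorbidities = frozenset(self.comorbidities)
        # stable sort: equal admission dates keep input order
        self.records = sorted(self.records, key=lambda r: r.admission_time)


@dataclass(frozen=True)
class Sample:
    """A prefix of a patient's admissions with the patient's final labels."""

    patient_id: str
    prefix_length: int
    tensor: np.ndarray  # (prefix_length, d) binary
    age: float
    gender: int
    died: int
    comorbidities: frozenset[str] = frozenset()


def build_schema(
    diagnosis_codes: Sequence[str],
    medication_groups: Sequence[str],
    lab_tests: Iterable[tuple[str, float, float] | LabTest],
    age_bounds: tuple[float, float] = (0.0, 120.0),
) -> EncodingSchema:
    """Build an :class:`EncodingSchema`; rejects duplicates and bad references."""
    tests = tuple(
        t if isinstance(t, LabTest) else LabTest(*t) for t in lab_tests
    )
    return EncodingSchema(
        diagnosis_codes=tuple(diagnosis_codes),
        medication_groups=tuple(medication_groups),
        lab_tests=tests,
        age_min=float(age_bounds[0]),
        age_max=float(age_bounds[1]),
    )


def flag_lab_result(value: float, ref_low: float, ref_high: float) -> str:
    """Classify a numeric lab value against its reference interval.

    Values exactly on a bound count as ``normal`` (inclusive interval):
    ``high`` iff value > ref_high, ``low`` iff value < ref_low.
    """
    if not ref_low < ref_high:
        raise ValueError("ref_low must be < ref_high")
    if value > ref_high:
        return "high"
    if value < ref_low:
        return "low"
    return "normal"


def encode_record(
    record: ClinicalRecord, schema: EncodingSchema, strict: bool = False
) -> np.ndarray:
    """Encode one admission as a length-d binary multi-hot vector.

    Unknown codes raise :class:`UnknownCodeError` in strict mode and are
    otherwise skipped with a logged warning.  A reported lab test sets
    exactly one of its three flag dimensions; unreported tests set none.
    """
    v = np.zeros(schema.clinical_dim, dtype=np.float64)

    def _unknown(kind: str, ident: str) -> None:
        if strict:
            raise UnknownCodeError(f"unknown {kind} {ident!r} not in schema")
        logger.warning("ignoring unknown %s %r (record %s)", kind, ident, record.record_id)

    for code in record.diagnoses:
        pos = schema._diag_index.get(code)
        if pos is None:
            _unknown("diagnosis code", code)
        else:
            v[pos] = 1.0
    for group in record.medications:
        pos = schema._med_index.get(group)
        if pos is None:
            _unknown("medication group", group)
        else:
            v[pos] = 1.0
    for test_id, value in record.lab_results.items():
        base = schema._lab_index.get(test_id)
        if base is None:
            _unknown("lab test", test_id)
            continue
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue  # missing value: all three flags stay zero
        test = schema.lab_tests[(base - schema.n_diagnoses - schema.n_medications) // 3]
        flag = flag_lab_result(float(value), test.ref_low, test.ref_high)
        v[base + LAB_FLAGS.index(flag)] = 1.0
    return v


def encode_patient(
    patient: PatientHistory, schema: EncodingSchema, strict: bool = False
) -> np.ndarray:
    """Encode a patient as an (n_records, d) binary tensor in admission order."""
    return np.stack(
        [encode_record(r, schema, strict=strict) for r in patient.records]
    )


def decode_vector(v: np.ndarray, schema: EncodingSchema) -> dict:
    """Invert :func:`encode_record`: recover events and flags from 1-positions."""
    nd, nm = schema.n_diagnoses, schema.n_medications
    diagnoses = {schema.diagnosis_codes[i] for i in np.flatnonzero(v[:nd])}
    medications = {
        schema.medication_groups[i] for i in np.flatnonzero(v[nd : nd + nm])
    }
    flags = {}
    lab_block = v[nd + nm :]
    for i, test in enumerate(schema.lab_tests):
        block = lab_block[3 * i : 3 * i + 3]
        on = np.flatnonzero(block)
        if on.size:
            flags[test.test_id] = LAB_FLAGS[on[0]]
    return {"diagnoses": diagnoses, "medications": medications, "lab_flags": flags}


def normalize_age(age: float, schema: EncodingSchema) -> float:
    """Min-max normalize age to [0, 1]; out-of-range ages are clipped."""
    lo, hi = schema.age_min, schema.age_max
    if not hi > lo:
        raise ValueError("degenerate age bounds")
    return float(np.clip((age - lo) / (hi - lo), 0.0, 1.0))


def prefix_split(
    patient: PatientHistory, schema: EncodingSchema, strict: bool = False
) -> list[Sample]:
    """Split a patient with n admissions into n prefix samples.

    The i-th sample holds the first i admissions; every sample inherits the
    patient's final in-hospital death flag and comorbidity set.
    """
    tensor = encode_patient(patient, schema, strict=strict)
    return [
        Sample(
            patient_id=patient.patient_id,
            prefix_length=i,
            tensor=tensor[:i],
            age=patient.age,
            gender=patient.gender,
            died=patient.died,
            comorbidities=patient.comorbidities,
        )
        for i in range(1, len(patient.records) + 1)
    ]


def split_cohort(
    patients: Sequence[PatientHistory], schema: EncodingSchema, strict: bool = False
) -> list[Sample]:
    """Prefix-split every patient; sample count equals total record count."""
    out: list[Sample] = []
    for p in patients:
        out.extend(prefix_split(p, schema, strict=strict))
    return out
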