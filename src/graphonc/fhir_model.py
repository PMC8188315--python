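"""Clinical domain model: FHIR-style coded records, patient bundles and cohort I/O.

The record families mirror the FHIR resources used for structured oncology data:
``Observation-genetics`` (gene symbols from genetic test reports), ``Observation``
(LOINC-coded lab tests with numeric values and reference ranges), ``Condition``
(ICD-9 diagnoses), ``Medication`` (RxNorm codes), ``FamilyMemberHistory`` (ICD-9
family-history diagnoses) and ``Patient`` demographics.  A :class:`Cohort` packages
one bundle per patient together with single-label primary-cancer annotations drawn
from the nine ICD-9 target codes.

Cohorts serialize to a single JSON document (``graphonc-cohort/1``); see
``docs/cohort_format.md`` for the schema.  All invariants are enforced at
construction time, so a cohort that loads is valid by construction.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Sequence

log = logging.getLogger(__name__)

FORMAT_TAG = "graphonc-cohort/1"

#: The nine ICD-9 primary-cancer codes that form the prediction target.
CANCER_CODES: tuple[str, ...] = (
    "153.9",  # colon
    "155",    # liver
    "157.9",  # pancreas
    "162.9",  # bronchus and lung
    "171.9",  # connective and other soft tissue
    "174.9",  # breast (female)
    "183",    # ovary
    "185",    # prostate
    "193",    # thyroid gland
)

CANCER_SITES: dict[str, str] = {
    "153.9": "colon",
    "155": "liver",
    "157.9": "pancreas",
    "162.9": "bronchus and lung",
    "171.9": "connective and other soft tissue",
    "174.9": "breast",
    "183": "ovary",
    "185": "prostate",
    "193": "thyroid gland",
}


class CohortError(Exception):
    """Base class for cohort construction and I/O failures."""


class CohortValidationError(CohortError):
    """An invariant of the domain model was violated."""


class CohortFormatError(CohortError):
    """A bundle document could not be parsed."""


class CodeSystem(str, Enum):
    ICD9 = "ICD9"
    LOINC = "LOINC"
    RXNORM = "RXNORM"
    GENE_SYMBOL = "GENE_SYMBOL"
    INTERNAL = "INTERNAL"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class CodedConcept:
    """A coded clinical concept; identity is ``(system, code)``, display is cosmetic."""

    system: CodeSystem
    code: str
    display: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.code:
            raise CohortValidationError("CodedConcept.code must be non-empty")


@dataclass(frozen=True)
class PatientDemographics:
    patient_id: str
    age_years: int
    sex: Sex = Sex.UNKNOWN

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortValidationError("patient_id must be non-empty")
        if not 0 <= self.age_years <= 120:
            raise CohortValidationError(
                f"{self.patient_id}: age_years={self.age_years} outside [0, 120]"
            )


@dataclass(frozen=True)
class GeneticObservation:
    patient_id: str
    gene: CodedConcept
    report_date: dt.date

    def __post_init__(self) -> None:
        if self.gene.system is not CodeSystem.GENE_SYMBOL:
            raise CohortValidationError(
                f"{self.patient_id}: genetic observation requires GENE_SYMBOL, "
                f"got {self.gene.system.value}"
            )


@dataclass(frozen=True)
class LabObservation:
    patient_id: str
    test: CodedConcept
    value: float | None
    unit: str
    ref_low: float | None
    ref_high: float | None
    effective_date: dt.date

    def __post_init__(self) -> None:
        if self.test.system is not CodeSystem.LOINC:
            raise CohortValidationError(
                f"{self.patient_id}: lab observation requires LOINC, "
                f"got {self.test.system.value}"
            )
        if (
            self.ref_low is not None
            and self.ref_high is not None
            and self.ref_low > self.ref_high
        ):
            raise CohortValidationError(
                f"{self.patient_id}: lab {self.test.code} has ref_low > ref_high"
            )


@dataclass(frozen=True)
class ConditionRecord:
    patient_id: str
    condition: CodedConcept
    recorded_date: dt.date

    def __post_init__(self) -> None:
        if self.condition.system is not CodeSystem.ICD9:
            raise CohortValidationError(
                f"{self.patient_id}: condition requires ICD9, "
                f"got {self.condition.system.value}"
            )


@dataclass(frozen=True)
class MedicationRecord:
    patient_id: str
    drug: CodedConcept
    recorded_date: dt.date

    def __post_init__(self) -> None:
        if self.drug.system is not CodeSystem.RXNORM:
            raise CohortValidationError(
                f"{self.patient_id}: medication requires RXNORM, "
                f"got {self.drug.system.value}"
            )


@dataclass(frozen=True)
class FamilyHistoryRecord:
    patient_id: str
    condition: CodedConcept

    def __post_init__(self) -> None:
        if self.condition.system is not CodeSystem.ICD9:
            raise CohortValidationError(
                f"{self.patient_id}: family history requires ICD9, "
                f"got {self.condition.system.value}"
            )


@dataclass(frozen=True)
class CancerLabel:
    """Single primary-cancer annotation; the code must be one of the 9 targets."""

    patient_id: str
    cancer: CodedConcept
    diagnosis_date: dt.date

    def __post_init__(self) -> None:
        if self.cancer.system is not CodeSystem.ICD9:
            raise CohortValidationError(f"{self.patient_id}: cancer label requires ICD9")
        if self.cancer.code not in CANCER_CODES:
            raise CohortValidationError(
                f"{self.patient_id}: {self.cancer.code!r} is not one of the 9 "
                f"target cancer codes"
            )


@dataclass(frozen=True)
class PatientBundle:
    """All records of one patient.  Every record must carry the patient's id."""

    demographics: PatientDemographics
    genetics: tuple[GeneticObservation, ...] = ()
    labs: tuple[LabObservation, ...] = ()
    conditions: tuple[ConditionRecord, ...] = ()
    medications: tuple[MedicationRecord, ...] = ()
    family_history: tuple[FamilyHistoryRecord, ...] = ()

    def __post_init__(self) -> None:
        pid = self.demographics.patient_id
        for fam in ("genetics", "labs", "conditions", "medications", "family_history"):
            for rec in getattr(self, fam):
                if rec.patient_id != pid:
                    raise CohortValidationError(
                        f"bundle {pid}: {fam} record carries patient_id "
                        f"{rec.patient_id!r}"
                    )

    @property
    def patient_id(self) -> str:
        return self.demographics.patient_id

    def n_records(self) -> int:
        return (
            len(self.genetics)
            + len(self.labs)
            + len(self.conditions)
            + len(self.medications)
            + len(self.family_history)
        )


@dataclass(frozen=True)
class Cohort:
    """A list of patient bundles plus per-patient cancer labels.

    Invariants: patient ids are unique, labelled ids are a subset of bundle ids,
    and at most one label exists per patient (enforced by the mapping).
    """

    bundles: tuple[PatientBundle, ...]
    labels: Mapping[str, CancerLabel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [b.patient_id for b in self.bundles]
        seen: set[str] = set()
        for pid in ids:
            if pid in seen:
                raise CohortValidationError(f"duplicate patient_id {pid!r}")
            seen.add(pid)
        for pid, label in self.labels.items():
            if pid not in seen:
                raise CohortValidationError(f"label for unknown patient {pid!r}")
            if label.patient_id != pid:
                raise CohortValidationError(
                    f"label keyed {pid!r} carries patient_id {label.patient_id!r}"
                )

    def __len__(self) -> int:
        return len(self.bundles)

    def __iter__(self) -> Iterator[PatientBundle]:
        return iter(self.bundles)

    @property
    def patient_ids(self) -> tuple[str, ...]:
        return tuple(b.patient_id for b in self.bundles)

    def bundle(self, patient_id: str) -> PatientBundle:
        for b in self.bundles:
            if b.patient_id == patient_id:
                return b
        raise KeyError(patient_id)

    def label_codes(self) -> dict[str, str]:
        """patient_id -> target cancer code, for labelled patients."""
        return {pid: lab.cancer.code for pid, lab in self.labels.items()}

    def subset(self, patient_ids: Sequence[str]) -> "Cohort":
        keep = set(patient_ids)
        return Cohort(
            bundles=tuple(b for b in self.bundles if b.patient_id in keep),
            labels={p: l for p, l in self.labels.items() if p in keep},
        )

    def fingerprint(self) -> str:
        """Stable content hash of the cohort (used for stage caching)."""
        import hashlib

        blob = json.dumps(cohort_to_dict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# serialization


def _date(s: str, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(s)
    except (TypeError, ValueError) as exc:
        raise CohortFormatError(f"{where}: bad date {s!r}") from exc


def _opt_float(v: object, where: str) -> float | None:
    if v is None:
        return None
    if isinstance(v, (int, float)) and not isinstance(v, bool):
        return float(v)
    raise CohortFormatError(f"{where}: expected number, got {v!r}")


def _warn_unknown(obj: Mapping, known: set[str], where: str) -> None:
    extra = set(obj) - known
    if extra:
        log.warning("%s: ignoring unknown fields %s", where, sorted(extra))


def _bundle_from_dict(obj: Mapping, idx: int) -> PatientBundle:
    where = f"bundle[{idx}]"
    if "patient" not in obj:
        raise CohortFormatError(f"{where}: missing 'patient'")
    _warn_unknown(
        obj,
        {"patient", "genetics", "labs", "conditions", "medications", "family_history"},
        where,
    )
    pat = obj["patient"]
    _warn_unknown(pat, {"patient_id", "age_years", "sex"}, f"{where}.patient")
    try:
        demo = PatientDemographics(
            patient_id=str(pat["patient_id"]),
            age_years=int(pat["age_years"]),
            sex=Sex(pat.get("sex", "unknown")),
        )
    except KeyError as exc:
        raise CohortFormatError(f"{where}.patient: missing field {exc}") from exc
    except ValueError as exc:
        raise CohortFormatError(f"{where}.patient: {exc}") from exc
    pid = demo.patient_id
    where = f"patient {pid}"

    def concept(system: CodeSystem, rec: Mapping, key: str) -> CodedConcept:
        if key not in rec:
            raise CohortFormatError(f"{where}: record missing {key!r}")
        return CodedConcept(system, str(rec[key]), rec.get("display"))

    genetics = tuple(
        GeneticObservation(
            pid,
            concept(CodeSystem.GENE_SYMBOL, r, "gene"),
            _date(r.get("report_date", ""), where),
        )
        for r in obj.get("genetics", ())
    )
    labs = tuple(
        LabObservation(
            pid,
            concept(CodeSystem.LOINC, r, "loinc"),
            _opt_float(r.get("value"), where),
            str(r.get("unit", "")),
            _opt_float(r.get("ref_low"), where),
            _opt_float(r.get("ref_high"), where),
            _date(r.get("effective_date", ""), where),
        )
        for r in obj.get("labs", ())
    )
    conditions = tuple(
        ConditionRecord(
            pid,
            concept(CodeSystem.ICD9, r, "icd9"),
            _date(r.get("recorded_date", ""), where),
        )
        for r in obj.get("conditions", ())
    )
    medications = tuple(
        MedicationRecord(
            pid,
            concept(CodeSystem.RXNORM, r, "rxnorm"),
            _date(r.get("recorded_date", ""), where),
        )
        for r in obj.get("medications", ())
    )
    family_history = tuple(
        FamilyHistoryRecord(pid, concept(CodeSystem.ICD9, r, "icd9"))
        for r in obj.get("family_history", ())
    )
    return PatientBundle(demo, genetics, labs, conditions, medications, family_history)


def cohort_from_dict(doc: Mapping) -> Cohort:
    if not isinstance(doc, Mapping):
        raise CohortFormatError("cohort document must be a JSON object")
    _warn_unknown(doc, {"format", "bundles", "labels"}, "cohort")
    bundles = tuple(
        _bundle_from_dict(b, i) for i, b in enumerate(doc.get("bundles", ()))
    )
    labels: dict[str, CancerLabel] = {}
    for pid, rec in (doc.get("labels") or {}).items():
        _warn_unknown(rec, {"cancer", "diagnosis_date"}, f"label {pid}")
        try:
            labels[pid] = CancerLabel(
                patient_id=pid,
                cancer=CodedConcept(
                    CodeSystem.ICD9, str(rec["cancer"]), CANCER_SITES.get(str(rec["cancer"]))
                ),
                diagnosis_date=_date(rec.get("diagnosis_date", ""), f"label {pid}"),
            )
        except KeyError as exc:
            raise CohortFormatError(f"label {pid}: missing field {exc}") from exc
    return Cohort(bundles=bundles, labels=labels)


def cohort_to_dict(cohort: Cohort) -> dict:
    def concept_fields(c: CodedConcept, key: str) -> dict:
        d: dict = {key: c.code}
        if c.display is not None:
            d["display"] = c.display
        return d

    bundles = []
    for b in cohort.bundles:
        bundles.append(
            {
                "patient": {
                    "patient_id": b.patient_id,
                    "age_years": b.demographics.age_years,
                    "sex": b.demographics.sex.value,
                },
                "genetics": [
                    {**concept_fields(r.gene, "gene"), "report_date": r.report_date.isoformat()}
                    for r in b.genetics
                ],
                "labs": [
                    {
                        **concept_fields(r.test, "loinc"),
                        "value": r.value,
                        "unit": r.unit,
                        "ref_low": r.ref_low,
                        "ref_high": r.ref_high,
                        "effective_date": r.effective_date.isoformat(),
                    }
                    for r in b.labs
                ],
                "conditions": [
                    {
                        **concept_fields(r.condition, "icd9"),
                        "recorded_date": r.recorded_date.isoformat(),
                    }
                    for r in b.conditions
                ],
                "medications": [
                    {
                        **concept_fields(r.drug, "rxnorm"),
                        "recorded_date": r.recorded_date.isoformat(),
                    }
                    for r in b.medications
                ],
                "family_history": [
                    concept_fields(r.condition, "icd9") for r in b.family_history
                ],
            }
        )
    labels = {
        pid: {
            "cancer": lab.cancer.code,
            "diagnosis_date": lab.diagnosis_date.isoformat(),
        }
        for pid, lab in sorted(cohort.labels.items())
    }
    return {"format": FORMAT_TAG, "bundles": bundles, "labels": labels}


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort bundle document.

    Raises :class:`CohortFormatError` on malformed documents (naming the offending
    patient or record) and :class:`CohortValidationError` on invariant violations
    such as duplicate patient ids.  Unknown fields are ignored with a warning.
    """
    path = Path(path)
    try:
        with path.open() as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise CohortFormatError(f"{path}: not valid JSON ({exc})") from exc
    return cohort_from_dict(doc)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as a JSON bundle document with deterministic key order."""
    path = Path(path)
    with path.open("w") as fh:
        json.dump(cohort_to_dict(cohort), fh, indent=1)
        fh.write("\n")


def strip_target_records(
    cohort: Cohort, codes: Sequence[str] = CANCER_CODES
) -> Cohort:
    """Remove condition records carrying any target cancer code.

    Mirrors the preprocessing step of dropping the billing records of the cancers
    being predicted, so the label cannot leak into the features through its own
    diagnosis code.  Only condition records are touched; the removal set defaults
    to the 9 target codes and can be widened via ``codes``.  Idempotent.
    """
    target = set(codes)
    new_bundles = []
    for b in cohort.bundles:
        kept = tuple(c for c in b.conditions if c.condition.code not in target)
        new_bundles.append(replace(b, conditions=kept) if len(kept) != len(b.conditions) else b)
    return Cohort(bundles=tuple(new_bundles), labels=dict(cohort.labels))
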