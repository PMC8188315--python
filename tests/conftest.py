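"""Shared fixtures: hand-built toy cohorts and small generated cohorts."""

from __future__ import annotations

import datetime as dt

import pytest

from graphonc import (
    CodedConcept,
    CodeSystem,
    Cohort,
    ConditionRecord,
    FamilyHistoryRecord,
    GeneratorConfig,
    GeneticObservation,
    LabObservation,
    MedicationRecord,
    PatientBundle,
    PatientDemographics,
    CancerLabel,
    Sex,
    generate_cohort,
)

D = dt.date


def make_bundle(
    pid: str,
    age: int = 60,
    sex: Sex = Sex.MALE,
    genes: tuple[str, ...] = (),
    conditions: tuple[str, ...] = (),
    medications: tuple[str, ...] = (),
    family_history: tuple[str, ...] = (),
    labs: tuple[tuple, ...] = (),  # (loinc, value, lo, hi)
    date: dt.date = D(2020, 6, 1),
) -> PatientBundle:
    return PatientBundle(
        demographics=PatientDemographics(pid, age, sex),
        genetics=tuple(
            GeneticObservation(pid, CodedConcept(CodeSystem.GENE_SYMBOL, g), date)
            for g in genes
        ),
        labs=tuple(
            LabObservation(
                pid, CodedConcept(CodeSystem.LOINC, code), value, "U/L", lo, hi, date
            )
            for code, value, lo, hi in labs
        ),
        conditions=tuple(
            ConditionRecord(pid, CodedConcept(CodeSystem.ICD9, c), date)
            for c in conditions
        ),
        medications=tuple(
            MedicationRecord(pid, CodedConcept(CodeSystem.RXNORM, m), date)
            for m in medications
        ),
        family_history=tuple(
            FamilyHistoryRecord(pid, CodedConcept(CodeSystem.ICD9, c))
            for c in family_history
        ),
    )


def make_label(pid: str, code: str, date: dt.date = D(2020, 7, 1)) -> CancerLabel:
    return CancerLabel(pid, CodedConcept(CodeSystem.ICD9, code), date)


@pytest.fixture
def two_patient_cohort() -> Cohort:
    """Two patients sharing the TP53 gene: the canonical merged-graph example."""
    b1 = make_bundle("P1", genes=("TP53",), conditions=("401.9",))
    b2 = make_bundle("P2", genes=("TP53",), labs=(("2160-0", 7.0, 0.6, 1.2),))
    return Cohort(
        (b1, b2),
        {"P1": make_label("P1", "162.9"), "P2": make_label("P2", "153.9")},
    )


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """9 classes x 12 patients; small enough for fast pipeline tests."""
    return generate_cohort(GeneratorConfig(n_per_class=12, seed=5))
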