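"""Synthetic cohort generator with planted class-conditional signal.

Emulates the statistical structure the prediction pipeline assumes, so every
stage is testable without clinical data:

* per-class marker items (genes, abnormal labs, site-specific diagnoses, sex
  constraints) planted at prevalence ``theta_signal`` in their class and
  ``theta_background`` elsewhere, with classic tumor-marker assignments (PSA and
  testosterone for prostate, thyroglobulin antibody and *TERT* for thyroid,
  CA 15-3 for breast, CA-125 for ovary, CA 19-9 for pancreas, AFP for liver,
  *EGFR* for lung, *APC* for colon);
* shared background codes at realistic prevalences (e.g. *TP53* in ~55% of
  genetic reports, hypertension and routine-exam codes, near-universal CBC
  labs), plus a filler vocabulary at the background rate;
* record timestamps drawn as whole months before the diagnosis date, with
  phenotype-marker presence decaying as ``exp(-decay_lambda * months)`` — so
  signal weakens as records move away from diagnosis.  Each phenotype marker
  gets ``marker_visits`` dated chances, reflecting repeat encounters; genetic
  observations are drawn once with a report date at the diagnostic workup, so
  genetic signal does not decay with the look-back horizon;
* each patient additionally carries their own cancer code as a condition record
  at the diagnosis date, which the preprocessing step must strip;
* a cancer-of-unknown-primary variant in which site-specific diagnoses are
  suppressed and marker gene/lab signal is attenuated toward background.

Fully reproducible from ``GeneratorConfig.seed``.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .fhir_model import (
    CANCER_CODES,
    CancerLabel,
    CodedConcept,
    CodeSystem,
    Cohort,
    ConditionRecord,
    FamilyHistoryRecord,
    GeneticObservation,
    LabObservation,
    MedicationRecord,
    PatientBundle,
    PatientDemographics,
    Sex,
)

DAYS_PER_MONTH = 30.44

#: Background item prevalences (fraction of patients), echoing published
#: top-10 frequency tables for an oncology genetic-report cohort.
BACKGROUND_GENES: dict[str, float] = {
    "TP53": 0.547, "KRAS": 0.289, "MLL2": 0.171, "LRP1B": 0.169, "MLL3": 0.148,
    "ARID1B": 0.136, "FAT1": 0.133, "PRKDC": 0.127, "ARID1A": 0.125,
}
BACKGROUND_DIAGNOSES: dict[str, float] = {
    "Z02.9": 0.257, "I10": 0.179, "401.9": 0.174, "272.4": 0.146, "R91.8": 0.142,
    "V68.9": 0.133, "Z00.00": 0.127, "E78.5": 0.117, "V72.83": 0.099, "V70.0": 0.099,
}
BACKGROUND_LABS: dict[str, float] = {
    "777-3": 0.994, "2160-0": 0.991, "965763": 0.988, "718-7": 0.988,
    "788-0": 0.988, "789-8": 0.988, "1749545": 0.988, "787-2": 0.988,
    "337180": 0.978, "383903": 0.976,
}
BACKGROUND_MEDICATIONS: dict[str, float] = {
    "5956": 0.724, "1359867": 0.679, "1807638": 0.552, "1807639": 0.541,
    "1740467": 0.456, "4337": 0.407, "314659": 0.376, "847630": 0.367,
    "198440": 0.341, "1808234": 0.296,
}
BACKGROUND_FAMILY_HISTORY: dict[str, float] = {
    "V47.2": 0.295, "429.9": 0.295, "429.89": 0.295, "162.9": 0.192, "162.8": 0.187,
    "272.4": 0.179, "434.91": 0.150, "799.9": 0.121, "311": 0.104, "447.9": 0.091,
}


@dataclass(frozen=True)
class ClassSignal:
    """Planted markers for one cancer class."""

    marker_genes: tuple[str, ...] = ()
    marker_labs: tuple[str, ...] = ()  # LOINC codes recorded as Abnormal
    marker_diagnoses: tuple[str, ...] = ()
    sex: Sex | None = None


@dataclass(frozen=True)
class SignalSpec:
    per_class: Mapping[str, ClassSignal]

    @classmethod
    def default(cls) -> "SignalSpec":
        return cls(
            {
                # gene-anchored sites: the genetic marker is the primary signal
                "153.9": ClassSignal(("APC",), (), ("578.1",)),
                "162.9": ClassSignal(("EGFR",), (), ("793.19",)),
                "171.9": ClassSignal(("NF1",), (), ("729.81",)),
                "193": ClassSignal(("TERT",), ("8098-6",), ("241.0",)),
                # lab-anchored sites: serum tumor markers carry the signal
                "155": ClassSignal((), ("1834-1", "1742-6"), ("571.5",)),
                "157.9": ClassSignal((), ("24108-3", "3040-3"), ("577.0",)),
                "174.9": ClassSignal((), ("6875-9",), ("611.72",), Sex.FEMALE),
                "183": ClassSignal((), ("10334-1",), ("620.2",), Sex.FEMALE),
                "185": ClassSignal((), ("2857-1", "2986-8"), ("600.0",), Sex.MALE),
            }
        )

    @classmethod
    def null(cls) -> "SignalSpec":
        """No markers and no sex constraints: classes are exchangeable."""
        return cls({c: ClassSignal() for c in CANCER_CODES})

    def all_marker_codes(self) -> dict[str, set[str]]:
        out = {"genes": set(), "labs": set(), "diagnoses": set()}
        for sig in self.per_class.values():
            out["genes"].update(sig.marker_genes)
            out["labs"].update(sig.marker_labs)
            out["diagnoses"].update(sig.marker_diagnoses)
        return out


@dataclass(frozen=True)
class GeneratorConfig:
    n_per_class: int = 100
    classes: tuple[str, ...] = CANCER_CODES
    n_genes: int = 300
    n_labs: int = 200
    n_diagnoses: int = 400
    n_medications: int = 300
    n_family_history: int = 100
    theta_signal: float = 0.6
    theta_background: float = 0.05
    background_prevalences: Mapping[str, float] | None = None
    decay_lambda: float = 0.08  # per month
    marker_visits: int = 4
    months_span: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.theta_signal <= 1:
            raise ValueError("theta_signal must be in (0, 1]")
        if not 0 <= self.theta_background <= 1:
            raise ValueError("theta_background must be in [0, 1]")
        if self.theta_signal <= self.theta_background:
            raise ValueError("theta_signal must exceed theta_background")
        if self.decay_lambda < 0:
            raise ValueError("decay_lambda must be non-negative")
        if self.n_per_class < 1 or self.marker_visits < 1:
            raise ValueError("n_per_class and marker_visits must be >= 1")
        unknown = set(self.classes) - set(CANCER_CODES)
        if unknown:
            raise ValueError(f"unknown target classes {sorted(unknown)}")


def reference_range(loinc: str) -> tuple[float, float]:
    """Deterministic per-code reference range (synthetic, for value realism)."""
    h = int.from_bytes(hashlib.md5(loinc.encode()).digest()[:4], "big")
    low = 1.0 + (h % 90) / 10.0
    span = 1.0 + ((h >> 8) % 30) / 10.0
    return round(low, 2), round(low + span, 2)


def _filler_codes(kind: str, n: int, used: set[str]) -> list[str]:
    """n synthetic codes of a family, skipping anything already in use."""
    out: list[str] = []
    i = 0
    while len(out) < n:
        if kind == "gene":
            code = f"GENE{i:03d}"
        elif kind == "lab":
            code = f"{9100 + i}-5"
        elif kind == "dx":
            code = f"{240 + i // 10}.{i % 10}"
        elif kind == "med":
            code = f"{600000 + i}"
        else:  # family history
            code = f"{300 + i // 10}.{i % 10}"
        i += 1
        if code not in used:
            used.add(code)
            out.append(code)
    return out


def _vocab(config: GeneratorConfig, signal: SignalSpec):
    """(code, prevalence) lists per family: real top items + fillers at theta_b."""
    markers = signal.all_marker_codes()
    used = (
        set(CANCER_CODES)
        | markers["genes"] | markers["labs"] | markers["diagnoses"]
    )
    bg = dict(config.background_prevalences or {})

    def fam(kind: str, top: dict[str, float], n: int) -> list[tuple[str, float]]:
        items = [(c, bg.get(c, r)) for c, r in top.items() if c not in markers_all]
        used.update(c for c, _ in items)
        fill = _filler_codes(kind, max(0, n - len(items)), used)
        items += [(c, bg.get(c, config.theta_background)) for c in fill]
        return items

    markers_all = markers["genes"] | markers["labs"] | markers["diagnoses"]
    return {
        "genes": fam("gene", BACKGROUND_GENES, config.n_genes),
        "labs": fam("lab", BACKGROUND_LABS, config.n_labs),
        "diagnoses": fam("dx", BACKGROUND_DIAGNOSES, config.n_diagnoses),
        "medications": fam("med", BACKGROUND_MEDICATIONS, config.n_medications),
        "family_history": fam("fh", BACKGROUND_FAMILY_HISTORY, config.n_family_history),
    }


def _months_ago(date: dt.date, months: int) -> dt.date:
    return date - dt.timedelta(days=round(months * DAYS_PER_MONTH))


def _lab_record(
    pid: str, code: str, date: dt.date, abnormal: bool, rng: np.random.Generator
) -> LabObservation:
    lo, hi = reference_range(code)
    if abnormal:
        if rng.random() < 0.5:
            value = round(hi + 0.1 + rng.random() * (hi - lo), 3)
        else:
            value = round(max(0.0, lo - 0.1 - rng.random() * (hi - lo)), 3)
    else:
        value = round(lo + rng.random() * (hi - lo), 3)
    return LabObservation(
        pid, CodedConcept(CodeSystem.LOINC, code), value, "U/L", lo, hi, date
    )


def _generate(
    config: GeneratorConfig,
    signal: SignalSpec,
    suppression: float,
    id_prefix: str,
) -> Cohort:
    rng = np.random.default_rng(config.seed)
    vocab = _vocab(config, signal)
    anchor = dt.date(2021, 1, 1)
    ts, tb = config.theta_signal, config.theta_background
    lam = config.decay_lambda
    # suppression interpolates marker gene/lab strength toward background and
    # thins marker diagnoses toward zero
    theta_marker = tb + (ts - tb) * (1.0 - suppression)
    theta_marker_dx = ts * (1.0 - suppression)
    marker_codes = signal.all_marker_codes()

    bundles: list[PatientBundle] = []
    labels: dict[str, CancerLabel] = {}
    counter = 0
    for cls in config.classes:
        sig = signal.per_class.get(cls, ClassSignal())
        for _ in range(config.n_per_class):
            pid = f"{id_prefix}{counter:04d}"
            counter += 1
            dx_date = anchor - dt.timedelta(days=int(rng.integers(0, 365)))
            if sig.sex is not None:
                sex = sig.sex
            else:
                sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
            age = int(rng.integers(40, 86))
            demo = PatientDemographics(pid, age, sex)

            genetics: list[GeneticObservation] = []
            labs: list[LabObservation] = []
            conditions: list[ConditionRecord] = []
            medications: list[MedicationRecord] = []
            family_history: list[FamilyHistoryRecord] = []

            # --- background items, one presence draw per code -----------------
            for code, rate in vocab["genes"]:
                if rng.random() < rate:
                    genetics.append(
                        GeneticObservation(
                            pid,
                            CodedConcept(CodeSystem.GENE_SYMBOL, code),
                            dx_date - dt.timedelta(days=int(rng.integers(0, 61))),
                        )
                    )
            for code, rate in vocab["diagnoses"]:
                if rng.random() < rate:
                    m = int(rng.integers(0, config.months_span + 1))
                    conditions.append(
                        ConditionRecord(
                            pid, CodedConcept(CodeSystem.ICD9, code), _months_ago(dx_date, m)
                        )
                    )
            for code, rate in vocab["labs"]:
                if rng.random() < rate:
                    m = int(rng.integers(0, config.months_span + 1))
                    labs.append(
                        _lab_record(pid, code, _months_ago(dx_date, m), rng.random() < 0.15, rng)
                    )
            for code, rate in vocab["medications"]:
                if rng.random() < rate:
                    m = int(rng.integers(0, config.months_span + 1))
                    medications.append(
                        MedicationRecord(
                            pid, CodedConcept(CodeSystem.RXNORM, code), _months_ago(dx_date, m)
                        )
                    )
            for code, rate in vocab["family_history"]:
                if rng.random() < rate:
                    family_history.append(
                        FamilyHistoryRecord(pid, CodedConcept(CodeSystem.ICD9, code))
                    )

            # --- planted in-class markers -------------------------------------
            for gene in sig.marker_genes:
                if rng.random() < theta_marker:
                    genetics.append(
                        GeneticObservation(
                            pid,
                            CodedConcept(CodeSystem.GENE_SYMBOL, gene),
                            dx_date - dt.timedelta(days=int(rng.integers(0, 61))),
                        )
                    )
            for code in sig.marker_labs:
                for _v in range(config.marker_visits):
                    m = int(rng.integers(0, config.months_span + 1))
                    if rng.random() < theta_marker * np.exp(-lam * m):
                        labs.append(_lab_record(pid, code, _months_ago(dx_date, m), True, rng))
                if rng.random() < 0.3:  # incidental normal measurement
                    m = int(rng.integers(0, config.months_span + 1))
                    labs.append(_lab_record(pid, code, _months_ago(dx_date, m), False, rng))
            for code in sig.marker_diagnoses:
                for _v in range(config.marker_visits):
                    m = int(rng.integers(0, config.months_span + 1))
                    if rng.random() < theta_marker_dx * np.exp(-lam * m):
                        conditions.append(
                            ConditionRecord(
                                pid, CodedConcept(CodeSystem.ICD9, code), _months_ago(dx_date, m)
                            )
                        )

            # --- other classes' markers appear at background rate -------------
            for gene in sorted(marker_codes["genes"] - set(sig.marker_genes)):
                if rng.random() < tb:
                    genetics.append(
                        GeneticObservation(
                            pid,
                            CodedConcept(CodeSystem.GENE_SYMBOL, gene),
                            dx_date - dt.timedelta(days=int(rng.integers(0, 61))),
                        )
                    )
            for code in sorted(marker_codes["labs"] - set(sig.marker_labs)):
                r = rng.random()
                if r < tb:
                    m = int(rng.integers(0, config.months_span + 1))
                    labs.append(_lab_record(pid, code, _months_ago(dx_date, m), True, rng))
                elif r < tb + 0.3:
                    m = int(rng.integers(0, config.months_span + 1))
                    labs.append(_lab_record(pid, code, _months_ago(dx_date, m), False, rng))
            for code in sorted(marker_codes["diagnoses"] - set(sig.marker_diagnoses)):
                if rng.random() < tb:
                    m = int(rng.integers(0, config.months_span + 1))
                    conditions.append(
                        ConditionRecord(
                            pid, CodedConcept(CodeSystem.ICD9, code), _months_ago(dx_date, m)
                        )
                    )

            # the billing record of the target cancer itself (to be stripped)
            conditions.append(
                ConditionRecord(pid, CodedConcept(CodeSystem.ICD9, cls), dx_date)
            )

            bundles.append(
                PatientBundle(
                    demo,
                    tuple(genetics),
                    tuple(labs),
                    tuple(conditions),
                    tuple(medications),
                    tuple(family_history),
                )
            )
            labels[pid] = CancerLabel(
                pid, CodedConcept(CodeSystem.ICD9, cls), dx_date
            )
    return Cohort(tuple(bundles), labels)


def generate_cohort(
    config: GeneratorConfig = GeneratorConfig(),
    signal: SignalSpec | None = None,
) -> Cohort:
    """Generate a labelled cohort with planted class signal (see module docs)."""
    return _generate(config, signal or SignalSpec.default(), 0.0, "P")


def generate_cup_cohort(
    config: GeneratorConfig,
    signal: SignalSpec | None = None,
    suppression: float = 0.5,
) -> Cohort:
    """Cancer-of-unknown-primary variant: site-specific signal suppressed.

    Marker diagnoses are thinned by ``(1 - suppression)`` (gone at 1) and marker
    gene/lab prevalence is interpolated toward the background rate; labels are
    retained as the ground-truth eventual primaries.  ``suppression=0`` is
    distributionally identical to :func:`generate_cohort`.
    """
    if not 0.0 <= suppression <= 1.0:
        raise ValueError("suppression must be in [0, 1]")
    return _generate(config, signal or SignalSpec.default(), suppression, "C")
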