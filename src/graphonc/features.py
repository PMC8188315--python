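"""Bag-of-features construction, lab categorization and information-gain selection.

A patient is represented by an orderless collection of binary indicators, one per
distinct coded item in each enabled record family (gene symbols, ICD-9 diagnoses,
RxNorm medications, family-history ICD-9 codes), plus lab tests keyed by
``code=category`` where the numeric result is discretized against its reference
range into Null / Normal / Abnormal, plus demographics (age in years as a numeric
column and sex indicators).  Feature columns are named with a family prefix
(``G:``, ``D:``, ``M:``, ``L:``, ``H:``, ``demo:``) so family ablations and model
manifests stay auditable.

Feature selection ranks columns by information gain — the reduction in label
entropy from conditioning on the feature, in bits — and keeps the top ``d``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fhir_model import Cohort


class LabCategory(str, Enum):
    NULL = "Null"
    NORMAL = "Normal"
    ABNORMAL = "Abnormal"


class Provenance(str, Enum):
    BOF = "BOF"
    N2V = "N2V"
    FUSED = "FUSED"


class Family(str, Enum):
    """Record families, named by the single-letter scheme used for ablations."""

    GENETICS = "G"
    DIAGNOSIS = "D"
    MEDICATION = "M"
    LAB = "L"
    FAMILY_HISTORY = "H"
    DEMOGRAPHICS = "demo"


ALL_FAMILIES: frozenset[Family] = frozenset(Family)


def parse_families(text: str) -> frozenset[Family]:
    """Parse e.g. ``"GDML"`` or ``"G,D,demo"`` into a family set."""
    text = text.strip()
    if "," in text:
        parts = [p.strip() for p in text.split(",") if p.strip()]
    else:
        parts = list(text)
    fams = set()
    i = 0
    # allow "demo" spelled out inside the compact form
    joined = "".join(parts)
    while i < len(joined):
        if joined[i : i + 4] == "demo":
            fams.add(Family.DEMOGRAPHICS)
            i += 4
        else:
            fams.add(Family(joined[i]))
            i += 1
    return frozenset(fams)


@dataclass(frozen=True)
class FeatureMatrix:
    """Patients x named features with per-feature provenance."""

    patient_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray  # shape (n_patients, n_features), float64
    feature_provenance: tuple[Provenance, ...]

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.patient_ids == other.patient_ids
            and self.feature_names == other.feature_names
            and self.feature_provenance == other.feature_provenance
            and np.array_equal(self.values, other.values)
        )

    def __post_init__(self) -> None:
        if len(set(self.feature_names)) != len(self.feature_names):
            dupes = [n for n, c in Counter(self.feature_names).items() if c > 1]
            raise ValueError(f"duplicate feature names: {dupes[:5]}")
        if self.values.shape != (len(self.patient_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.patient_ids)}, {len(self.feature_names)})"
            )
        if len(self.feature_provenance) != len(self.feature_names):
            raise ValueError("feature_provenance length mismatch")

    @property
    def provenance(self) -> Provenance:
        kinds = set(self.feature_provenance)
        if kinds <= {Provenance.BOF}:
            return Provenance.BOF
        if kinds == {Provenance.N2V}:
            return Provenance.N2V
        return Provenance.FUSED

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset in the given order."""
        idx = {n: i for i, n in enumerate(self.feature_names)}
        cols = [idx[n] for n in names]
        return FeatureMatrix(
            self.patient_ids,
            tuple(names),
            self.values[:, cols].copy(),
            tuple(self.feature_provenance[c] for c in cols),
        )

    def rows(self, patient_ids: Sequence[str]) -> "FeatureMatrix":
        idx = {p: i for i, p in enumerate(self.patient_ids)}
        r = [idx[p] for p in patient_ids]
        return FeatureMatrix(
            tuple(patient_ids), self.feature_names, self.values[r].copy(),
            self.feature_provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.patient_ids), columns=list(self.feature_names)
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "patient_id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(
        cls, path: str | Path, provenance: Provenance = Provenance.BOF
    ) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="patient_id")
        return cls(
            tuple(str(p) for p in df.index),
            tuple(df.columns),
            df.to_numpy(dtype=float),
            (provenance,) * df.shape[1],
        )


def restrict_families(cohort: Cohort, families: frozenset[Family]) -> Cohort:
    """Drop record families that are not enabled (demographics stay structural).

    Used for data-source ablations: the returned cohort drives both
    bag-of-features and graph construction, so a disabled family contributes
    neither indicator columns nor network edges.
    """
    from dataclasses import replace

    bundles = []
    for b in cohort.bundles:
        bundles.append(
            replace(
                b,
                genetics=b.genetics if Family.GENETICS in families else (),
                labs=b.labs if Family.LAB in families else (),
                conditions=b.conditions if Family.DIAGNOSIS in families else (),
                medications=b.medications if Family.MEDICATION in families else (),
                family_history=(
                    b.family_history if Family.FAMILY_HISTORY in families else ()
                ),
            )
        )
    return Cohort(tuple(bundles), dict(cohort.labels))


def categorize_lab(
    value: float | None, ref_low: float | None, ref_high: float | None
) -> LabCategory:
    """Discretize a lab result against its reference range.

    Missing value -> Null; value within the inclusive range -> Normal; outside ->
    Abnormal.  A missing bound is open (treated as -inf / +inf).
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return LabCategory.NULL
    lo = -math.inf if ref_low is None else ref_low
    hi = math.inf if ref_high is None else ref_high
    return LabCategory.NORMAL if lo <= value <= hi else LabCategory.ABNORMAL


def patient_feature_items(bundle, families: frozenset[Family]) -> set[str]:
    """The set of binary feature names a bundle activates (demographic sex
    indicators included; the numeric age column is handled separately)."""
    items: set[str] = set()
    if Family.GENETICS in families:
        items.update(f"G:{r.gene.code}" for r in bundle.genetics)
    if Family.DIAGNOSIS in families:
        items.update(f"D:{r.condition.code}" for r in bundle.conditions)
    if Family.MEDICATION in families:
        items.update(f"M:{r.drug.code}" for r in bundle.medications)
    if Family.FAMILY_HISTORY in families:
        items.update(f"H:{r.condition.code}" for r in bundle.family_history)
    if Family.LAB in families:
        for r in bundle.labs:
            cat = categorize_lab(r.value, r.ref_low, r.ref_high)
            items.add(f"L:{r.test.code}={cat.value}")
    if Family.DEMOGRAPHICS in families:
        items.add(f"demo:sex={bundle.demographics.sex.value}")
    return items


def bag_of_features(
    cohort: Cohort,
    families: frozenset[Family] = ALL_FAMILIES,
    vocabulary: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Build the binary bag-of-features matrix for a cohort.

    One indicator per distinct code in each enabled family; a patient's indicator
    is 1 iff the patient has at least one matching record, so the representation
    is insensitive to record order and duplication.  With demographics enabled an
    integer ``demo:age`` column and sex indicator columns are added.

    ``vocabulary`` pins the column set (missing items become all-zero columns and
    novel items are dropped), which is how a held-out cohort is featurized against
    a training vocabulary.
    """
    if len(cohort) == 0:
        raise ValueError("cannot featurize an empty cohort")
    if not families:
        raise ValueError("families must be non-empty")
    per_patient = [patient_feature_items(b, families) for b in cohort.bundles]
    if vocabulary is None:
        names = sorted(set().union(*per_patient))
        if Family.DEMOGRAPHICS in families:
            names = ["demo:age"] + names
    else:
        names = list(vocabulary)
    col = {n: i for i, n in enumerate(names)}
    X = np.zeros((len(cohort), len(names)), dtype=float)
    for i, (bundle, items) in enumerate(zip(cohort.bundles, per_patient)):
        for item in items:
            j = col.get(item)
            if j is not None:
                X[i, j] = 1.0
        if "demo:age" in col and Family.DEMOGRAPHICS in families:
            X[i, col["demo:age"]] = float(bundle.demographics.age_years)
    return FeatureMatrix(
        cohort.patient_ids, tuple(names), X, (Provenance.BOF,) * len(names)
    )


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def information_gain(feature_column: Sequence, labels: Sequence) -> float:
    """H(Y) - H(Y|F) in bits, for a categorical feature and class labels.

    Non-negative, bounded by the label entropy, and invariant under relabeling of
    the feature categories.
    """
    f = np.asarray(feature_column)
    y = np.asarray(labels)
    if f.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: {f.shape[0]} features vs {y.shape[0]} labels")
    if y.shape[0] == 0:
        raise ValueError("empty input")
    _, y_idx = np.unique(y, return_inverse=True)
    _, f_idx = np.unique(f, return_inverse=True)
    n_y = y_idx.max() + 1
    n_f = f_idx.max() + 1
    joint = np.zeros((n_f, n_y))
    np.add.at(joint, (f_idx, y_idx), 1.0)
    h_y = _entropy(joint.sum(axis=0))
    n = len(y)
    h_y_given_f = sum(
        (row.sum() / n) * _entropy(row) for row in joint if row.sum() > 0
    )
    return max(0.0, h_y - h_y_given_f)


def rank_features(matrix: FeatureMatrix, labels: Mapping[str, str] | Sequence) -> list[str]:
    """Feature names sorted by descending information gain, ties lexical."""
    y = _labels_vector(matrix, labels)
    gains = [
        (-information_gain(matrix.values[:, j], y), name)
        for j, name in enumerate(matrix.feature_names)
    ]
    gains.sort()
    return [name for _, name in gains]


def _labels_vector(matrix: FeatureMatrix, labels) -> np.ndarray:
    if isinstance(labels, Mapping):
        return np.asarray([labels[p] for p in matrix.patient_ids])
    y = np.asarray(labels)
    if y.shape[0] != len(matrix.patient_ids):
        raise ValueError("labels length does not match matrix rows")
    return y


def select_features(
    matrix: FeatureMatrix, labels: Mapping[str, str] | Sequence, d: int
) -> FeatureMatrix:
    """Keep the ``d`` features with highest information gain.

    Ties are broken by lexical feature name, so selections are nested: the
    selection at d1 <= d2 is a subset of the selection at d2.  If the matrix has
    fewer than ``d`` features, all are kept.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    ranked = rank_features(matrix, labels)
    keep = sorted(ranked[:d])
    return matrix.select(keep)


def fuse(bof: FeatureMatrix, emb: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation of a bag-of-features block and an embedding block.

    The hybrid representation feeds both blocks to the classifier side by side;
    feature provenance is preserved per column.
    """
    if bof.patient_ids != emb.patient_ids:
        raise ValueError("fuse: patient_id order differs between inputs")
    if emb.n_features == 0:
        return bof
    if bof.n_features == 0:
        return emb
    overlap = set(bof.feature_names) & set(emb.feature_names)
    if overlap:
        raise ValueError(f"fuse: overlapping feature names {sorted(overlap)[:5]}")
    return FeatureMatrix(
        bof.patient_ids,
        bof.feature_names + emb.feature_names,
        np.hstack([bof.values, emb.values]),
        bof.feature_provenance + emb.feature_provenance,
    )
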