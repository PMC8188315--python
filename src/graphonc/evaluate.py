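"""Evaluation harness: cross-validation, ranking metrics, paired comparison,
time-window ablation, unknown-primary hold-out and Shapley feature attribution.

The primary report is one-vs-rest AUROC/AUPRC per cancer class, pooled over
held-out cross-validation scores (each patient scored exactly once by a model
not trained on it), with per-fold values retained for paired model comparison
by the Wilcoxon signed-rank test.  Feature selection and classifier fitting
happen inside each training fold; graph embeddings are transductive (built from
the unlabelled graph over all patients), so labels never touch them.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from . import features as feat
from .classify import TrainedModel, train_classifier
from .embedding import embed_patients
from .features import (
    FeatureMatrix,
    Provenance,
    bag_of_features,
    fuse,
    restrict_families,
    select_features,
)
from .fhir_model import Cohort, strip_target_records
from .rdf_graph import cohort_to_graph

log = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44


class MetricError(ValueError):
    """A metric is undefined for the given inputs."""


class DegenerateComparisonError(ValueError):
    """Paired comparison with all-zero differences."""


# ---------------------------------------------------------------------------
# ranking metrics


def auroc(scores: Sequence[float], binary_labels: Sequence) -> float:
    """Area under the ROC curve as the Mann-Whitney statistic.

    Equals P(score+ > score-) + 0.5 P(tie), computed from midranks; invariant
    under strictly monotone transforms of the scores.
    """
    y = np.asarray(binary_labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise MetricError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUROC undefined: one class absent")
    r = rankdata(s)
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores: Sequence[float], binary_labels: Sequence) -> float:
    """Area under the precision-recall curve (average-precision formulation)."""
    from sklearn.metrics import average_precision_score

    y = np.asarray(binary_labels).astype(int)
    if y.sum() == 0:
        raise MetricError("AUPRC undefined: no positives")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# paired model comparison (Wilcoxon signed-rank)


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p for integer ranks by subset-sum DP over sign patterns."""
    total = int(ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    counts /= counts.sum()
    w = int(round(w_plus))
    p_low = counts[: w + 1].sum()
    p_high = counts[w:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def compare_models(
    fold_scores_a: Sequence[float], fold_scores_b: Sequence[float]
) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired fold-level scores.

    Exact null distribution when there are no zero differences, no tied
    magnitudes and n <= 25; otherwise a normal approximation with Pratt's
    treatment of zeros, tie correction and continuity correction.
    """
    a = np.asarray(fold_scores_a, dtype=float)
    b = np.asarray(fold_scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs differ in length")
    if a.size < 5:
        raise ValueError("need at least 5 paired observations")
    d = a - b
    if np.all(d == 0):
        raise DegenerateComparisonError("all paired differences are zero")
    abs_d = np.abs(d)
    n_zero = int((d == 0).sum())
    no_ties = len(np.unique(abs_d[d != 0])) == (d != 0).sum()
    if n_zero == 0 and no_ties and d.size <= 25:
        ranks = rankdata(abs_d)
        w_plus = ranks[d > 0].sum()
        return _exact_signed_rank_p(w_plus, ranks)
    # Pratt: rank |d| including zeros, then discard the zeros' ranks
    ranks = rankdata(abs_d)
    w_plus = ranks[d > 0].sum()
    n = d.size
    mu = (n * (n + 1) - n_zero * (n_zero + 1)) / 4.0
    var = (n * (n + 1) * (2 * n + 1) - n_zero * (n_zero + 1) * (2 * n_zero + 1)) / 24.0
    _, tie_counts = np.unique(abs_d[d != 0], return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise DegenerateComparisonError("zero variance in signed-rank statistic")
    from scipy.stats import norm

    z = (abs(w_plus - mu) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(z)))


# ---------------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    assignment: Mapping[str, int]  # patient_id -> fold in [0, k)

    def fold_ids(self, fold: int) -> list[str]:
        return [p for p, f in self.assignment.items() if f == fold]


def assign_folds(
    patient_ids: Sequence[str],
    k: int,
    seed: int,
    labels: Mapping[str, str] | None = None,
) -> FoldAssignment:
    """Random partition into k folds with sizes differing by at most 1.

    Falls back to a stratified partition (with a warning) when some class has
    fewer members than k, to keep every class represented in training folds.
    """
    if k < 2 or k > len(patient_ids):
        raise ValueError(f"k={k} invalid for {len(patient_ids)} patients")
    rng = np.random.default_rng(seed)
    ids = list(patient_ids)
    assignment: dict[str, int] = {}
    stratify = False
    if labels is not None:
        smallest = min(Counter(labels[p] for p in ids).values())
        stratify = smallest < k
        if stratify:
            warnings.warn(
                f"smallest class has {smallest} < k={k} members; "
                "using stratified folds",
                stacklevel=2,
            )
    if stratify:
        by_class: dict[str, list[str]] = {}
        for p in ids:
            by_class.setdefault(labels[p], []).append(p)
        counter = 0
        for cls in sorted(by_class):
            members = by_class[cls]
            rng.shuffle(members)
            for p in members:
                assignment[p] = counter % k
                counter += 1
    else:
        perm = rng.permutation(len(ids))
        for pos, idx in enumerate(perm):
            assignment[ids[idx]] = pos % k
    return FoldAssignment(k, assignment)


@dataclass
class EvalResult:
    """Per-class and macro one-vs-rest AUROC/AUPRC with fold-level values."""

    per_class_auroc: dict[str, float]
    per_class_auprc: dict[str, float]
    macro_auroc: float
    macro_auprc: float
    fold_scores: dict[str, list[float]] = field(default_factory=dict)
    run_log: dict = field(default_factory=dict, compare=False)

    def to_json_dict(self) -> dict:
        return {
            "macro_auroc": self.macro_auroc,
            "macro_auprc": self.macro_auprc,
            "per_class_auroc": dict(sorted(self.per_class_auroc.items())),
            "per_class_auprc": dict(sorted(self.per_class_auprc.items())),
            "fold_scores": {c: list(v) for c, v in sorted(self.fold_scores.items())},
        }

    def to_json(self, indent: int | None = 1) -> str:
        return json.dumps(self.to_json_dict(), indent=indent, sort_keys=True)

    def summary_table(self) -> str:
        from .fhir_model import CANCER_SITES

        lines = [f"{'cancer (ICD-9)':<42s} {'AUROC':>7s} {'AUPRC':>7s}"]
        for cls in sorted(self.per_class_auroc):
            site = CANCER_SITES.get(cls, "")
            lines.append(
                f"{site + ' (' + cls + ')':<42s} "
                f"{self.per_class_auroc[cls] * 100:7.2f} "
                f"{self.per_class_auprc[cls] * 100:7.2f}"
            )
        lines.append(
            f"{'macro average':<42s} {self.macro_auroc * 100:7.2f} "
            f"{self.macro_auprc * 100:7.2f}"
        )
        return "\n".join(lines)


def _result_from_scores(
    classes: Sequence[str],
    pooled: np.ndarray,
    y: np.ndarray,
    fold_of: np.ndarray | None,
    k: int,
    run_log: dict,
) -> EvalResult:
    per_auroc: dict[str, float] = {}
    per_auprc: dict[str, float] = {}
    fold_scores: dict[str, list[float]] = {}
    for j, cls in enumerate(classes):
        pos = y == cls
        per_auroc[cls] = auroc(pooled[:, j], pos)
        per_auprc[cls] = auprc(pooled[:, j], pos)
        if fold_of is not None:
            vals = []
            for f in range(k):
                m = fold_of == f
                if pos[m].any() and (~pos[m]).any():
                    vals.append(auroc(pooled[m, j], pos[m]))
                else:
                    vals.append(float("nan"))
            fold_scores[cls] = vals
    return EvalResult(
        per_auroc,
        per_auprc,
        float(np.mean(list(per_auroc.values()))),
        float(np.mean(list(per_auprc.values()))),
        fold_scores,
        run_log,
    )


def _featurize(cohort: Cohort, config) -> tuple[FeatureMatrix | None, FeatureMatrix | None, dict]:
    """Bag-of-features and/or transductive patient embeddings per the config."""
    import time

    log_entries: dict = {}
    fams = frozenset(config.families)
    work = restrict_families(cohort, fams)
    representation = Provenance(config.representation)
    bof = emb = None
    if representation in (Provenance.BOF, Provenance.FUSED):
        t0 = time.perf_counter()
        bof = bag_of_features(work, fams)
        log_entries["bag_of_features"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "n_features": bof.n_features,
        }
    if representation in (Provenance.N2V, Provenance.FUSED):
        t0 = time.perf_counter()
        graph = cohort_to_graph(
            work, include_demographics=feat.Family.DEMOGRAPHICS in fams
        )
        log_entries["graph"] = {"n_nodes": graph.n_nodes, "n_edges": graph.n_edges}
        emb = _embed_cached(work, graph, config)
        log_entries["embedding"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "dimension": config.embedding.dimension,
        }
    return bof, emb, log_entries


# embeddings are label-free, so they may be cached across pipeline runs that
# share the cohort, family set and embedding hyperparameters
_EMB_CACHE: dict[tuple, FeatureMatrix] = {}
_EMB_CACHE_MAX = 4


def _embed_cached(work: Cohort, graph, config) -> FeatureMatrix:
    key = (work.fingerprint(), tuple(sorted(f.value for f in config.families)),
           config.embedding)
    if getattr(config, "cache", True) and key in _EMB_CACHE:
        return _EMB_CACHE[key].rows(work.patient_ids)
    emb = embed_patients(graph, config.embedding, patient_order=list(work.patient_ids))
    if getattr(config, "cache", True):
        if len(_EMB_CACHE) >= _EMB_CACHE_MAX:
            _EMB_CACHE.pop(next(iter(_EMB_CACHE)))
        _EMB_CACHE[key] = emb
    return emb


def _fold_matrices(
    bof: FeatureMatrix | None,
    emb: FeatureMatrix | None,
    ids: Sequence[str],
    selected_names: Sequence[str] | None,
) -> FeatureMatrix:
    parts = []
    if bof is not None:
        m = bof.rows(ids)
        if selected_names is not None:
            m = m.select(selected_names)
        parts.append(m)
    if emb is not None:
        parts.append(emb.rows(ids))
    if len(parts) == 1:
        return parts[0]
    return fuse(parts[0], parts[1])


def cross_validate(
    cohort: Cohort,
    pipeline_config,
    k: int | None = None,
    seed: int | None = None,
) -> EvalResult:
    """k-fold cross-validation of the configured pipeline over a labelled cohort.

    Target-cancer condition records are stripped and the optional time window
    applied before featurization.  Information-gain selection (bag-of-features
    columns only) and classifier fitting happen inside each training fold;
    embeddings are transductive and label-free.  Metrics are one-vs-rest,
    pooled over held-out scores.
    """
    config = pipeline_config
    k = config.cv_k if k is None else k
    seed = config.seed if seed is None else seed
    work = strip_target_records(cohort)
    if getattr(config, "time_window", None) is not None:
        work = time_window_filter(work, config.time_window)
    label_map = work.label_codes()
    ids = [p for p in work.patient_ids if p in label_map]
    if len(ids) < len(work.patient_ids):
        log.info("ignoring %d unlabelled patients", len(work.patient_ids) - len(ids))
    work = work.subset(ids)
    y = np.asarray([label_map[p] for p in ids])
    class_counts = Counter(y.tolist())
    if min(class_counts.values()) < 2:
        raise ValueError(f"classes with <2 members: {class_counts}")
    classes = sorted(class_counts)
    folds = assign_folds(ids, k, seed, labels=label_map)
    bof, emb, run_log = _featurize(work, config)
    run_log["n_patients"] = len(ids)
    run_log["k"] = k

    pooled = np.zeros((len(ids), len(classes)))
    fold_of = np.asarray([folds.assignment[p] for p in ids])
    id_pos = {p: i for i, p in enumerate(ids)}
    for f in range(k):
        test_ids = [p for p in ids if folds.assignment[p] == f]
        train_ids = [p for p in ids if folds.assignment[p] != f]
        y_train = {p: label_map[p] for p in train_ids}
        selected = None
        if bof is not None:
            sel = select_features(bof.rows(train_ids), y_train, config.d_select)
            selected = sel.feature_names
        m_train = _fold_matrices(bof, emb, train_ids, selected)
        model = train_classifier(m_train, y_train, config.classifier)
        m_test = _fold_matrices(bof, emb, test_ids, selected)
        scores = model.predict_scores(m_test)
        col = {c: j for j, c in enumerate(scores.class_order)}
        for i, p in enumerate(test_ids):
            for j, cls in enumerate(classes):
                if cls in col:
                    pooled[id_pos[p], j] = scores.scores[i, col[cls]]
    run_log["pooled_scores"] = {
        "patient_ids": list(ids),
        "classes": list(classes),
        "matrix": pooled,
    }
    return _result_from_scores(classes, pooled, y, fold_of, k, run_log)


# ---------------------------------------------------------------------------
# time-window ablation


@dataclass(frozen=True)
class TimeWindowSpec:
    """Look-back horizon: keep time-dependent records at least ``months_before``
    months before each patient's diagnosis date."""

    months_before: int = 0

    def __post_init__(self) -> None:
        if self.months_before < 0:
            raise ValueError("months_before must be >= 0")


def time_window_filter(cohort: Cohort, spec: TimeWindowSpec) -> Cohort:
    """Drop condition/medication/lab records dated after diagnosis - horizon.

    Genetics, family history and demographics are untouched.  A month is a
    30.44-day interval anchored at the diagnosis date.  Raises on patients
    without a diagnosis date.
    """
    cutoff_delta = dt.timedelta(days=round(spec.months_before * DAYS_PER_MONTH))
    bundles = []
    for b in cohort.bundles:
        label = cohort.labels.get(b.patient_id)
        if label is None:
            raise ValueError(
                f"patient {b.patient_id} has no diagnosis date for time filtering"
            )
        cutoff = label.diagnosis_date - cutoff_delta
        bundles.append(
            replace(
                b,
                conditions=tuple(
                    r for r in b.conditions if r.recorded_date <= cutoff
                ),
                medications=tuple(
                    r for r in b.medications if r.recorded_date <= cutoff
                ),
                labs=tuple(r for r in b.labs if r.effective_date <= cutoff),
            )
        )
    return Cohort(tuple(bundles), dict(cohort.labels))


# ---------------------------------------------------------------------------
# cancer of unknown primary


def cup_evaluate(train_cohort: Cohort, cup_cohort: Cohort, pipeline_config) -> EvalResult:
    """Train once on the training cohort, score the unknown-primary cohort.

    CUP classes unseen in training are skipped with a warning, as are classes
    lacking both polarities among CUP patients.  For embedding representations
    the graph is built over the union of both cohorts (transductive, label-free).
    """
    config = pipeline_config
    fams = frozenset(config.families)
    train = restrict_families(strip_target_records(train_cohort), fams)
    cup = restrict_families(strip_target_records(cup_cohort), fams)
    overlap = set(train.patient_ids) & set(cup.patient_ids)
    if overlap:
        raise ValueError(f"cohorts share patient ids: {sorted(overlap)[:5]}")
    train_labels = train.label_codes()
    cup_labels = cup.label_codes()
    representation = Provenance(config.representation)

    bof_train = bof_cup = emb_train = emb_cup = None
    if representation in (Provenance.BOF, Provenance.FUSED):
        bof_train = bag_of_features(train, fams)
        bof_cup = bag_of_features(cup, fams, vocabulary=bof_train.feature_names)
    if representation in (Provenance.N2V, Provenance.FUSED):
        union = Cohort(train.bundles + cup.bundles, {**train.labels, **cup.labels})
        graph = cohort_to_graph(
            union, include_demographics=feat.Family.DEMOGRAPHICS in fams
        )
        emb_all = embed_patients(
            graph, config.embedding, patient_order=list(union.patient_ids)
        )
        emb_train = emb_all.rows(train.patient_ids)
        emb_cup = emb_all.rows(cup.patient_ids)

    selected = None
    if bof_train is not None:
        sel = select_features(bof_train, train_labels, config.d_select)
        selected = sel.feature_names
    m_train = _fold_matrices(bof_train, emb_train, list(train.patient_ids), selected)
    model = train_classifier(m_train, train_labels, config.classifier)
    m_cup = _fold_matrices(bof_cup, emb_cup, list(cup.patient_ids), selected)
    scores = model.predict_scores(m_cup)

    y = np.asarray([cup_labels[p] for p in cup.patient_ids])
    unseen = sorted(set(y) - set(model.class_order))
    if unseen:
        warnings.warn(f"CUP classes unseen in training skipped: {unseen}", stacklevel=2)
    per_auroc: dict[str, float] = {}
    per_auprc: dict[str, float] = {}
    for cls in sorted(set(y) & set(model.class_order)):
        pos = y == cls
        if not pos.any() or pos.all():
            warnings.warn(f"class {cls}: metric undefined among CUP patients",
                          stacklevel=2)
            continue
        col = scores.column(cls)
        per_auroc[cls] = auroc(col, pos)
        per_auprc[cls] = auprc(col, pos)
    if not per_auroc:
        raise MetricError("no CUP class had both polarities; nothing to evaluate")
    return EvalResult(
        per_auroc,
        per_auprc,
        float(np.mean(list(per_auroc.values()))),
        float(np.mean(list(per_auprc.values()))),
        {},
        {"n_train": len(train.patient_ids), "n_cup": len(cup.patient_ids)},
    )


# ---------------------------------------------------------------------------
# Shapley feature attribution


@dataclass(frozen=True)
class AttributionResult:
    """Per-class feature contributions, sorted by descending |contribution|."""

    class_code: str
    contributions: tuple[tuple[str, float], ...]

    def top(self, n: int = 5) -> tuple[tuple[str, float], ...]:
        return self.contributions[:n]

    def feature_rank(self, name: str) -> int:
        for i, (f, _) in enumerate(self.contributions):
            if f == name:
                return i
        raise KeyError(name)


def _marginal_background(X: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample a background matrix from per-feature empirical marginals."""
    rows = rng.integers(0, X.shape[0], size=(n, X.shape[1]))
    return X[rows, np.arange(X.shape[1])]


def _shapley_exact(
    score, x: np.ndarray, background: np.ndarray
) -> np.ndarray:
    """Exact Shapley values by subset enumeration (features <= 16)."""
    import math

    f = x.size
    if f > 16:
        raise ValueError("exact enumeration limited to 16 features")
    n_masks = 1 << f
    b = background.shape[0]
    # value of every coalition: explicand features on mask, background elsewhere
    rows = np.empty((n_masks * b, f))
    for mask in range(n_masks):
        mix = background.copy()
        for j in range(f):
            if mask >> j & 1:
                mix[:, j] = x[j]
        rows[mask * b : (mask + 1) * b] = mix
    vals = score(rows).reshape(n_masks, b).mean(axis=1)
    phi = np.zeros(f)
    fact = [math.factorial(i) for i in range(f + 1)]
    for j in range(f):
        for mask in range(n_masks):
            if mask >> j & 1:
                continue
            s = bin(mask).count("1")
            w = fact[s] * fact[f - s - 1] / fact[f]
            phi[j] += w * (vals[mask | (1 << j)] - vals[mask])
    return phi


def _shapley_sampling(
    score, x: np.ndarray, background: np.ndarray, n_perms: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation-sampling Shapley estimate with one background draw per
    permutation; unbiased, cost (features+1) evaluations per permutation."""
    f = x.size
    rows = np.empty((n_perms * (f + 1), f))
    perms = np.empty((n_perms, f), dtype=np.int64)
    for p in range(n_perms):
        perm = rng.permutation(f)
        perms[p] = perm
        base = background[rng.integers(0, background.shape[0])].copy()
        block = rows[p * (f + 1) : (p + 1) * (f + 1)]
        block[0] = base
        cur = base
        for step, j in enumerate(perm, start=1):
            cur = cur.copy()
            cur[j] = x[j]
            block[step] = cur
    vals = score(rows).reshape(n_perms, f + 1)
    deltas = np.diff(vals, axis=1)  # contribution of the feature added at each step
    phi = np.zeros(f)
    for p in range(n_perms):
        phi[perms[p]] += deltas[p]
    return phi / n_perms


def feature_attribution(
    model: TrainedModel,
    matrix: FeatureMatrix,
    class_code: str,
    n_samples: int = 100,
    seed: int = 0,
    background: FeatureMatrix | np.ndarray | None = None,
    n_background: int = 100,
    exact: bool = False,
) -> AttributionResult:
    """Shapley attribution of the class score to features.

    Explains the model's probability for ``class_code`` on the rows of
    ``matrix`` (contributions averaged over rows, ranked by absolute value).
    The background distribution defaults to ``n_background`` samples from the
    per-feature marginals of ``matrix``.  ``exact=True`` enumerates all
    coalitions (<= 16 features), satisfying the efficiency property
    sum(phi) = f(x) - E_background[f] to float precision; otherwise a
    permutation-sampling estimate with ``n_samples`` permutations per row.
    """
    if matrix.feature_names != model.feature_names:
        raise ValueError("matrix columns do not match the model's manifest")
    if class_code not in model.class_order:
        raise ValueError(f"model does not score class {class_code!r}")
    rng = np.random.default_rng(seed)
    X = matrix.values
    if background is None:
        bg = _marginal_background(X, n_background, rng)
    elif isinstance(background, FeatureMatrix):
        bg = background.values
    else:
        bg = np.asarray(background, dtype=float)
    cls_idx = model.class_order.index(class_code)

    def score(rows: np.ndarray) -> np.ndarray:
        out = np.empty(rows.shape[0])
        for lo in range(0, rows.shape[0], 50000):
            out[lo : lo + 50000] = model.score_array(rows[lo : lo + 50000])[:, cls_idx]
        return out

    phis = []
    for i in range(X.shape[0]):
        if exact:
            phis.append(_shapley_exact(score, X[i], bg))
        else:
            phis.append(_shapley_sampling(score, X[i], bg, n_samples, rng))
    mean_phi = np.mean(phis, axis=0)
    order = np.argsort(-np.abs(mean_phi), kind="stable")
    contributions = tuple(
        (matrix.feature_names[j], float(mean_phi[j])) for j in order
    )
    return AttributionResult(class_code, contributions)
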