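"""Metrics against brute-force oracles, CV laws, time filtering, CUP and Shapley."""

import datetime as dt
import itertools

import numpy as np
import pytest

from graphonc import (
    Cohort,
    GeneratorConfig,
    PipelineConfig,
    Provenance,
    TimeWindowSpec,
    auprc,
    auroc,
    compare_models,
    cross_validate,
    cup_evaluate,
    feature_attribution,
    generate_cohort,
    generate_cup_cohort,
    time_window_filter,
)
from graphonc.classify import ClassifierSpec, TrainedModel
from graphonc.evaluate import (
    DegenerateComparisonError,
    MetricError,
    assign_folds,
)
from graphonc.features import FeatureMatrix, Provenance as Prov

from .conftest import make_bundle, make_label

D = dt.date


# ---------------------------------------------------------------------------
# AUROC / AUPRC


def _auroc_bruteforce(scores, labels):
    """O(n^2) pair-counting oracle: P(s+ > s-) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1 for p in pos for n in neg if p > n)
    ties = sum(1 for p in pos for n in neg if p == n)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_ranking(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_four_point_case(self):
        scores, labels = [0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]
        assert auroc(scores, labels) == pytest.approx(
            _auroc_bruteforce(scores, labels)
        )

    def test_random_instances_match_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 6, n) / 5.0  # ties likely
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auroc(scores, labels) == pytest.approx(
                _auroc_bruteforce(scores, labels), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        assert auroc(scores, labels) == pytest.approx(
            auroc(np.exp(5 * scores), labels)
        )

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            auroc([0.1, 0.2], [1, 1])


def _auprc_bruteforce(scores, labels):
    """Hand-stepped PR curve: sum of precision at each recall increment."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    tp = fp = 0
    total_pos = y.sum()
    ap = 0.0
    for yi in y:
        if yi:
            tp += 1
            ap += tp / (tp + fp) / total_pos
        else:
            fp += 1
    return ap


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_four_point_manual_table(self):
        # ranked: 1, 0, 1, 0 -> precisions at hits: 1/1 and 2/3; AP = 5/6
        assert auprc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(5 / 6)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(2)
        n, prevalence = 20000, 0.15
        labels = rng.random(n) < prevalence
        got = auprc(rng.random(n), labels)
        assert got == pytest.approx(prevalence, abs=0.02)

    def test_random_instances_match_stepped_curve(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(4, 25))
            scores = rng.random(n)  # distinct scores: step curve is exact
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                labels[0] = 1
            assert auprc(scores, labels) == pytest.approx(
                _auprc_bruteforce(scores, labels), abs=1e-10
            )

    def test_no_positives_rejected(self):
        with pytest.raises(MetricError):
            auprc([0.5, 0.4], [0, 0])


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _wilcoxon_enumeration(d):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    total = n * (n + 1) / 2
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_low = (ws <= w_obs).mean()
    p_high = (ws >= w_obs).mean()
    return min(1.0, 2 * min(p_low, p_high))


class TestCompareModels:
    def test_identical_inputs_degenerate(self):
        with pytest.raises(DegenerateComparisonError):
            compare_models([0.9] * 6, [0.9] * 6)

    def test_six_positive_differences_exact(self):
        a = [0.91, 0.92, 0.93, 0.94, 0.95, 0.96]
        b = [0.90, 0.90, 0.90, 0.90, 0.90, 0.90]
        assert compare_models(a, b) == pytest.approx(2 * (1 / 2**6))

    def test_exact_matches_sign_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(60):
            n = int(rng.integers(5, 11))
            d = rng.normal(0.3, 1.0, n)
            while len(np.unique(np.abs(d))) < n or (d == 0).any():
                d = rng.normal(0.3, 1.0, n)
            b = rng.random(n)
            assert compare_models(b + d, b) == pytest.approx(
                _wilcoxon_enumeration(d), abs=1e-12
            )

    def test_exact_matches_scipy(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(5)
        for _ in range(20):
            n = 12
            d = rng.normal(0.2, 1.0, n)
            p_ours = compare_models(d, np.zeros(n))
            p_scipy = scipy_wilcoxon(d, method="exact").pvalue
            assert p_ours == pytest.approx(p_scipy, abs=1e-10)

    def test_exact_vs_normal_approximation_at_25(self):
        rng = np.random.default_rng(6)
        n = 25
        d = rng.normal(0.3, 1.0, n)
        p_exact = compare_models(d, np.zeros(n))
        # push the same data through the approximation by growing n past 25
        from graphonc.evaluate import compare_models as cm

        d26 = np.append(d, 1e-7)  # one extra tiny difference
        p_approx = cm(d26, np.zeros(26))
        assert p_exact == pytest.approx(p_approx, abs=0.01)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            compare_models([1, 2], [0, 0])


# ---------------------------------------------------------------------------
# fold assignment and cross-validation


class TestFolds:
    def test_partition_law_and_balance(self):
        ids = [f"P{i}" for i in range(23)]
        folds = assign_folds(ids, 5, seed=0)
        sizes = [len(folds.fold_ids(f)) for f in range(5)]
        assert sum(sizes) == 23
        assert max(sizes) - min(sizes) <= 1
        assert set(folds.assignment) == set(ids)

    def test_leave_one_out_partition(self):
        ids = [f"P{i}" for i in range(12)]
        folds = assign_folds(ids, 12, seed=1)
        assert sorted(len(folds.fold_ids(f)) for f in range(12)) == [1] * 12

    def test_stratified_fallback_warns(self):
        ids = [f"P{i}" for i in range(10)]
        labels = {p: ("a" if i < 2 else "b") for i, p in enumerate(ids)}
        with pytest.warns(UserWarning, match="stratified"):
            folds = assign_folds(ids, 5, seed=0, labels=labels)
        # the rare class lands in different folds
        assert len({folds.assignment["P0"], folds.assignment["P1"]}) == 2


def _quick_config(**kw):
    seed = kw.pop("seed", 0)
    defaults = dict(
        representation=Provenance.BOF,
        d_select=40,
        cv_k=3,
        classifier=ClassifierSpec(hyperparameters={"n_estimators": 80}),
    )
    defaults.update(kw)
    return PipelineConfig(**defaults).with_seed(seed)


@pytest.fixture(scope="module")
def planted_cohort():
    return generate_cohort(
        GeneratorConfig(n_per_class=15, classes=("153.9", "185", "155"), seed=8)
    )


class TestCrossValidate:
    def test_deterministic(self, planted_cohort):
        cfg = _quick_config()
        r1 = cross_validate(planted_cohort, cfg)
        r2 = cross_validate(planted_cohort, cfg)
        assert r1.per_class_auroc == r2.per_class_auroc
        assert r1.fold_scores == r2.fold_scores

    def test_macro_is_unweighted_mean(self, planted_cohort):
        r = cross_validate(planted_cohort, _quick_config())
        assert r.macro_auroc == pytest.approx(
            np.mean(list(r.per_class_auroc.values()))
        )
        assert set(r.per_class_auroc) == {"153.9", "185", "155"}
        assert all(0 <= v <= 1 for v in r.per_class_auroc.values())

    def test_planted_beats_null(self, planted_cohort):
        from graphonc import SignalSpec

        null = generate_cohort(
            GeneratorConfig(n_per_class=15, classes=("153.9", "185", "155"), seed=9),
            SignalSpec.null(),
        )
        cfg = _quick_config()
        assert (
            cross_validate(planted_cohort, cfg).macro_auroc
            > cross_validate(null, cfg).macro_auroc
        )

    def test_held_out_score_ignores_own_label(self, planted_cohort):
        """Leakage guard: flipping one patient's label cannot change the score
        that patient receives, because the model scoring it never saw it."""
        cfg = _quick_config()
        r1 = cross_validate(planted_cohort, cfg)
        victim = planted_cohort.patient_ids[0]
        flipped_labels = dict(planted_cohort.labels)
        old = flipped_labels[victim].cancer.code
        new_code = "185" if old != "185" else "155"
        flipped_labels[victim] = make_label(
            victim, new_code, flipped_labels[victim].diagnosis_date
        )
        flipped = Cohort(planted_cohort.bundles, flipped_labels)
        r2 = cross_validate(flipped, cfg)
        row1 = r1.run_log["pooled_scores"]
        row2 = r2.run_log["pooled_scores"]
        i1 = row1["patient_ids"].index(victim)
        i2 = row2["patient_ids"].index(victim)
        assert (row1["matrix"][i1] == row2["matrix"][i2]).all()

    def test_class_with_single_member_rejected(self):
        bundles = tuple(make_bundle(f"P{i}") for i in range(6))
        labels = {f"P{i}": make_label(f"P{i}", "185") for i in range(5)}
        labels["P5"] = make_label("P5", "193")
        with pytest.raises(ValueError, match="<2"):
            cross_validate(Cohort(bundles, labels), _quick_config(cv_k=2))


class TestTimeWindowFilter:
    def _cohort(self, months_ago):
        date = D(2020, 12, 1) - dt.timedelta(days=round(months_ago * 30.44))
        b = make_bundle("P1", conditions=("401.9",), medications=("5956",),
                        genes=("TP53",), date=date)
        return Cohort((b,), {"P1": make_label("P1", "185", D(2020, 12, 1))})

    def test_recent_record_removed(self):
        out = time_window_filter(self._cohort(5), TimeWindowSpec(6))
        assert out.bundles[0].conditions == ()
        assert out.bundles[0].medications == ()

    def test_old_record_kept(self):
        out = time_window_filter(self._cohort(5), TimeWindowSpec(3))
        assert len(out.bundles[0].conditions) == 1

    def test_zero_horizon_drops_only_postdiagnosis(self):
        post = make_bundle("P1", conditions=("401.9",), date=D(2021, 1, 15))
        pre = make_bundle("P2", conditions=("401.9",), date=D(2020, 11, 1))
        cohort = Cohort(
            (post, pre),
            {"P1": make_label("P1", "185", D(2020, 12, 1)),
             "P2": make_label("P2", "185", D(2020, 12, 1))},
        )
        out = time_window_filter(cohort, TimeWindowSpec(0))
        assert out.bundles[0].conditions == ()
        assert len(out.bundles[1].conditions) == 1

    def test_genetics_always_retained(self):
        out = time_window_filter(self._cohort(0), TimeWindowSpec(24))
        assert len(out.bundles[0].genetics) == 1

    def test_unlabelled_patient_rejected(self):
        cohort = Cohort((make_bundle("P1"),))
        with pytest.raises(ValueError, match="P1"):
            time_window_filter(cohort, TimeWindowSpec(0))


class TestCupEvaluate:
    def test_training_subset_scores_near_perfect(self, planted_cohort):
        # a CUP cohort drawn from the same planted distribution (suppression 0)
        cup = generate_cup_cohort(
            GeneratorConfig(n_per_class=10, classes=("153.9", "185", "155"), seed=10),
            suppression=0.0,
        )
        r = cup_evaluate(planted_cohort, cup, _quick_config())
        assert r.macro_auroc > 0.8

    def test_degradation_with_suppression(self, planted_cohort):
        cfg = _quick_config()
        gens = {
            s: generate_cup_cohort(
                GeneratorConfig(
                    n_per_class=10, classes=("153.9", "185", "155"), seed=11
                ),
                suppression=s,
            )
            for s in (0.0, 1.0)
        }
        r0 = cup_evaluate(planted_cohort, gens[0.0], cfg)
        r1 = cup_evaluate(planted_cohort, gens[1.0], cfg)
        assert r0.macro_auroc > r1.macro_auroc

    def test_single_polarity_class_skipped(self, planted_cohort):
        cup = generate_cup_cohort(
            GeneratorConfig(n_per_class=8, classes=("153.9",), seed=12),
            suppression=0.2,
        )
        with pytest.raises(MetricError):
            # only one class present among CUP patients -> no OVR metric
            cup_evaluate(planted_cohort, cup, _quick_config())


# ---------------------------------------------------------------------------
# Shapley attribution


class _LinearStub:
    """Duck-typed TrainedModel scoring f(x) = sigmoid-free linear map."""

    def __init__(self, names, weights):
        self.feature_names = tuple(names)
        self.class_order = ("pos", "neg")
        self.weights = np.asarray(weights, dtype=float)

    def score_array(self, X):
        raw = X @ self.weights
        return np.column_stack([raw, 1 - raw])


def _fm(values, names):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(
        tuple(f"P{i}" for i in range(values.shape[0])),
        tuple(names), values, (Prov.BOF,) * len(names),
    )


class TestAttribution:
    def test_additive_model_closed_form(self):
        # linear model: phi_j = w_j * (x_j - mean(background_j)) exactly
        names = ("a", "b", "c")
        w = [0.5, -0.3, 0.0]
        model = _LinearStub(names, w)
        rng = np.random.default_rng(0)
        bg = rng.random((50, 3))
        x = np.array([[0.9, 0.1, 0.4]])
        res = feature_attribution(
            model, _fm(x, names), "pos", background=bg, exact=True
        )
        expected = {n: wi * (x[0, i] - bg[:, i].mean())
                    for i, (n, wi) in enumerate(zip(names, w))}
        for name, value in res.contributions:
            assert value == pytest.approx(expected[name], abs=1e-10)

    def test_null_feature_gets_zero(self):
        model = _LinearStub(("a", "b"), [1.0, 0.0])
        bg = np.random.default_rng(1).random((30, 2))
        res = feature_attribution(
            model, _fm([[0.7, 0.2]], ("a", "b")), "pos", background=bg, exact=True
        )
        assert dict(res.contributions)["b"] == pytest.approx(0.0, abs=1e-12)

    def test_efficiency_exact_mode(self, small_cohort):
        """sum(phi) = f(x) - E_bg[f] to 1e-6 on a 6-feature trained model."""
        from graphonc import bag_of_features, select_features, strip_target_records
        from graphonc.classify import train_classifier

        cohort = strip_target_records(small_cohort)
        labels = cohort.label_codes()
        m = select_features(bag_of_features(cohort), labels, 6)
        model = train_classifier(
            m, labels, ClassifierSpec(hyperparameters={"n_estimators": 50}, seed=0)
        )
        rng = np.random.default_rng(2)
        bg = m.values[rng.choice(len(m.patient_ids), 25, replace=False)]
        x = m.rows(m.patient_ids[:1])
        res = feature_attribution(model, x, "185", background=bg, exact=True)
        cls = model.class_order.index("185")
        f_x = model.score_array(x.values)[0, cls]
        f_bg = model.score_array(bg)[:, cls].mean()
        assert sum(v for _, v in res.contributions) == pytest.approx(
            f_x - f_bg, abs=1e-6
        )

    def test_sampling_approximates_exact(self):
        rng = np.random.default_rng(3)
        names = tuple("abcde")
        model = _LinearStub(names, rng.normal(size=5) * 0.3)
        bg = rng.random((40, 5))
        x = _fm(rng.random((1, 5)), names)
        exact = dict(
            feature_attribution(model, x, "pos", background=bg, exact=True).contributions
        )
        approx = dict(
            feature_attribution(
                model, x, "pos", background=bg, n_samples=400, seed=4
            ).contributions
        )
        for n in names:
            assert approx[n] == pytest.approx(exact[n], abs=0.03)

    def test_results_sorted_by_magnitude(self):
        model = _LinearStub(("a", "b"), [0.1, -0.9])
        bg = np.zeros((5, 2))
        res = feature_attribution(
            model, _fm([[1.0, 1.0]], ("a", "b")), "pos", background=bg, exact=True
        )
        mags = [abs(v) for _, v in res.contributions]
        assert mags == sorted(mags, reverse=True)
        assert res.contributions[0][0] == "b"
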