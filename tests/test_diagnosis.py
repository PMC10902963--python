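"""Diagnostic pipeline: splits, metric formulas vs brute-force oracles,
forward selection, binary-relevance fits and the diagnosis resolution rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthoplan.cohort import CohortSpec, DeformitySpec, synthesize_cohort
from orthoplan.diagnosis import (
    ConfusionCounts,
    DiagnosisConfig,
    DiagnosisError,
    DiagnosisModel,
    compute_metrics,
    fit_br,
    forward_select,
    predict,
    resolve_diagnosis,
    roc_auc,
    split_dataset,
    tune_hyperparams,
)
from orthoplan.registry import LABELS

FAST_CFG = DiagnosisConfig(n_estimators=30, selection_folds=2)


def _frame(n):
    return pd.DataFrame({"f": np.arange(n, dtype=float)})


class TestSplit:
    @pytest.mark.parametrize("n,expected", [(110, (70, 30, 10)), (11, (7, 3, 1)), (12, (8, 3, 1))])
    def test_largest_remainder_sizes(self, n, expected):
        parts = split_dataset(_frame(n), seed=0)
        assert tuple(len(p) for p in parts) == expected

    def test_partition_is_disjoint_exhaustive_reproducible(self):
        data = _frame(97)
        a = split_dataset(data, seed=42)
        b = split_dataset(data, seed=42)
        ids = np.concatenate([p["f"].to_numpy() for p in a])
        assert sorted(ids) == list(range(97))
        assert len(set(ids)) == 97
        for pa, pb in zip(a, b):
            pd.testing.assert_frame_equal(pa, pb)

    def test_too_small_rejected(self):
        with pytest.raises(DiagnosisError):
            split_dataset(_frame(10), seed=0)


def brute_force_metrics(tp, fp, tn, fn):
    """Independent evaluation of the metric formulas by explicit counting
    over a reconstructed prediction list."""
    y = [1] * tp + [0] * fp + [0] * tn + [1] * fn
    p = [1] * tp + [1] * fp + [0] * tn + [0] * fn
    n = len(y)
    correct = sum(yi == pi for yi, pi in zip(y, p))
    pos_pred = sum(p)
    pos_true = sum(y)
    neg_true = n - pos_true
    out = {"accuracy": correct / n}
    out["precision"] = (tp / pos_pred) if pos_pred else 0.0
    out["recall"] = (tp / pos_true) if pos_true else 0.0
    out["specificity"] = (tn / neg_true) if neg_true else 0.0
    pr = out["precision"] + out["recall"]
    out["f1"] = 2 * out["precision"] * out["recall"] / pr if pr else 0.0
    return out


class TestMetrics:
    def test_reference_confusion_table(self):
        rep = compute_metrics(ConfusionCounts(tp=45, fp=5, tn=40, fn=10))
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.precision == pytest.approx(0.9)
        assert rep.recall == pytest.approx(0.8182, abs=1e-4)
        assert rep.specificity == pytest.approx(0.8889, abs=1e-4)
        assert rep.f1 == pytest.approx(0.8571, abs=1e-4)

    def test_perfect_classifier(self):
        rep = compute_metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert (rep.accuracy, rep.precision, rep.recall, rep.specificity, rep.f1) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_degenerate_precision_flagged(self):
        rep = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert rep.precision == 0.0
        assert "precision" in rep.degenerate

    def test_empty_table_rejected(self):
        with pytest.raises(DiagnosisError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_matches_brute_force_oracle_on_random_tables(self, rng):
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 30, size=4)
            if tp + fp + tn + fn == 0:
                continue
            rep = compute_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            oracle = brute_force_metrics(int(tp), int(fp), int(tn), int(fn))
            for key, value in oracle.items():
                assert getattr(rep, key) == pytest.approx(value, abs=1e-12), key


def pair_counting_auc(y, s):
    """AUC as the tie-corrected fraction of correctly ordered
    positive-negative pairs."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_full_tie(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_reference_pairs(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.5, 0.1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(DiagnosisError):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])

    @given(
        labels=st.lists(st.integers(0, 1), min_size=4, max_size=20),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_pair_counting_oracle(self, labels, data):
        if len(set(labels)) < 2:
            return
        scores = data.draw(
            st.lists(
                st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.5, 0.75, 1.0]),
                min_size=len(labels),
                max_size=len(labels),
            )
        )
        assert roc_auc(labels, scores) == pytest.approx(
            pair_counting_auc(labels, scores), abs=1e-12
        )


def _threshold_dataset(n, seed, duplicate=False):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {f"f{i}": rng.normal(size=n) for i in range(1, 11)},
    )
    y = (X["f1"] > 0.0).astype(int).to_numpy()
    if duplicate:
        X["f1_copy"] = X["f1"]
    return X, y


class TestForwardSelect:
    def test_informative_feature_retained(self):
        X, y = _threshold_dataset(500, seed=3)
        subset = forward_select(X, y, folds=3, seed=0, config=FAST_CFG)
        assert "f1" in subset
        assert 1 <= len(subset) <= X.shape[1]

    def test_duplicated_feature_not_retained_twice(self):
        X, y = _threshold_dataset(500, seed=3, duplicate=True)
        subset = forward_select(X, y, folds=3, seed=0, config=FAST_CFG)
        assert len({"f1", "f1_copy"} & set(subset)) <= 1
        assert {"f1", "f1_copy"} & set(subset)

    def test_single_class_rejected(self):
        X, _ = _threshold_dataset(50, seed=0)
        with pytest.raises(DiagnosisError):
            forward_select(X, np.zeros(50, dtype=int), folds=2, seed=0, config=FAST_CFG)


@pytest.fixture(scope="module")
def small_cohort():
    return synthesize_cohort(CohortSpec(n=180, seed=7), DeformitySpec(noise_sd_mm=0.0))


class TestBinaryRelevance:
    def test_separable_cohort_validates_well(self, small_cohort):
        model = DiagnosisModel(small_cohort.data, config=FAST_CFG)
        results = model.fit(seed=0)
        for label, acc in results.br.validation_accuracy.items():
            assert acc >= 0.95, label

    def test_refit_identical_predictions(self, small_cohort):
        model = DiagnosisModel(small_cohort.data, config=FAST_CFG)
        r1, r2 = model.fit(seed=1), model.fit(seed=1)
        l1, p1 = r1.predict(small_cohort.data)
        l2, p2 = r2.predict(small_cohort.data)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(p1, p2)

    def test_feature_column_permutation_invariance(self, small_cohort):
        data = small_cohort.data
        model = DiagnosisModel(data, config=FAST_CFG)
        results = model.fit(seed=2)
        shuffled = data[list(reversed(data.columns))]
        l1, p1 = results.predict(data)
        l2, p2 = results.predict(shuffled)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(p1, p2)

    def test_probability_tie_resolves_positive(self, small_cohort):
        train, validation, _ = split_dataset(small_cohort.data, seed=0)
        features = [c for c in train.columns if c not in LABELS + ("patient_id", "sex")]
        br = fit_br(train, validation, features, config=FAST_CFG, seed=0)

        class Half:
            def predict_proba(self, X):
                return np.column_stack([np.full(len(X), 0.5), np.full(len(X), 0.5)])

        label = br.labels[0]
        br.classifiers[label] = Half()
        br.selected_features[label] = features[:1]
        labels, probs = predict(br, train.head(3))
        assert np.all(labels[:, 0] == 1)
        np.testing.assert_allclose(probs[:, 0], 0.5)

    def test_missing_feature_named(self, small_cohort):
        model = DiagnosisModel(small_cohort.data, config=FAST_CFG)
        results = model.fit(seed=0)
        needed = next(iter(results.br.selected_features.values()))[0]
        broken = small_cohort.data.drop(columns=[needed])
        with pytest.raises(DiagnosisError, match=needed):
            results.predict(broken)

    def test_degenerate_label_named(self, small_cohort):
        data = small_cohort.data.copy()
        data["maxillary_deviation"] = 0
        train, validation, _ = split_dataset(data, seed=0)
        features = ["SNA", "SNB"]
        with pytest.raises(DiagnosisError, match="maxillary_deviation"):
            fit_br(train, validation, features, config=FAST_CFG, seed=0)


class TestResolveDiagnosis:
    def test_simple_positive(self):
        out = resolve_diagnosis([1, 0, 0, 0, 0, 0])
        assert out["maxilla"]["development"] == "over"
        assert out["mandible"]["development"] == "normal"

    def test_conflict_resolved_by_probability(self):
        out = resolve_diagnosis([1, 1, 0, 0, 0, 0], [0.9, 0.6, 0.1, 0.1, 0.1, 0.1])
        assert out["maxilla"]["development"] == "over"
        out = resolve_diagnosis([1, 1, 0, 0, 0, 0], [0.6, 0.9, 0.1, 0.1, 0.1, 0.1])
        assert out["maxilla"]["development"] == "under"

    def test_all_negative_is_normal(self):
        out = resolve_diagnosis([0] * 6)
        assert out == {
            "maxilla": {"development": "normal", "deviation": False},
            "mandible": {"development": "normal", "deviation": False},
        }


class TestTuneHyperparams:
    space = {"n_estimators": [20, 40], "max_depth": [2, 3]}

    def test_zero_budget_returns_defaults(self, small_cohort):
        cfg = DiagnosisConfig()
        out = tune_hyperparams(pd.DataFrame({"f": [1.0, 2.0]}), [0, 1], self.space, 0, config=cfg)
        assert out == {
            "learner": cfg.learner,
            "n_estimators": cfg.n_estimators,
            "max_depth": cfg.max_depth,
            "learning_rate": cfg.learning_rate,
            "selection_folds": cfg.selection_folds,
            "threshold": cfg.threshold,
        }

    def test_result_in_space_and_deterministic(self, small_cohort):
        data = small_cohort.data
        X = data[["SNA", "SNB", "Pog_MSP"]]
        y = data["maxillary_overdevelopment"]
        a = tune_hyperparams(X, y, self.space, budget=3, folds=2, seed=5, config=FAST_CFG)
        b = tune_hyperparams(X, y, self.space, budget=3, folds=2, seed=5, config=FAST_CFG)
        assert a == b
        assert a["n_estimators"] in self.space["n_estimators"]
        assert a["max_depth"] in self.space["max_depth"]

    def test_empty_space_rejected(self):
        with pytest.raises(DiagnosisError):
            tune_hyperparams(pd.DataFrame({"f": [1.0]}), [1], {}, budget=2)
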