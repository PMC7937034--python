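import numpy as np
import pytest

import funlink as fl
from funlink.classifier import (
    FunctionalAssociationResults,
    GoldInteraction,
    _sens_spec,
)
from funlink.errors import CapacityError, LeakageError, SchemaError, ValidationError
from funlink.evidence import FeatureMatrix


def make_fm(X, names=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = names or [f"f{j}" for j in range(X.shape[1])]
    pairs = [(f"a{i}", f"b{i}") for i in range(X.shape[0])]
    return FeatureMatrix(pairs, X, names)


class TestGoldFilter:
    @pytest.mark.parametrize(
        "n_studies,low_tp,kept",
        [(1, False, False), (2, False, True), (1, True, True), (3, True, True)],
    )
    def test_filter_branches(self, n_studies, low_tp, kept):
        gi = GoldInteraction("a", "b", n_studies, low_tp)
        assert (fl.filter_gold_positives([gi]) == [gi]) is kept

    def test_order_preserved(self):
        gis = [GoldInteraction("a", "b", 2), GoldInteraction("c", "d", 1, True),
               GoldInteraction("e", "f", 1)]
        assert fl.filter_gold_positives(gis) == gis[:2]

    def test_self_pair_rejected(self):
        with pytest.raises(ValidationError):
            GoldInteraction("a", "a", 2)


class TestSampleNegatives:
    def test_ratio_zero_gives_empty_set(self):
        assert fl.sample_negatives({"a", "b", "c"}, {("a", "b")}, 0, seed=1) == set()

    def test_exact_count_no_positives_no_self_pairs(self):
        genes = {f"g{i}" for i in range(40)}
        pos = {("g0", "g1"), ("g2", "g3")}
        neg = fl.sample_negatives(genes, pos, 50, seed=3)
        assert len(neg) == 100
        assert not neg & pos
        assert all(a != b for a, b in neg)
        assert all(a < b for a, b in neg)

    def test_seed_reproducibility(self):
        genes = {f"g{i}" for i in range(30)}
        pos = {("g0", "g1")}
        a = fl.sample_negatives(genes, pos, 20, seed=5)
        b = fl.sample_negatives(genes, pos, 20, seed=5)
        c = fl.sample_negatives(genes, pos, 20, seed=6)
        assert a == b
        assert a != c

    def test_dense_regime_exhausts_capacity_exactly(self):
        genes = {"a", "b", "c", "d"}  # 6 pairs, 1 positive -> 5 available
        neg = fl.sample_negatives(genes, {("a", "b")}, 5, seed=0)
        assert len(neg) == 5

    def test_infeasible_request_raises(self):
        with pytest.raises(CapacityError):
            fl.sample_negatives({"a", "b", "c"}, {("a", "b")}, 10, seed=0)


class TestHarmonicMean:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [(1.0, 0.0, 0.0), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0), (0.8, 0.6, 0.6857)],
    )
    def test_values(self, sens, spec, expected):
        assert fl.harmonic_mean_sens_spec(sens, spec) == pytest.approx(expected, abs=1e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fl.harmonic_mean_sens_spec(1.2, 0.5)


def separable_data(seed=0, n_pos=40, n_neg=400, gap=6.0):
    rng = np.random.default_rng(seed)
    Xp = rng.normal(gap, 1.0, size=(n_pos, 3))
    Xn = rng.normal(0.0, 1.0, size=(n_neg, 3))
    X = np.vstack([Xp, Xn])
    y = np.array([1] * n_pos + [0] * n_neg)
    return fl.LabeledPairSet(make_fm(X), y)


SMALL_GRID = dict(sigma_grid=(0.5, 2.0), c_grid=(1.0, 10.0), folds=3)


class TestTrain:
    def test_separable_classes_reach_high_harmonic_mean(self):
        res = fl.train(separable_data(), fl.TrainingConfig(seed=1, **SMALL_GRID))
        assert res.cv_harmonic_mean >= 0.95

    def test_shuffled_labels_fail_to_learn(self):
        data = separable_data(seed=2)
        rng = np.random.default_rng(2)
        shuffled = fl.LabeledPairSet(data.features, rng.permutation(data.labels))
        res = fl.train(shuffled, fl.TrainingConfig(seed=2, **SMALL_GRID))
        assert res.cv_sensitivity < 0.3  # chance-level at 1:10 imbalance

    def test_fixed_seed_gives_identical_hyperparameters(self):
        data = separable_data(seed=3)
        r1 = fl.train(data, fl.TrainingConfig(seed=7, **SMALL_GRID))
        r2 = fl.train(data, fl.TrainingConfig(seed=7, **SMALL_GRID))
        assert (r1.sigma, r1.c) == (r2.sigma, r2.c)
        assert r1.cv_table.equals(r2.cv_table)

    def test_grid_order_invariance(self):
        data = separable_data(seed=4)
        fwd = fl.TrainingConfig(sigma_grid=(0.5, 2.0), c_grid=(1.0, 10.0),
                                folds=3, seed=5)
        rev = fl.TrainingConfig(sigma_grid=(2.0, 0.5), c_grid=(10.0, 1.0),
                                folds=3, seed=5)
        r1, r2 = fl.train(data, fwd), fl.train(data, rev)
        assert (r1.sigma, r1.c) == (r2.sigma, r2.c)

    def test_single_class_data_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValidationError):
            fl.FunctionalAssociationSVM(
                fl.LabeledPairSet(make_fm(X), np.ones(10, dtype=int))
            )

    def test_too_few_minority_members_for_folds_rejected(self):
        X = np.zeros((10, 2))
        y = np.array([1, 1] + [0] * 8)
        with pytest.raises(ValidationError):
            fl.FunctionalAssociationSVM(
                fl.LabeledPairSet(make_fm(X), y),
                fl.TrainingConfig(folds=5),
            )


class _StubModel:
    """Deterministic decision function for contract tests."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)

    def decision_function(self, X):
        return self.values[: len(X)]


def stub_results(values, names=("f0",), training_pairs=frozenset()):
    import pandas as pd

    return FunctionalAssociationResults(
        model=_StubModel(values), sigma=1.0, c=1.0,
        selected_features=list(names),
        cv_table=pd.DataFrame([{"sigma": 1.0, "C": 1.0, "cv_sensitivity": 1.0,
                                "cv_specificity": 1.0, "cv_harmonic_mean": 1.0}]),
        cv_sensitivity=1.0, cv_specificity=1.0,
        apparent_sensitivity=1.0, apparent_specificity=1.0,
        training_pairs=training_pairs, config=fl.TrainingConfig(),
    )


class TestPredict:
    def test_confidence_is_margin_clipped_decision_value(self):
        res = stub_results([2.3, -0.4, 0.0])
        fm = make_fm(np.zeros((3, 1)), names=["f0"])
        calls = res.predict(fm)
        assert [(hit, pytest.approx(conf)) for _, hit, conf in calls] == [
            (True, pytest.approx(1.0)),
            (False, pytest.approx(0.4)),
            (False, pytest.approx(0.0)),
        ]

    def test_column_mismatch_raises_schema_error(self):
        res = stub_results([1.0], names=("f0",))
        with pytest.raises(SchemaError):
            res.predict(make_fm(np.zeros((1, 2)), names=["f0", "other"]))

    def test_ranking_recovers_planted_positives(self):
        data = separable_data(seed=9, n_pos=30, n_neg=300)
        res = fl.train(data, fl.TrainingConfig(seed=9, **SMALL_GRID))
        d = res.decision_values(data.features)
        assert fl.roc_auc(d, data.labels) > 0.9


class TestExternalValidate:
    def test_all_positive_predictor(self):
        res = stub_results([5.0] * 4)
        held = fl.LabeledPairSet(make_fm(np.zeros((4, 1)), names=["f0"]),
                                 np.array([1, 1, 0, 0]))
        assert res.external_validate(held) == (1.0, 0.0)

    def test_all_negative_predictor(self):
        res = stub_results([-5.0] * 4)
        held = fl.LabeledPairSet(make_fm(np.zeros((4, 1)), names=["f0"]),
                                 np.array([1, 1, 0, 0]))
        assert res.external_validate(held) == (0.0, 1.0)

    def test_matches_brute_force_confusion_matrix(self):
        rng = np.random.default_rng(11)
        d = rng.normal(0, 1, 50)
        y = rng.integers(0, 2, 50)
        res = stub_results(d)
        held = fl.LabeledPairSet(make_fm(np.zeros((50, 1)), names=["f0"]), y)
        sens, spec = res.external_validate(held)
        pred = d > 0
        tp = np.sum((y == 1) & pred); fn = np.sum((y == 1) & ~pred)
        tn = np.sum((y == 0) & ~pred); fp = np.sum((y == 0) & pred)
        assert sens == pytest.approx(tp / (tp + fn))
        assert spec == pytest.approx(tn / (tn + fp))

    def test_overlap_with_training_raises_leakage(self):
        held_fm = make_fm(np.zeros((1, 1)), names=["f0"])
        res = stub_results([1.0], training_pairs=frozenset(held_fm.pairs))
        with pytest.raises(LeakageError):
            res.external_validate(fl.LabeledPairSet(held_fm, np.array([1])))


def test_sens_spec_empty_classes_are_zero():
    assert _sens_spec(np.array([1, 1]), np.array([True, False])) == (0.5, 0.0)
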