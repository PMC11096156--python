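"""Grading protocol: stratified splitting, tuning, metric derivation,
PCA reduction, backward feature selection, and the Model/Results API."""

import numpy as np
import pandas as pd
import pytest
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from pearloct.features import FAMILY_BLOCKS, N_FEATURES, feature_names
from pearloct.grading import (
    GRADES,
    FeatureTable,
    GradingError,
    LusterGrader,
    SearchSpace,
    SelectionMask,
    SplitSpec,
    evaluate,
    pca_reduce,
    repeated_experiment,
    sequential_select,
    split,
    tune_and_train,
)


def make_table(n_per_class: int, n_features: int = 8, sep: float = 6.0, seed: int = 0):
    """Gaussian blobs: one shifted mean per grade -> linearly separable."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, g in enumerate(GRADES):
        X.append(rng.normal(i * sep, 1.0, size=(n_per_class, n_features)))
        y += [g] * n_per_class
    return FeatureTable(np.vstack(X), np.array(y), [f"f{i}" for i in range(n_features)])


class StubModel:
    """Fixed-prediction classifier for metric arithmetic checks."""

    def __init__(self, predictions):
        self.predictions = np.asarray(predictions, dtype=object)

    def predict(self, X):
        return self.predictions


# ---------------------------------------------------------------------------
# split

def test_split_116_gives_92_24():
    table = make_table(29)
    train, test = split(table, SplitSpec(seed=0))
    assert (len(train), len(test)) == (92, 24)


def test_split_10_gives_8_2():
    rng = np.random.default_rng(0)
    table = FeatureTable(rng.normal(size=(10, 3)), np.array(list("AAAAABBBBB")), ["a", "b", "c"])
    train, test = split(table, SplitSpec(seed=1))
    assert (len(train), len(test)) == (8, 2)


def test_split_stratification_and_reproducibility():
    table = make_table(29)
    train, test = split(table, SplitSpec(seed=7))
    _, counts = np.unique(train.labels, return_counts=True)
    assert set(counts) <= {23, 24}
    train2, test2 = split(table, SplitSpec(seed=7))
    np.testing.assert_array_equal(train.matrix, train2.matrix)
    assert len(train) + len(test) == len(table)


def test_split_rejects_tiny_class():
    table = FeatureTable(np.zeros((5, 2)), np.array(["A", "A", "B", "B", "C"]), ["a", "b"])
    with pytest.raises(GradingError):
        split(table, SplitSpec())


# ---------------------------------------------------------------------------
# evaluate

def test_evaluate_perfect_predictions():
    table = make_table(5)
    rec = evaluate(StubModel(table.labels), table)
    assert rec["precision"] == rec["recall"] == rec["f1"] == rec["accuracy"] == 1.0
    cm = np.array(rec["confusion_matrix"])
    assert np.trace(cm) == cm.sum() == 20


def test_evaluate_single_misclassification_hand_metrics():
    table = make_table(5)
    pred = table.labels.copy()
    a_idx = np.flatnonzero(table.labels == "A")[0]
    pred[a_idx] = "B"  # one A predicted as B
    rec = evaluate(StubModel(pred), table)
    assert rec["accuracy"] == pytest.approx(19 / 20)
    assert rec["recall"] == pytest.approx((4 / 5 + 1 + 1 + 1) / 4)
    assert rec["precision"] == pytest.approx((1 + 5 / 6 + 1 + 1) / 4)
    f1_a = 2 * (1 * 0.8) / 1.8
    f1_b = 2 * ((5 / 6) * 1) / (5 / 6 + 1)
    assert rec["f1"] == pytest.approx((f1_a + f1_b + 2) / 4)


def test_evaluate_constant_predictor_on_balanced_classes():
    table = make_table(5)
    rec = evaluate(StubModel(["A"] * 20), table)
    assert rec["accuracy"] == pytest.approx(0.25)
    assert rec["recall"] == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# tuning

def test_tune_single_iteration_returns_a_configuration():
    table = make_table(8)
    space = SearchSpace(iterations=1, cv_folds=2)
    model, best = tune_and_train(table, space, "svm", seed=0)
    assert set(best) == {"clf__kernel", "clf__C", "clf__gamma"}
    assert best["clf__kernel"] in space.svm_kernels


def test_tune_constant_space_recovers_that_configuration():
    table = make_table(8)
    space = SearchSpace(
        svm_kernels=("rbf",), svm_c_range=(1.0, 1.0), svm_gamma_range=(0.01, 0.01),
        iterations=100, cv_folds=2,
    )
    _, best = tune_and_train(table, space, "svm", seed=0)
    assert best == {"clf__kernel": "rbf", "clf__C": 1.0, "clf__gamma": 0.01}


@pytest.mark.parametrize("kind", ["svm", "rfc"])
def test_separable_clusters_reach_perfect_accuracy(kind):
    table = make_table(8, sep=10.0)
    model, _ = tune_and_train(table, SearchSpace(iterations=5, cv_folds=2), kind, seed=0)
    assert evaluate(model, table)["accuracy"] == 1.0


def test_tune_rejects_unknown_kind():
    with pytest.raises(GradingError):
        tune_and_train(make_table(8), SearchSpace(iterations=1), "mlp")


def test_tune_requires_enough_per_class():
    table = make_table(3)
    with pytest.raises(GradingError, match="5-fold"):
        tune_and_train(table, SearchSpace(iterations=1, cv_folds=5), "rfc")


# ---------------------------------------------------------------------------
# repeated experiment

def test_single_run_aggregate_collapses():
    table = make_table(8)
    rep = repeated_experiment(
        table, SplitSpec(seed=3), SearchSpace(iterations=2, cv_folds=2), "rfc", n_runs=1
    )
    agg = rep.aggregate
    for m in ("test_accuracy", "train_f1"):
        assert agg[m]["max"] == agg[m]["min"] == agg[m]["avg"]


def test_repeated_experiment_deterministic():
    table = make_table(8)
    kwargs = dict(
        spec=SplitSpec(seed=5), space=SearchSpace(iterations=2, cv_folds=2),
        model_kind="svm", n_runs=2,
    )
    r1 = repeated_experiment(table, **kwargs)
    r2 = repeated_experiment(table, **kwargs)
    assert r1.aggregate == r2.aggregate
    assert [r["best_params"] for r in r1.per_run] == [r["best_params"] for r in r2.per_run]


def test_metrics_bounded_and_consistent(small_table):
    rep = repeated_experiment(
        small_table, SplitSpec(seed=1), SearchSpace(iterations=3), "rfc", n_runs=2
    )
    for run in rep.per_run:
        for part in ("train", "test"):
            cm = np.array(run[part]["confusion_matrix"])
            assert run[part]["accuracy"] == pytest.approx(np.trace(cm) / cm.sum())
            for m in ("precision", "recall", "f1", "accuracy"):
                assert 0.0 <= run[part][m] <= 1.0


# ---------------------------------------------------------------------------
# PCA

def test_pca_rank_deficient_data():
    rng = np.random.default_rng(0)
    basis = rng.normal(size=(2, 20))
    coeffs = rng.normal(size=(40, 2))
    X = coeffs @ basis  # exactly rank 2
    table = FeatureTable(X, np.array(list("ABCD") * 10), [f"f{i}" for i in range(20)])
    train, test = split(table, SplitSpec(seed=0))
    model, ptrain, ptest = pca_reduce(train, test, k=6)
    evr = model.explained_variance_ratio
    assert evr[:2].sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(evr) <= 1e-12)
    assert ptrain.matrix.shape == (len(train), 6)


def test_pca_train_scores_centered_and_mean_maps_to_zero(small_table):
    train, test = split(small_table, SplitSpec(seed=2))
    model, ptrain, _ = pca_reduce(train, test, k=6)
    np.testing.assert_allclose(ptrain.matrix.mean(axis=0), 0, atol=1e-9)
    mean_point = train.matrix.mean(axis=0, keepdims=True)
    np.testing.assert_allclose(model.transform(mean_point), 0, atol=1e-9)


def test_pca_k_too_large():
    table = make_table(1)
    with pytest.raises(GradingError):
        pca_reduce(table, table, k=6)


# ---------------------------------------------------------------------------
# sequential selection

def test_sfs_keeps_the_informative_feature():
    rng = np.random.default_rng(0)
    n = 40
    labels = np.array((["A", "B", "C", "D"] * (n // 4)))
    signal = np.array([GRADES.index(g) for g in labels], float)
    X = np.column_stack([signal, rng.normal(size=n), rng.normal(size=n)])
    table = FeatureTable(X, labels, ["signal", "noise1", "noise2"])
    mask = sequential_select(
        table, fraction=1 / 3, cv_folds=2,
        estimator=DecisionTreeClassifier(max_depth=2, random_state=0),
    )
    assert mask.n_selected == 1
    assert mask.selected[0]  # the label-determining feature survives


def test_sfs_fraction_one_keeps_all():
    table = make_table(4, n_features=5)
    mask = sequential_select(table, fraction=1.0, cv_folds=2, estimator=GaussianNB())
    assert mask.selected.all()


def test_sfs_rounding_half_up():
    table = make_table(4, n_features=10)
    mask = sequential_select(table, fraction=0.45, cv_folds=2, estimator=GaussianNB())
    assert mask.n_selected == 5  # round(4.5) -> 5, half away from zero


def test_selection_mask_family_partition():
    rng = np.random.default_rng(1)
    selected = rng.random(N_FEATURES) < 0.3
    mask = SelectionMask(fraction=0.3, selected=selected, feature_names=feature_names())
    assert sum(mask.family_counts.values()) == mask.n_selected
    assert set(mask.family_counts) == set(FAMILY_BLOCKS)


def test_sfs_prefers_the_signal_family():
    # exactly one family (HOG, features 189-206) carries class signal; the
    # signal is kept moderate so retaining noise features measurably hurts
    # the 1-NN CV score and backward elimination prunes them actively
    from sklearn.neighbors import KNeighborsClassifier

    rng = np.random.default_rng(4)
    n = 96
    labels = np.array((["A", "B", "C", "D"] * (n // 4)))
    X = rng.normal(size=(n, N_FEATURES))
    a, b = FAMILY_BLOCKS["HOG"]
    signal = np.array([GRADES.index(g) for g in labels], float)
    X[:, a:b] += 0.8 * signal[:, None]
    table = FeatureTable(X, labels)
    mask = sequential_select(
        table, fraction=0.2, cv_folds=2,
        estimator=KNeighborsClassifier(n_neighbors=1),
    )
    shares = {
        fam: cnt / (FAMILY_BLOCKS[fam][1] - FAMILY_BLOCKS[fam][0])
        for fam, cnt in mask.family_counts.items()
    }
    hog_share = shares.pop("HOG")
    assert hog_share > max(shares.values())


# ---------------------------------------------------------------------------
# Model / Results objects

def test_luster_grader_fit_and_summary(small_table):
    grader = LusterGrader(
        small_table, model_kind="rfc", search_space=SearchSpace(iterations=3)
    )
    res = grader.fit(n_runs=2, seed=9)
    assert 0.0 <= res.test_accuracy <= 1.0
    text = res.summary()
    assert "RFC" in text and "test_accuracy" in text
    assert res.mean_confusion().shape[0] <= 4


def test_luster_grader_from_dataframe(small_table):
    df = small_table.to_dataframe()
    grader = LusterGrader.from_dataframe(
        df, model_kind="svm", use_pca=True, search_space=SearchSpace(iterations=2)
    )
    res = grader.fit(n_runs=1, seed=0)
    assert res.per_run[0]["pca"]["total_explained_variance"] > 0.5
    assert len(res.per_run[0]["pca"]["explained_variance_ratio"]) == 6


def test_luster_grader_rejects_unknown_kind(small_table):
    with pytest.raises(GradingError):
        LusterGrader(small_table, model_kind="nnet")
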