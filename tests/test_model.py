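"""Classifier training, evaluation, determinism and serialization.

Unit tests use small hidden layers: the estimator contract is identical
at any width and the published architecture is exercised by the
pipeline-level tests.
"""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from inophase.errors import LayoutError, ValidationError
from inophase.features import FeatureMatrix
from inophase.model import ReadEditingClassifier, evaluate_auc, predict, train

SMALL = dict(hidden_layer_sizes=(32, 16), max_epochs=30, random_state=0)


def separable_data(n=1200, shift=3.0, dim=10, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, dim))
    X[:, 0] += shift * y
    return X, y


def brute_force_auc(y, scores):
    """Exhaustive positive-negative pair counting with midrank ties."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_separable_data_reaches_auc_99():
    # classes disjoint along one feature: a bare threshold on it is
    # already a perfect ranker, and the network should match that
    rng = np.random.default_rng(0)
    n = 1200
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, 10))
    X[:, 0] = rng.uniform(0.5, 3.5, n) * (2 * y - 1)
    assert evaluate_auc(y, X[:, 0]) == 1.0
    model = ReadEditingClassifier(**SMALL).fit(X, y)
    assert model.heldout_auc_ >= 0.99


def test_shuffled_labels_give_chance_auc():
    X, y = separable_data(n=4000, shift=1.0, seed=3)
    rng = np.random.default_rng(7)
    model = ReadEditingClassifier(**SMALL).fit(X, rng.permutation(y))
    assert 0.45 <= model.heldout_auc_ <= 0.55


def test_positives_score_above_negatives_at_moderate_shift():
    X, y = separable_data(n=3000, shift=1.0, seed=5)
    model = ReadEditingClassifier(**SMALL).fit(X, y)
    p = model.editing_probability(X)
    assert p[y == 1].mean() > p[y == 0].mean()


def test_training_is_deterministic_given_seed():
    X, y = separable_data(n=800, seed=2)
    a = ReadEditingClassifier(**SMALL).fit(X, y)
    b = ReadEditingClassifier(**SMALL).fit(X, y)
    assert a.weights_hash() == b.weights_hash()
    np.testing.assert_array_equal(a.editing_probability(X), b.editing_probability(X))
    c = ReadEditingClassifier(**{**SMALL, "random_state": 1}).fit(X, y)
    assert c.weights_hash() != a.weights_hash()


def test_save_load_roundtrip(tmp_path):
    X, y = separable_data(n=600, seed=4)
    model = ReadEditingClassifier(**SMALL).fit(X, y)
    path = tmp_path / "model.json"
    model.save(path)
    back = ReadEditingClassifier.load(path)
    p0, p1 = model.editing_probability(X), back.editing_probability(X)
    np.testing.assert_allclose(p0, p1, atol=1e-7)
    np.testing.assert_array_equal(p0, p1)  # float32 JSON round-trip is exact
    assert back.get_params() == model.get_params()
    assert back.weights_hash() == model.weights_hash()


def test_predict_purity_and_empty():
    X, y = separable_data(n=400, seed=6)
    model = ReadEditingClassifier(**SMALL).fit(X, y)
    dup = np.vstack([X[:5], X[:5]])
    p = model.editing_probability(dup)
    np.testing.assert_array_equal(p[:5], p[5:])
    assert model.predict_proba(np.empty((0, X.shape[1]))).shape == (0, 2)
    assert np.all((p >= 0) & (p <= 1))


def test_single_class_rejected():
    X, _ = separable_data(n=100)
    with pytest.raises(ValidationError):
        ReadEditingClassifier(**SMALL).fit(X, np.zeros(100))
    with pytest.raises(ValidationError):
        evaluate_auc([1, 1, 1], [0.2, 0.4, 0.9])


def test_layout_mismatch_errors():
    X, y = separable_data(n=200, dim=4)
    layout = ("a", "b", "c", "d")
    fm = FeatureMatrix(
        X=X,
        index=pd.DataFrame({"read_id": [f"r{i}" for i in range(200)],
                            "transcript_id": "tx", "pos": 0}),
        layout=layout,
    )
    model = train(fm, y, **SMALL)
    assert model.feature_layout_ == layout
    bad = FeatureMatrix(X=X, index=fm.index, layout=("a", "b", "c", "e"))
    with pytest.raises(LayoutError):
        predict(model, bad)
    with pytest.raises(LayoutError):
        model.predict_proba(X[:, :3])


def test_predict_wrapper_preserves_batch_order():
    X, y = separable_data(n=100, dim=4)
    fm = FeatureMatrix(
        X=X,
        index=pd.DataFrame({"read_id": [f"r{i}" for i in range(100)],
                            "transcript_id": "tx", "pos": 0}),
        layout=("a", "b", "c", "d"),
    )
    model = train(fm, y, **SMALL)
    out = predict(model, fm)
    assert list(out["read_id"]) == [f"r{i}" for i in range(100)]
    np.testing.assert_array_equal(
        out["probability"].to_numpy(), model.editing_probability(X)
    )


def test_evaluate_auc_matches_pair_counting():
    # the 6 hand-listed pairs: one inversion and one tie
    y = [1, 0, 1, 0, 1, 0]
    s = [0.9, 0.8, 0.7, 0.7, 0.2, 0.1]
    assert evaluate_auc(y, s) == pytest.approx(brute_force_auc(y, s))
    assert evaluate_auc([0, 1], [0.1, 0.9]) == 1.0
    assert evaluate_auc([0, 1], [0.9, 0.1]) == 0.0
    rng = np.random.default_rng(11)
    for _ in range(50):
        n = int(rng.integers(4, 20))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        s = np.round(rng.random(n), 1)  # coarse grid to force ties
        assert evaluate_auc(y, s) == pytest.approx(brute_force_auc(y, s), abs=1e-12)


def test_sklearn_estimator_protocol():
    model = ReadEditingClassifier(**SMALL)
    params = model.get_params()
    assert params["hidden_layer_sizes"] == (32, 16)
    cloned = clone(model)
    assert cloned.get_params() == params
    X, y = separable_data(n=300, shift=2.0)
    cloned.set_params(max_epochs=5).fit(X, y)
    assert cloned.n_epochs_ <= 5
    assert set(cloned.predict(X)) <= {0, 1}


def test_invalid_hyperparameters_rejected():
    X, y = separable_data(n=50)
    for bad in (
        dict(dropout=1.0),
        dict(train_fraction=1.0),
        dict(hidden_layer_sizes=(0,)),
        dict(class_weight="wat"),
    ):
        with pytest.raises(ValidationError):
            ReadEditingClassifier(**{**SMALL, **bad}).fit(X, y)
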