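"""Logistic fits, prediction, grid ROC, and MCC."""

import math

import numpy as np
import pandas as pd
import pytest

from entroscan.classify import (
    LogisticModel,
    fit_logistic,
    mcc,
    predict_proba,
    roc_auc,
)


def _frame(X, names=("f1", "f2")):
    return pd.DataFrame(np.atleast_2d(X), columns=list(names)[: np.atleast_2d(X).shape[1]])


# ---------------------------------------------------------------------------
# fitting


def test_symmetric_two_class_data_gives_zero_intercept():
    # mirror-symmetric, non-separable data: the ML intercept is exactly zero
    X = np.array([[1.0], [2.0], [1.5], [-1.0], [-2.0], [-1.5]])
    y = ["pos", "pos", "neg", "neg", "neg", "pos"]
    m = fit_logistic(_frame(X, ("f",)), y, reference_class="neg", maxiter=100)
    assert abs(m.coefficients[1, 0]) < 1e-6


def test_separable_data_orders_probabilities():
    X = np.array([[x] for x in [-3, -2, -1, 1, 2, 3]], dtype=float)
    y = ["neg"] * 3 + ["pos"] * 3
    with pytest.warns(UserWarning, match="iterations"):
        m = fit_logistic(_frame(X, ("f",)), y, reference_class="neg", maxiter=25)
    p = predict_proba(m, _frame(X, ("f",)))["pos"]
    assert (p[3:] > 0.5).all() and (p[:3] < 0.5).all()


def test_three_class_reference_parameterization(rng):
    X = rng.normal(size=(300, 2))
    y = np.array(["utr", "antisense", "riboswitch"])[rng.integers(0, 3, 300)]
    m = fit_logistic(_frame(X), y, reference_class="antisense")
    assert m.classes[0] == "antisense"
    assert np.all(m.coefficients[0] == 0.0)
    probs = predict_proba(m, _frame(X))
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)


def test_fit_rejects_single_class():
    X = np.ones((5, 1))
    with pytest.raises(ValueError):
        fit_logistic(_frame(X, ("f",)), ["a"] * 5, reference_class="a")


def test_fit_rejects_nonfinite_features():
    X = np.array([[1.0], [np.nan]])
    with pytest.raises(ValueError):
        fit_logistic(_frame(X, ("f",)), ["a", "b"], reference_class="a")


def test_fit_recovers_generating_coefficients():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(5000, 2))
    beta = np.array([0.8, -1.0, 1.2])  # intercept, f1, f2
    logits = beta[0] + X @ beta[1:]
    y = np.where(rng.random(5000) < 1 / (1 + np.exp(-logits)), "pos", "neg")
    m = fit_logistic(_frame(X), y, reference_class="neg")
    rel = np.abs(m.coefficients[1] - beta) / np.abs(beta)
    assert np.all(rel <= 0.10)


def test_model_round_trip(tmp_path, rng):
    X = rng.normal(size=(200, 2))
    y = np.where(X[:, 0] + rng.normal(size=200) > 0, "pos", "neg")
    m = fit_logistic(_frame(X), y, reference_class="neg")
    path = tmp_path / "model.tsv"
    m.save(path)
    m2 = LogisticModel.load(path)
    assert m2.classes == m.classes and m2.reference_class == "neg"
    assert np.allclose(m2.coefficients, m.coefficients)


# ---------------------------------------------------------------------------
# prediction


def test_all_zero_coefficients_give_uniform_probabilities():
    m = LogisticModel(("a", "b", "c"), "a", ("f",), np.zeros((3, 2)))
    p = predict_proba(m, _frame([[3.0]], ("f",)))
    assert np.allclose(p.to_numpy(), 1 / 3)


def test_score_shift_invariance(rng):
    coef = rng.normal(size=(3, 3))
    X = _frame(rng.normal(size=(10, 2)))
    m1 = LogisticModel(("a", "b", "c"), "a", ("f1", "f2"), coef)
    m2 = LogisticModel(("a", "b", "c"), "a", ("f1", "f2"), coef + 5.0)  # shift all scores
    assert np.allclose(predict_proba(m1, X), predict_proba(m2, X))


def test_two_class_log3_score_gives_three_quarters():
    m = LogisticModel(
        ("neg", "pos"), "neg", ("f",), np.array([[0.0, 0.0], [math.log(3), 0.0]])
    )
    p = predict_proba(m, _frame([[0.0]], ("f",)))
    assert p["pos"].iloc[0] == pytest.approx(0.75)


def test_predict_rejects_feature_mismatch():
    m = LogisticModel(("a", "b"), "a", ("f1",), np.zeros((2, 2)))
    with pytest.raises(ValueError, match="missing"):
        predict_proba(m, _frame([[1.0]], ("other",)))


# ---------------------------------------------------------------------------
# ROC


def test_roc_perfect_separation():
    _, a = roc_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
    assert a == pytest.approx(1.0)


def test_roc_identical_scores_is_diagonal():
    _, a = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
    assert a == pytest.approx(0.5)


def test_roc_matches_rank_sum_oracle():
    # off-grid scores so the 0.01 grid resolves every case exactly
    scores = np.array([0.855, 0.755, 0.355, 0.255])
    labels = np.array([1, 0, 1, 0])
    pos, neg = scores[labels == 1], scores[labels == 0]
    u = sum((p > q) for p in pos for q in neg) / (len(pos) * len(neg))
    _, a = roc_auc(scores, labels)
    assert a == pytest.approx(u)


def test_roc_complement_symmetry(rng):
    scores = np.round(rng.random(40), 3) + 0.0005  # keep off the grid
    labels = rng.integers(0, 2, 40)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    _, a1 = roc_auc(scores, labels)
    _, a2 = roc_auc(scores, 1 - labels)
    assert a1 + a2 == pytest.approx(1.0, abs=0.02)


def test_roc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([0.5, 0.6], [1, 1])


def test_roc_standard_sweep_flag():
    scores = [0.9, 0.8, 0.3, 0.2]
    _, a = roc_auc(scores, [1, 1, 0, 0], grid=False)
    assert a == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# MCC


def test_mcc_printed_mutagenesis_value():
    assert mcc(10, 1, 5, 2) == pytest.approx(0.645, abs=5e-4)


@pytest.mark.parametrize("k", [1, 7])
def test_mcc_perfect_prediction(k):
    assert mcc(k, 0, k, 0) == pytest.approx(1.0)


def test_mcc_uninformative_prediction():
    assert mcc(1, 1, 1, 1) == 0.0


def test_mcc_zero_marginal_convention():
    assert mcc(0, 0, 3, 2) == 0.0


def test_mcc_negative_counts_rejected():
    with pytest.raises(ValueError):
        mcc(-1, 0, 1, 0)


def test_mcc_matches_sklearn(rng):
    from sklearn.metrics import matthews_corrcoef

    y_true = rng.integers(0, 2, 60)
    y_pred = rng.integers(0, 2, 60)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    assert mcc(tp, fp, tn, fn) == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)
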