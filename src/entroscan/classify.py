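"""Logistic-regression classifiers over feature vectors.

Binomial and multinomial maximum-likelihood logistic regression with an
explicit reference class (coefficients of the reference are identically
zero, the convention used when reporting riboswitch/UTR coefficients
against the antisense class), a fixed-grid ROC construction, and the
Matthews correlation coefficient.

The fit itself is delegated to statsmodels (unregularized Newton ML);
prediction, the ROC sweep, and MCC follow this package's conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class LogisticModel:
    """Fitted multinomial logistic model.

    ``coefficients`` has one row per class in ``classes`` order (the
    reference row is all zeros) and one column per ``(intercept, *features)``.
    """

    classes: tuple[str, ...]
    reference_class: str
    feature_names: tuple[str, ...]
    coefficients: np.ndarray  # (n_classes, 1 + n_features)
    converged: bool = True

    def linear_scores(self, X: np.ndarray) -> np.ndarray:
        X1 = np.column_stack([np.ones(len(X)), X])
        return X1 @ self.coefficients.T

    def to_table(self) -> pd.DataFrame:
        rows = []
        for ci, cls in enumerate(self.classes):
            for fi, name in enumerate(("intercept", *self.feature_names)):
                rows.append({"class": cls, "feature": name, "value": self.coefficients[ci, fi]})
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        df = self.to_table()
        with open(path, "w") as fh:
            fh.write(f"# reference_class\t{self.reference_class}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def load(cls, path: str | Path) -> "LogisticModel":
        lines = Path(path).read_text().splitlines()
        reference = lines[0].split("\t")[1]
        df = pd.read_csv(Path(path), sep="\t", comment="#")
        classes = tuple(dict.fromkeys(df["class"]))
        features = tuple(f for f in dict.fromkeys(df["feature"]) if f != "intercept")
        coef = np.zeros((len(classes), 1 + len(features)))
        fidx = {"intercept": 0, **{f: i + 1 for i, f in enumerate(features)}}
        cidx = {c: i for i, c in enumerate(classes)}
        for _, r in df.iterrows():
            coef[cidx[r["class"]], fidx[r["feature"]]] = r["value"]
        return cls(classes, reference, features, coef)


def fit_logistic(
    features: pd.DataFrame,
    labels,
    reference_class: str,
    feature_names: tuple[str, ...] | None = None,
    tol: float = 1e-8,
    maxiter: int = 200,
) -> LogisticModel:
    """Unregularized maximum-likelihood multinomial logistic regression.

    ``features`` is a numeric table (one row per case); ``labels`` the class
    per row.  The reference class's coefficient vector is fixed at zero.
    Separable data is handled by the iteration cap: the fit stops at
    ``maxiter`` Newton steps with a warning rather than diverging.
    """
    labels = np.asarray(labels, dtype=object)
    classes = [reference_class] + sorted(set(map(str, labels)) - {reference_class})
    if len(classes) < 2 or reference_class not in set(map(str, labels)):
        raise ValueError("need at least two classes including the reference")
    if feature_names is None:
        feature_names = tuple(features.columns)
    X = features.loc[:, list(feature_names)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    y = np.array([classes.index(str(v)) for v in labels])

    import statsmodels.api as sm

    X1 = sm.add_constant(X, has_constant="add")
    model = sm.MNLogit(y, X1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=False)
        if not np.isfinite(np.asarray(res.params)).all():
            # singular Hessian (typically separable data): fall back to a
            # capped quasi-Newton fit, which stays finite
            res = model.fit(method="lbfgs", maxiter=maxiter, disp=False)
    converged = bool(res.mle_retvals.get("converged", True))
    if not np.isfinite(np.asarray(res.params)).all():
        raise ArithmeticError("logistic fit produced non-finite coefficients")
    if not converged:
        warnings.warn(
            f"logistic fit stopped at {maxiter} iterations (possibly separable data)",
            stacklevel=2,
        )
    # statsmodels params: (1+p, J-1) relative to class 0 (our reference)
    params = np.asarray(res.params)
    coef = np.zeros((len(classes), 1 + len(feature_names)))
    coef[1:, :] = params.T
    return LogisticModel(
        classes=tuple(classes),
        reference_class=reference_class,
        feature_names=tuple(feature_names),
        coefficients=coef,
        converged=converged,
    )


def predict_proba(model: LogisticModel, features: pd.DataFrame) -> pd.DataFrame:
    """Per-class probabilities: softmax of linear scores, reference fixed at 0."""
    missing = set(model.feature_names) - set(features.columns)
    if missing:
        raise ValueError(f"missing features: {sorted(missing)}")
    X = features.loc[:, list(model.feature_names)].to_numpy(dtype=float)
    scores = model.linear_scores(X)
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    probs = e / e.sum(axis=1, keepdims=True)
    return pd.DataFrame(probs, columns=list(model.classes), index=features.index)


def predict_class(model: LogisticModel, features: pd.DataFrame) -> np.ndarray:
    """Maximum-likelihood class per row (argmax probability)."""
    probs = predict_proba(model, features)
    return probs.to_numpy().argmax(axis=1).astype(object), probs.columns.to_numpy()


def roc_auc(
    scores,
    labels,
    resolution: float = 0.01,
    grid: bool = True,
) -> tuple[np.ndarray, float]:
    """ROC curve and area under it.

    By default thresholds sweep a fixed grid of step ``resolution`` over
    [0, 1]; a case is called positive iff its score is strictly greater
    than the threshold.  ``grid=False`` uses the conventional unique-score
    sweep instead.  Returns ``(points, area)`` where points are (FPR, TPR)
    rows including (0,0) and (1,1); area by the trapezoid rule.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    pos = labels == 1
    neg = ~pos
    if grid:
        thresholds = np.round(np.arange(0.0, 1.0 + resolution / 2, resolution), 10)
    else:
        thresholds = np.unique(scores)
    pts = {(0.0, 0.0), (1.0, 1.0)}
    for t in thresholds:
        called = scores > t
        tpr = called[pos].mean()
        fpr = called[neg].mean()
        pts.add((float(fpr), float(tpr)))
    points = np.array(sorted(pts))
    area = float(np.trapezoid(points[:, 1], points[:, 0]))
    return points, area


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient from a 2x2 confusion table.

    Returns 0 by convention when any marginal is empty.
    """
    for v in (tp, fp, tn, fn):
        if v < 0:
            raise ValueError("negative confusion counts")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)
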