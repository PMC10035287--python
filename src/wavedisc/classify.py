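"""Gaussian discriminant classifiers, leave-one-out cross-validation and metrics.

The linear discriminant pools the within-group covariance across groups
(one shared ellipsoid, linear decision boundary); the quadratic discriminant
estimates a covariance per group (quadratic boundary).  Both use equal class
priors and predict by the largest Gaussian log-density.  Covariances are
regularized as ``(1 - lam) * S + lam * diag(S)``, which keeps the fit usable
when the number of selected features approaches the number of trials.

Performance is summarized by leave-one-out cross-validation: each trial is
predicted by a model trained on all the others, and predictions are tallied
into a confusion matrix against a declared positive class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

_KINDS = ("linear", "quadratic")


@dataclass
class ConfusionMatrix:
    """Binary-classification tallies: TP, FN, FP, TN (actual class in rows)."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class Metrics:
    """Derived rates; a metric whose denominator is zero is ``None`` (undefined).

    accuracy    = (TP + TN) / (TP + FN + FP + TN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)
    precision   = TP / (TP + FP)
    f_measure   = 2 * precision * sensitivity / (precision + sensitivity)
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f_measure: float | None


@dataclass
class DiscriminantModel:
    kind: str
    classes: np.ndarray
    means: np.ndarray  # (g, q)
    cho_factors: list  # per class for quadratic, single shared for linear
    logdets: np.ndarray  # (g,)
    shrinkage: float

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class Gaussian log-density scores (equal priors), shape (n, g)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        g = self.classes.size
        scores = np.empty((n, g))
        for k in range(g):
            cho = self.cho_factors[0] if self.kind == "linear" else self.cho_factors[k]
            diff = X - self.means[k]
            sol = linalg.cho_solve(cho, diff.T)
            maha = np.einsum("ij,ji->i", diff, sol)
            scores[:, k] = -0.5 * maha - 0.5 * self.logdets[k]
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        return self.classes[np.argmax(scores, axis=1)]


def _shrink(S: np.ndarray, lam: float) -> np.ndarray:
    return (1.0 - lam) * S + lam * np.diag(np.diag(S))


def fit_discriminant(
    X: np.ndarray,
    labels: np.ndarray,
    kind: str = "linear",
    shrinkage: float = 1e-4,
) -> DiscriminantModel:
    """Fit a linear or quadratic Gaussian discriminant with equal priors.

    Parameters
    ----------
    X : ndarray, shape (n, q)
        Feature values.
    labels : ndarray, shape (n,)
        Group labels; every group needs >= 2 trials.
    kind : {"linear", "quadratic"}
        Pooled covariance (linear boundary) or per-group covariance.
    shrinkage : float in [0, 1]
        Regularization weight toward the covariance diagonal.

    Raises
    ------
    numpy.linalg.LinAlgError
        If a covariance is singular after shrinkage; increase ``shrinkage``
        or select fewer features.
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    n, q = X.shape
    classes = np.unique(labels)
    g = classes.size
    counts = np.array([(labels == c).sum() for c in classes])
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 trials to fit a covariance")

    means = np.vstack([X[labels == c].mean(axis=0) for c in classes])

    def _factor(S: np.ndarray):
        S = _shrink(S, shrinkage)
        evals = np.linalg.eigvalsh(S)
        if evals[0] <= 0.0 or evals[0] <= 1e-14 * evals[-1]:
            raise np.linalg.LinAlgError(
                "covariance singular after shrinkage; increase the shrinkage "
                "parameter or select fewer features"
            )
        try:
            cho = linalg.cho_factor(S)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "covariance singular after shrinkage; increase the shrinkage "
                "parameter or select fewer features"
            ) from exc
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        return cho, logdet

    if kind == "linear":
        pooled = np.zeros((q, q))
        for c in classes:
            Xc = X[labels == c] - X[labels == c].mean(axis=0)
            pooled += Xc.T @ Xc
        pooled /= n - g
        cho, logdet = _factor(pooled)
        cho_factors = [cho]
        logdets = np.full(g, logdet)
    else:
        cho_factors = []
        logdets = np.empty(g)
        for k, c in enumerate(classes):
            S_k = np.atleast_2d(np.cov(X[labels == c], rowvar=False, ddof=1))
            cho, logdets[k] = _factor(S_k)
            cho_factors.append(cho)

    return DiscriminantModel(
        kind=kind,
        classes=classes,
        means=means,
        cho_factors=cho_factors,
        logdets=logdets,
        shrinkage=shrinkage,
    )


def loocv(
    X: np.ndarray,
    labels: np.ndarray,
    kind: str = "linear",
    shrinkage: float = 1e-4,
    positive: object | None = None,
) -> ConfusionMatrix:
    """Leave-one-out cross-validation of the discriminant classifier.

    Each trial in turn is held out, the classifier is fit on the remaining
    ``n - 1`` trials, and the held-out trial is predicted; results are
    tallied against the declared positive class (default: lexicographically
    first label).

    Raises
    ------
    ValueError
        If a fold's training set leaves some group with fewer than 2 trials
        (the offending fold is named).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    n = X.shape[0]
    if n < 4:
        raise ValueError("leave-one-out needs at least 4 trials")
    if positive is None:
        positive = np.unique(labels)[0]

    tp = fn = fp = tn = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        train_labels = labels[mask]
        _, counts = np.unique(train_labels, return_counts=True)
        if counts.min() < 2:
            raise ValueError(
                f"fold {i}: removing trial {i} leaves a group with fewer than 2 trials"
            )
        model = fit_discriminant(X[mask], train_labels, kind=kind, shrinkage=shrinkage)
        pred = model.predict(X[i : i + 1])[0]
        mask[i] = True

        actual_pos = labels[i] == positive
        pred_pos = pred == positive
        if actual_pos and pred_pos:
            tp += 1
        elif actual_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, sensitivity, specificity, precision and F-measure from tallies.

    A metric whose denominator is zero is reported as ``None`` rather than 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    sens = ratio(cm.tp, cm.tp + cm.fn)
    prec = ratio(cm.tp, cm.tp + cm.fp)
    if prec is None or sens is None or (prec + sens) == 0:
        f_meas = None
    else:
        f_meas = 2.0 * prec * sens / (prec + sens)
    return Metrics(
        accuracy=(cm.tp + cm.tn) / cm.total,
        sensitivity=sens,
        specificity=ratio(cm.tn, cm.fp + cm.tn),
        precision=prec,
        f_measure=f_meas,
    )
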