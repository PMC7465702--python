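"""Classifiers: Fisher LDA, least-squares SVM with a quadratic kernel,
a weighted-majority ensemble, stratified 10-fold cross-validation,
within-subject standardization, and the exact-binomial chance level."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold


class SingleClassError(ValueError):
    """Training data must contain both classes."""


def _encode(labels: np.ndarray,
            class_labels: tuple | None) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    if len(uniq) < 2:
        raise SingleClassError("training labels contain a single class")
    if len(uniq) > 2:
        raise ValueError("binary classification only")
    if class_labels is None:
        class_labels = tuple(uniq)
    y = np.where(labels == class_labels[0], 1.0, -1.0)
    return y, class_labels


@dataclass
class LinearClassifier:
    """Linear discriminant: sign(w.x + bias) -> class_labels[0 or 1]."""

    weights: np.ndarray
    bias: float
    class_labels: tuple = ("A", "B")

    def score(self, x: np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        s = x @ self.weights + self.bias
        return float(s) if s.ndim == 0 else s

    def predict(self, x: np.ndarray):
        s = np.asarray(self.score(x))
        out = np.where(s >= 0, self.class_labels[0], self.class_labels[1])
        return out[()] if out.ndim == 0 else out

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearClassifier":
        fitted = lda_fit(X, y, class_labels=None)
        self.weights, self.bias = fitted.weights, fitted.bias
        self.class_labels = fitted.class_labels
        return self


def lda_fit(features: np.ndarray, labels: np.ndarray,
            class_labels: tuple | None = None,
            ridge: float = 1e-8) -> LinearClassifier:
    """Fisher LDA: w = pooled-covariance^-1 (m1 - m2), boundary midway
    between projected class means."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y, class_labels = _encode(np.asarray(labels), class_labels)
    m1 = X[y > 0].mean(axis=0)
    m2 = X[y < 0].mean(axis=0)
    x1 = X[y > 0] - m1
    x2 = X[y < 0] - m2
    n = X.shape[0]
    pooled = (x1.T @ x1 + x2.T @ x2) / max(n - 2, 1)
    pooled = pooled + ridge * np.trace(pooled) / max(X.shape[1], 1) * np.eye(X.shape[1])
    try:
        w = np.linalg.solve(pooled, m1 - m2)
    except np.linalg.LinAlgError:
        w = np.linalg.pinv(pooled) @ (m1 - m2)
    bias = -float(w @ (m1 + m2) / 2.0)
    return LinearClassifier(weights=w, bias=bias, class_labels=class_labels)


def lda_score(model: LinearClassifier, x: np.ndarray):
    return model.score(x)


@dataclass
class KernelClassifier:
    """Least-squares SVM with the quadratic kernel (x.y + 1)^2."""

    support: np.ndarray = field(default_factory=lambda: np.zeros((0, 1)))
    dual_coef: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bias: float = 0.0
    class_labels: tuple = ("A", "B")
    gamma: float = 1.0

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        return (A @ B.T + 1.0) ** 2

    def score(self, x: np.ndarray):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        s = self._kernel(x, self.support) @ self.dual_coef + self.bias
        return float(s[0]) if s.shape[0] == 1 else s

    def predict(self, x: np.ndarray):
        s = np.asarray(self.score(x))
        out = np.where(s >= 0, self.class_labels[0], self.class_labels[1])
        return out[()] if out.ndim == 0 else out

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KernelClassifier":
        fitted = svm_fit(X, y, gamma=self.gamma)
        self.support = fitted.support
        self.dual_coef = fitted.dual_coef
        self.bias = fitted.bias
        self.class_labels = fitted.class_labels
        return self


def svm_fit(features: np.ndarray, labels: np.ndarray,
            class_labels: tuple | None = None,
            gamma: float = 1.0) -> KernelClassifier:
    """Least-squares SVM: solve the saddle-point system for dual
    coefficients; the ridge term is grown x10 (up to 3 times) if the
    system is singular."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y, class_labels = _encode(np.asarray(labels), class_labels)
    n = X.shape[0]
    K = (X @ X.T + 1.0) ** 2
    ridge = 1.0 / gamma
    for attempt in range(4):
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = K + ridge * np.eye(n)
        rhs = np.concatenate(([0.0], y))
        try:
            sol = np.linalg.solve(A, rhs)
            if not np.all(np.isfinite(sol)):
                raise np.linalg.LinAlgError("non-finite solution")
            break
        except np.linalg.LinAlgError:
            if attempt == 3:
                raise
            ridge *= 10.0
    return KernelClassifier(support=X, dual_coef=sol[1:], bias=float(sol[0]),
                            class_labels=class_labels, gamma=gamma)


def svm_score(model: KernelClassifier, x: np.ndarray):
    return model.score(x)


@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    k: int
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def crossval_accuracy(features: np.ndarray, labels: np.ndarray,
                      make_estimator, k: int = 10, seed: int = 0) -> CVResult:
    """Stratified k-fold accuracy; fold assignment fixed by seed.

    ``make_estimator`` is a zero-argument factory returning an object
    with fit(X, y) and predict(X).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} samples, got {X.shape[0]}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        est = make_estimator()
        est.fit(X[train_idx], y[train_idx])
        pred = np.asarray(est.predict(X[test_idx]))
        accs.append(float(np.mean(pred == y[test_idx])))
    return CVResult(fold_accuracies=np.array(accs), k=k, seed=seed)


@dataclass
class EnsembleModel:
    """LDA + LS-SVM members combined by weighted majority voting."""

    lda: LinearClassifier
    svm: KernelClassifier
    voting_weights: tuple[float, float]  # (lda, svm), nonnegative, sum 1
    class_labels: tuple = ("A", "B")

    def predict(self, x: np.ndarray):
        single = np.asarray(x).ndim == 1
        x = np.atleast_2d(np.asarray(x, dtype=float))
        preds = []
        for row in x:
            votes = {label: 0.0 for label in self.class_labels}
            members = ((self.lda, self.voting_weights[0]),
                       (self.svm, self.voting_weights[1]))
            for member, weight in members:
                votes[member.predict(row)] += weight
            best = max(votes.values())
            tied = [lab for lab, v in votes.items() if v == best]
            if len(tied) == 1:
                preds.append(tied[0])
            else:
                # Tie: follow the higher-weight member (LDA on equal weights).
                lead = self.lda if self.voting_weights[0] >= self.voting_weights[1] else self.svm
                preds.append(lead.predict(row))
        out = np.array(preds)
        return out[0] if single else out

    def score(self, x: np.ndarray):
        """Weighted sum of member decision scores (sign-normalized)."""
        s_lda = np.asarray(self.lda.score(x), dtype=float)
        s_svm = np.asarray(self.svm.score(x), dtype=float)
        s = self.voting_weights[0] * np.sign(s_lda) + self.voting_weights[1] * np.sign(s_svm)
        return float(s) if s.ndim == 0 else s

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EnsembleModel":
        fitted = ensemble_fit(X, y)
        self.lda, self.svm = fitted.lda, fitted.svm
        self.voting_weights = fitted.voting_weights
        self.class_labels = fitted.class_labels
        return self


def ensemble_fit(features: np.ndarray, labels: np.ndarray,
                 k: int = 10, seed: int = 0,
                 class_labels: tuple | None = None) -> EnsembleModel:
    """Fit both members; voting weights are their normalized k-fold
    cross-validated training accuracies."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    _, class_labels = _encode(y, class_labels)
    lda = lda_fit(X, y, class_labels)
    svm = svm_fit(X, y, class_labels)
    k_eff = min(k, int(np.min(np.unique(y, return_counts=True)[1])))
    if k_eff >= 2 and X.shape[0] >= k_eff:
        acc_lda = crossval_accuracy(X, y, lambda: LinearClassifier(np.zeros(1), 0.0),
                                    k=k_eff, seed=seed).mean_accuracy
        acc_svm = crossval_accuracy(X, y, lambda: KernelClassifier(),
                                    k=k_eff, seed=seed).mean_accuracy
    else:
        acc_lda = acc_svm = 0.5
    total = acc_lda + acc_svm
    weights = (0.5, 0.5) if total == 0 else (acc_lda / total, acc_svm / total)
    return EnsembleModel(lda=lda, svm=svm, voting_weights=weights,
                         class_labels=class_labels)


def ensemble_predict(model: EnsembleModel, x: np.ndarray):
    return model.predict(x)


def standardize_within(table: np.ndarray) -> np.ndarray:
    """Per-row (subject) z-scores of an accuracy table (subject x method).

    Rows with zero spread are set to zeros.
    """
    table = np.atleast_2d(np.asarray(table, dtype=float))
    if table.shape[1] < 2:
        raise ValueError("need at least 2 methods per subject")
    means = table.mean(axis=1, keepdims=True)
    sds = table.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(table)
    nonzero = sds[:, 0] > 0
    out[nonzero] = (table[nonzero] - means[nonzero]) / sds[nonzero]
    return out


def true_chance_level(n_trials: int, n_classes: int = 2,
                      alpha: float = 0.05) -> float:
    """Exact-binomial upper bound on guessing accuracy, in percent.

    The (1 - alpha) quantile of Binomial(n, 1/n_classes) divided by n.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly inside (0, 1)")
    q = stats.binom.ppf(1 - alpha, n_trials, 1.0 / n_classes)
    return float(q) / n_trials * 100.0
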