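"""Linear discriminant analysis on score matrices.

Classical LDA with a pooled within-class covariance, equal priors by default
(so the 63-sample class cannot dominate the 11-sample class), and a tiny
ridge on the covariance diagonal for numerical safety. Classification is by
the largest linear discriminant score; ties resolve to the lowest class index
in sorted class-name order.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .exceptions import FitError, ParameterError


class LinearDiscriminantClassifier:
    """LDA classifier (scikit-learn-style estimator).

    Parameters
    ----------
    ridge : float
        Diagonal regularization added to the pooled covariance as
        ``ridge * trace(S) / k`` (k = feature dimension). Default 1e-8.
    priors : "equal" or "empirical"
        Equal priors treat every class symmetrically regardless of size
        (default); empirical priors weight by training frequency.

    Attributes
    ----------
    classes_ : ndarray of class names, sorted.
    means_ : ndarray (c, k) class mean scores.
    coef_, intercept_ : discriminant weights; score of class j for x is
        ``x @ coef_[j] + intercept_[j]``.
    """

    def __init__(self, ridge: float = 1e-8, priors: str = "equal"):
        self.ridge = ridge
        self.priors = priors

    def get_params(self, deep: bool = True):  # noqa: ARG002
        return {"ridge": self.ridge, "priors": self.priors}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def __sklearn_tags__(self):
        from ._sklearn_compat import classifier_tags

        return classifier_tags()

    def fit(self, X: np.ndarray, y) -> "LinearDiscriminantClassifier":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ParameterError("X and y disagree on the number of rows")
        classes, y_idx = np.unique(y.astype(str), return_inverse=True)
        if classes.size < 2:
            raise FitError("LDA needs at least 2 classes")
        n, k = X.shape
        counts = np.bincount(y_idx, minlength=classes.size)
        if counts.min() < 2:
            small = classes[int(np.argmin(counts))]
            raise FitError(f"class {small!r} has fewer than 2 training members")

        means = np.vstack([X[y_idx == j].mean(axis=0) for j in range(classes.size)])
        resid = X - means[y_idx]
        cov = resid.T @ resid / (n - classes.size)
        tr = float(np.trace(cov))
        cov = cov + np.eye(k) * (self.ridge * tr / k if tr > 0 else self.ridge)
        try:
            cho = linalg.cho_factor(cov, lower=True)
            inv_means = linalg.cho_solve(cho, means.T)  # (k, c) = Σ⁻¹ μᵀ
        except linalg.LinAlgError as exc:
            raise FitError(f"pooled covariance singular beyond ridge: {exc}") from exc

        self.classes_ = classes
        self.means_ = means
        self.coef_ = inv_means.T  # (c, k)
        self.intercept_ = -0.5 * np.einsum("ck,ck->c", means, self.coef_)
        if self.priors == "empirical":
            self.intercept_ = self.intercept_ + np.log(counts / n)
        elif self.priors != "equal":
            raise ParameterError("priors must be 'equal' or 'empirical'")
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef_.T + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        # argmax returns the first (lowest sorted class index) on ties
        return self.classes_[np.argmax(scores, axis=1)]

    def score(self, X: np.ndarray, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y).astype(str)))
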