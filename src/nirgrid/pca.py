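"""NIPALS principal component analysis.

NIPALS extracts components one at a time: power-type iteration of a score
vector against the (mean-centered) data matrix, followed by rank-1 deflation.
It is the classical chemometrics PCA and, unlike a full SVD, stops after the
requested number of components.

For wide matrices (p > n) the iteration is run on the Gram matrix
G = X Xᵀ, which produces the same score iterates at a fraction of the cost;
loadings are recovered as Xᵀt/‖Xᵀt‖ once the score has converged. Components
that fail to converge within the iteration cap are accepted as-is and flagged
in ``converged_``.
"""

from __future__ import annotations

import logging

import numpy as np

from .exceptions import ParameterError

logger = logging.getLogger(__name__)


class NipalsPCA:
    """PCA by the NIPALS algorithm (scikit-learn-style estimator).

    Parameters
    ----------
    n_components : int
        Number of components to extract; must satisfy
        ``n_components <= min(n_samples - 1, n_features)``.
    tol : float
        Convergence threshold on the relative change of the score vector
        between iterations (default 1e-10).
    max_iter : int
        Iteration cap per component (default 500); a non-converged component
        is accepted at the cap and recorded in ``converged_``.

    Attributes
    ----------
    mean_ : ndarray (p,)
        Training column means; data are centered with these before projection.
    components_ : ndarray (k, p)
        Unit-norm loadings, one row per component.
    scores_ : ndarray (n, k)
        Training scores (mutually orthogonal columns).
    explained_variance_ : ndarray (k,)
        Score variances tᵀt/(n-1) per component.
    converged_ : ndarray of bool (k,)
    n_iter_ : ndarray of int (k,)
    """

    def __init__(self, n_components: int, tol: float = 1e-10, max_iter: int = 500):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    # -- sklearn plumbing ----------------------------------------------------
    def get_params(self, deep: bool = True):  # noqa: ARG002
        return {"n_components": self.n_components, "tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def __sklearn_tags__(self):
        from ._sklearn_compat import transformer_tags

        return transformer_tags()

    # -- core ---------------------------------------------------------------
    def fit(self, X: np.ndarray, y=None) -> "NipalsPCA":  # noqa: ARG002
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ParameterError("NIPALS needs a 2-D matrix with >= 2 rows")
        n, p = X.shape
        k = int(self.n_components)
        if k < 1 or k > min(n - 1, p):
            raise ParameterError(
                f"n_components={k} outside [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
            )
        self.mean_ = X.mean(axis=0)
        E = X - self.mean_

        scores = np.zeros((n, k))
        loadings = np.zeros((k, p))
        ev = np.zeros(k)
        n_iter = np.zeros(k, dtype=int)
        converged = np.zeros(k, dtype=bool)

        use_gram = p > n
        for comp in range(k):
            col_var = np.einsum("ij,ij->j", E, E)
            j0 = int(np.argmax(col_var))
            if col_var[j0] <= np.finfo(float).eps * max(1.0, float(np.abs(E).max()) ** 2):
                # residual exhausted: remaining components are null
                converged[comp:] = True
                break
            t = E[:, j0].copy()
            if use_gram:
                # same iterate sequence as plain NIPALS: the update
                # t <- E (Eᵀt / ‖Eᵀt‖) equals G t / sqrt(tᵀ G t) with G = E Eᵀ
                G = E @ E.T
                for it in range(1, self.max_iter + 1):
                    Gt = G @ t
                    s = float(t @ Gt)
                    if s <= 0.0:
                        t = np.zeros(n)
                        break
                    t_new = Gt / np.sqrt(s)
                    delta = np.linalg.norm(t_new - t) / max(
                        np.linalg.norm(t_new), np.finfo(float).tiny
                    )
                    t = t_new
                    if delta < self.tol:
                        converged[comp] = True
                        break
            else:
                for it in range(1, self.max_iter + 1):
                    pt = E.T @ t
                    pn = np.linalg.norm(pt)
                    if pn == 0.0:
                        t = np.zeros(n)
                        break
                    t_new = E @ (pt / pn)
                    delta = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), np.finfo(float).tiny)
                    t = t_new
                    if delta < self.tol:
                        converged[comp] = True
                        break
            n_iter[comp] = it
            if not converged[comp]:
                logger.debug("NIPALS component %d accepted at iteration cap", comp + 1)
            pt = E.T @ t
            pn = np.linalg.norm(pt)
            if pn == 0.0:
                converged[comp] = True
                continue
            pvec = pt / pn
            t = E @ pvec
            scores[:, comp] = t
            loadings[comp] = pvec
            ev[comp] = float(t @ t) / (n - 1)
            E = E - np.outer(t, pvec)

        self.scores_ = scores
        self.components_ = loadings
        self.explained_variance_ = ev
        total_var = float(np.einsum("ij,ij->", X - self.mean_, X - self.mean_)) / (n - 1)
        self.explained_variance_ratio_ = ev / total_var if total_var > 0 else np.zeros(k)
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:  # noqa: ARG002
        return self.fit(X).scores_
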