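"""Orthogonal projections to latent structures (O-PLS) signal correction.

Given a centred samples x features matrix X and a binary response y coded
-1/+1, O-PLS splits the predictor variation into a part correlated with y
and structured components orthogonal to it, and removes the latter. With a
single response the NIPALS update per orthogonal component is

    w   = X'y / ||X'y||          predictive weights
    t   = X w                    predictive scores
    p   = X't / (t't)            loadings of t
    w_o = p - (w'p) w,  normalized   orthogonal weights
    t_o = X w_o                  orthogonal scores
    p_o = X't_o / (t_o't_o)      orthogonal loadings
    X  <- X - t_o p_o'

Because w is proportional to X'y, every orthogonal score satisfies
t_o'y = y'X w_o ∝ w'w_o = 0 exactly: the removed variation carries no
class information. The deflated matrix plus the removed rank-one pieces
reconstructs the input exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be a 2-D samples x features matrix")
    if X.shape[0] != y.size:
        raise ValueError("X and y have different numbers of samples")
    if np.unique(np.sign(y[y != 0])).size < 2:
        raise ValueError("y must contain both classes")
    return X, y


class OPLS(TransformerMixin, BaseEstimator):
    """O-PLS filter: remove y-orthogonal structured variation from X.

    Parameters
    ----------
    n_orth : int
        Number of orthogonal components to extract (default 1: remove the
        single dominant orthogonal component).
    degenerate_tol : float
        Relative threshold on ||w_o||: below it there is no orthogonal
        variation left and extraction stops early.

    Attributes
    ----------
    w_ : (n_features,) predictive weight vector (unit norm).
    w_orth_, p_orth_ : lists of orthogonal weight / loading vectors.
    t_orth_ : list of orthogonal score vectors on the training samples.
    n_orth_effective_ : number of components actually removed.
    """

    def __init__(self, n_orth: int = 1, degenerate_tol: float = 1e-12):
        self.n_orth = n_orth
        self.degenerate_tol = degenerate_tol

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        if X.shape[0] < 3:
            # 3 allows leave-one-out folds over 4-sample comparisons
            raise ValueError("O-PLS needs at least 3 samples")
        if self.n_orth < 1:
            raise ValueError("n_orth must be a positive integer")
        Xd = X.copy()
        self.w_orth_: list[np.ndarray] = []
        self.p_orth_: list[np.ndarray] = []
        self.t_orth_: list[np.ndarray] = []
        for _ in range(self.n_orth):
            w = Xd.T @ y
            wn = np.linalg.norm(w)
            if wn == 0:
                logger.info("X'y vanished; no predictive direction, stopping")
                break
            w /= wn
            t = Xd @ w
            tt = t @ t
            if tt == 0:
                break
            p = Xd.T @ t / tt
            w_o = p - (w @ p) * w
            if np.linalg.norm(w_o) < self.degenerate_tol * max(np.linalg.norm(p), 1.0):
                logger.info("no orthogonal variation left; stopping early")
                break
            w_o /= np.linalg.norm(w_o)
            t_o = Xd @ w_o
            to_to = t_o @ t_o
            if to_to == 0:
                break
            p_o = Xd.T @ t_o / to_to
            Xd -= np.outer(t_o, p_o)
            self.w_orth_.append(w_o)
            self.p_orth_.append(p_o)
            self.t_orth_.append(t_o)
        self.n_orth_effective_ = len(self.w_orth_)
        # predictive weight of the deflated matrix
        w = Xd.T @ y
        wn = np.linalg.norm(w)
        self.w_ = w / wn if wn > 0 else w
        self.X_filtered_ = Xd
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "w_")
        X = np.asarray(X, dtype=float)
        one_d = X.ndim == 1
        if one_d:
            X = X[np.newaxis, :]
        Xd = X.copy()
        for w_o, p_o in zip(self.w_orth_, self.p_orth_):
            t_o = Xd @ w_o
            Xd -= np.outer(t_o, p_o)
        return Xd[0] if one_d else Xd

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X, y)
        return self.X_filtered_


@dataclass
class OplsFilterResult:
    """Filtered matrix plus the removed orthogonal structure."""

    X_filtered: np.ndarray
    t_orth: list[np.ndarray]
    p_orth: list[np.ndarray]
    w_orth: list[np.ndarray]
    w: np.ndarray
    n_orth: int
    n_orth_effective: int

    def reconstruct(self) -> np.ndarray:
        X = self.X_filtered.copy()
        for t_o, p_o in zip(self.t_orth, self.p_orth):
            X += np.outer(t_o, p_o)
        return X


def opls_filter(X: np.ndarray, y: np.ndarray, n_orth: int = 1) -> OplsFilterResult:
    """Functional wrapper over :class:`OPLS` returning the filter result."""
    est = OPLS(n_orth=n_orth).fit(X, y)
    return OplsFilterResult(
        X_filtered=est.X_filtered_,
        t_orth=list(est.t_orth_),
        p_orth=list(est.p_orth_),
        w_orth=list(est.w_orth_),
        w=est.w_,
        n_orth=n_orth,
        n_orth_effective=est.n_orth_effective_,
    )
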