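"""One-component PLS classification scored by cross-validated Q2 / DQ2
with a permutation null.

The classifier is the two-stage model used throughout the pipeline: an
O-PLS filter removes the dominant class-orthogonal component, then a
single-component PLS regression predicts the -1/+1 feeding-state label.
Model quality is the cross-validated

    Q2  = 1 - sum_k (y_k - yhat_k)^2 / sum_k (y_k - ybar)^2,

and its discriminant variant DQ2 in which each out-of-sample prediction is
first truncated to the label range, yhat'_k = clip(yhat_k, -1, +1), so a
correct prediction that overshoots its class label is not penalized.
Significance comes from refitting the whole pipeline on permuted labels
and evaluating the observed DQ2 against a normal fitted to the permuted
DQ2 values (two-tailed survival function).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .opls import OPLS, _validate_xy


class PLS1(RegressorMixin, BaseEstimator):
    """Single-component PLS1 regression of a single response on X.

    fit computes w ∝ X'y (unit norm) on the column-centred matrix, scores
    t = Xw, and regresses y on t by least squares; predict projects new
    rows through (centre, w, slope, intercept).
    """

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        self.x_mean_ = X.mean(axis=0)
        Xc = X - self.x_mean_
        if not np.any(Xc):
            raise ValueError("X has no variation")
        w = Xc.T @ y
        wn = np.linalg.norm(w)
        if wn == 0:
            # no covariance with y: degenerate but well-defined null model
            self.w_ = np.zeros(X.shape[1])
            self.b_ = 0.0
        else:
            self.w_ = w / wn
            t = Xc @ self.w_
            tt = t @ t
            self.b_ = float(t @ y / tt) if tt > 0 else 0.0
        self.intercept_ = float(y.mean())
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "w_")
        X = np.asarray(X, dtype=float)
        one_d = X.ndim == 1
        if one_d:
            X = X[np.newaxis, :]
        yhat = self.intercept_ + self.b_ * ((X - self.x_mean_) @ self.w_)
        return yhat[0] if one_d else yhat


def dq2_score(labels: np.ndarray, cv_predictions: np.ndarray) -> tuple[float, float]:
    """Return (Q2, DQ2) for -1/+1 labels and out-of-sample predictions."""
    y = np.asarray(labels, dtype=float).ravel()
    yhat = np.asarray(cv_predictions, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("labels and predictions differ in length")
    if not np.isin(y, (-1.0, 1.0)).all():
        raise ValueError("labels must be -1/+1")
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        raise ValueError("all labels identical: Q2 undefined")
    q2 = 1.0 - ((y - yhat) ** 2).sum() / tss
    yhat_trunc = np.clip(yhat, -1.0, 1.0)
    dq2 = 1.0 - ((y - yhat_trunc) ** 2).sum() / tss
    return float(q2), float(dq2)


def cv_predict(
    X: np.ndarray,
    y: np.ndarray,
    n_orth: int = 1,
    scheme: str = "loo",
) -> np.ndarray:
    """Leave-one-out predictions of the O-PLS + PLS1 pipeline.

    The O-PLS filter is refit inside every fold (on the training rows
    only) and the held-out row is passed through the training fold's
    orthogonal-component removal before prediction, so no information
    leaks from the held-out label.
    """
    X, y = _validate_xy(X, y)
    if scheme != "loo":
        raise ValueError(f"unsupported CV scheme: {scheme!r}")
    n = X.shape[0]
    for cls in (-1, 1):
        if (y == cls).sum() < 2:
            raise ValueError("need at least 2 samples per class for leave-one-out")
    yhat = np.empty(n)
    for k in range(n):
        mask = np.ones(n, dtype=bool)
        mask[k] = False
        Xtr, ytr = X[mask], y[mask]
        if n_orth > 0:
            filt = OPLS(n_orth=n_orth).fit(Xtr, ytr)
            Xtr_f = filt.X_filtered_
            x_held = filt.transform(X[k])
        else:
            Xtr_f, x_held = Xtr, X[k]
        model = PLS1().fit(Xtr_f, ytr)
        yhat[k] = model.predict(x_held)
    return yhat


@dataclass
class Dq2Result:
    """Observed Q2/DQ2 with the permutation null and its normal-fit p-value."""

    q2: float
    dq2: float
    cv_predictions: np.ndarray
    labels: np.ndarray
    perm_dq2: np.ndarray
    perm_mean: float
    perm_sd: float
    z: float
    p_value: float
    n_perm: int
    seed: int | None


def permutation_significance(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    n_orth: int = 1,
) -> Dq2Result:
    """Permutation test of the pipeline's DQ2.

    The labels are fully shuffled ``n_perm`` times; for each shuffle the
    complete O-PLS + PLS1 leave-one-out pipeline is re-run and its DQ2
    recorded. A normal is fitted to the permuted DQ2 values by their
    sample mean and SD; p = 2 * SF((|DQ2_obs - mean|)/SD), clamped to
    [0, 1]. A degenerate null (SD = 0) reports p = 1.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    X, y = _validate_xy(X, y)
    rng = np.random.default_rng(seed)
    yhat = cv_predict(X, y, n_orth=n_orth)
    q2, dq2 = dq2_score(y, yhat)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        yhat_p = cv_predict(X, yp, n_orth=n_orth)
        perm[i] = dq2_score(yp, yhat_p)[1]
    mean = float(perm.mean())
    sd = float(perm.std(ddof=1))
    if sd == 0:
        import logging

        logging.getLogger(__name__).warning("degenerate permutation null (SD=0); p=1")
        z, p = 0.0, 1.0
    else:
        z = (dq2 - mean) / sd
        p = float(min(1.0, max(0.0, 2.0 * stats.norm.sf(abs(z)))))
    return Dq2Result(
        q2=q2, dq2=dq2, cv_predictions=yhat, labels=y.copy(),
        perm_dq2=perm, perm_mean=mean, perm_sd=sd, z=float(z), p_value=p,
        n_perm=n_perm, seed=seed,
    )


def pls1_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Functional wrapper: returns (weight vector, regression scalar, intercept)."""
    m = PLS1().fit(X, y)
    return m.w_, m.b_, m.intercept_
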