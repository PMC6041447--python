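"""Shared single-kernel mixed-model machinery (eigen-rotation REML).

Model: y = X beta + u + e with u ~ N(0, sg2 * K) and e ~ N(0, se2 * I).
After rotating by the eigenvectors of K the covariance is diagonal,
sg2 * (D + delta * I) with delta = se2 / sg2, and the REML likelihood is
profiled down to a one-dimensional optimization over delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar


@dataclass
class MixedFit:
    delta: float          # se2 / sg2
    sg2: float
    se2: float
    beta: np.ndarray
    eigvals: np.ndarray
    U: np.ndarray
    reml_loglik: float

    @property
    def weights(self) -> np.ndarray:
        """1/sqrt(eigval + delta): whitening weights in the rotated basis."""
        return 1.0 / np.sqrt(self.eigvals + self.delta)


def _neg_reml(log_delta, yt, Xt, eigvals):
    delta = np.exp(log_delta)
    w = eigvals + delta
    n, p = Xt.shape
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    try:
        beta = np.linalg.solve(XtWX, Xw.T @ yt)
    except np.linalg.LinAlgError:
        return 1e300
    r = yt - Xt @ beta
    quad = float(r @ (r / w))
    if quad <= 0:
        return 1e300
    sg2 = quad / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return 1e300
    ll = -0.5 * (
        (n - p) * np.log(sg2)
        + np.sum(np.log(w))
        + logdet_xwx
        + (n - p)
    )
    return -ll


def fit_mixed(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> MixedFit:
    """REML fit of the one-kernel mixed model by spectral decomposition."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    eigvals, U = np.linalg.eigh(K)
    eigvals = np.clip(eigvals, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    res = minimize_scalar(
        _neg_reml,
        bounds=(np.log(1e-8), np.log(1e8)),
        args=(yt, Xt, eigvals),
        method="bounded",
        options={"xatol": 1e-10},
    )
    delta = float(np.exp(res.x))
    w = eigvals + delta
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yt)
    r = yt - Xt @ beta
    sg2 = float(r @ (r / w)) / (len(y) - X.shape[1])
    return MixedFit(
        delta=delta,
        sg2=sg2,
        se2=sg2 * delta,
        beta=beta,
        eigvals=eigvals,
        U=U,
        reml_loglik=-res.fun,
    )
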