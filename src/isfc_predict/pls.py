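"""Partial least squares regression with a univariate response (PLS1).

PLS1 finds latent components T = X W that sequentially maximize the squared
sample covariance with the response, subject to unit-norm weight vectors and
mutually uncorrelated scores. With a single response the NIPALS iteration
collapses to a closed form per component: the weight is the covariance
direction X_d' y of the current deflated predictor matrix. The y-loadings Q
come from ordinary least squares of y on T, and the regression vector on the
*original* (centered) predictors is

    beta = W (P' W)^{-1} Q

which maps the weights back through the deflated spaces so that predictions
from the original X reproduce the sequential fit exactly.

X and y are centered internally; variance scaling is deliberately left to the
caller (the feature pipeline standardizes within training folds), so there is
a single normalization site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_TOL = 1e-12


@dataclass
class PLSModel:
    """Fitted PLS1 model: weights, loadings, scores, and the beta vector."""

    W: np.ndarray        # p x k weights, unit-norm columns
    T: np.ndarray        # n x k latent scores (mutually uncorrelated)
    P: np.ndarray        # p x k X-loadings
    Q: np.ndarray        # k y-loadings
    beta: np.ndarray     # p regression vector on centered X
    x_means: np.ndarray
    y_mean: float
    k: int

    def to_json(self, path=None) -> str:
        payload = {
            "k": self.k, "y_mean": self.y_mean,
            "x_means": self.x_means.tolist(), "W": self.W.tolist(),
            "P": self.P.tolist(), "Q": self.Q.tolist(), "beta": self.beta.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PLSModel":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and \
            str(source).endswith(".json") else source
        d = json.loads(text)
        W = np.asarray(d["W"], float)
        return cls(W=W, T=np.empty((0, d["k"])), P=np.asarray(d["P"], float),
                   Q=np.asarray(d["Q"], float), beta=np.asarray(d["beta"], float),
                   x_means=np.asarray(d["x_means"], float),
                   y_mean=float(d["y_mean"]), k=int(d["k"]))


def fit_beta(Xc: np.ndarray, yc: np.ndarray, k: int) -> np.ndarray:
    """Regression vector for pre-centered inputs (fast path for CV loops)."""
    Xd = Xc.copy()
    p = Xc.shape[1]
    W = np.empty((p, k))
    P = np.empty((p, k))
    Q = np.empty(k)
    for i in range(k):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < _TOL:
            raise ValueError(
                f"no covariance left at component {i + 1}; reduce k")
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt < _TOL:
            raise ValueError(f"degenerate latent score at component {i + 1}")
        P[:, i] = Xd.T @ t / tt
        Q[i] = yc @ t / tt
        W[:, i] = w
        Xd -= np.outer(t, P[:, i])
    return W @ np.linalg.solve(P.T @ W, Q)


def fit_pls(X: np.ndarray, y: np.ndarray, k: int) -> PLSModel:
    """Fit a k-component PLS1 model.

    Requires 1 <= k <= min(n - 1, p) and a non-constant response (a constant
    y has zero covariance with every direction, so no weight is defined).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y disagree on the number of samples")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    k_max = min(n - 1, p)
    if not (1 <= k <= k_max):
        raise ValueError(f"k must be in [1, {k_max}] for this problem size")
    x_means = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_means
    yc = y - y_mean
    if np.max(np.abs(yc)) < _TOL:
        raise ValueError("y is constant; PLS direction undefined")

    Xd = Xc.copy()
    W = np.empty((p, k))
    P = np.empty((p, k))
    Q = np.empty(k)
    T = np.empty((n, k))
    for i in range(k):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < _TOL:
            raise ValueError(f"no covariance left at component {i + 1}; reduce k")
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt < _TOL:
            raise ValueError(f"degenerate latent score at component {i + 1}")
        W[:, i] = w
        T[:, i] = t
        P[:, i] = Xd.T @ t / tt
        Q[i] = yc @ t / tt
        Xd -= np.outer(t, P[:, i])

    beta = W @ np.linalg.solve(P.T @ W, Q)
    return PLSModel(W=W, T=T, P=P, Q=Q, beta=beta, x_means=x_means,
                    y_mean=y_mean, k=k)


def predict_pls(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted response: (X_new - x_means) @ beta + y_mean."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.beta.shape[0]:
        raise ValueError(
            f"X_new must have {model.beta.shape[0]} columns, got {X_new.shape}")
    return (X_new - model.x_means) @ model.beta + model.y_mean
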