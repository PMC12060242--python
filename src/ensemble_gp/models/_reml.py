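"""Closed-form mixed-model machinery shared by the ridge and kernel models.

Model: y = W f + g + e with g ~ N(0, sg2 * K), e ~ N(0, se2 * I).
The variance ratio delta = se2/sg2 is estimated by maximizing the restricted
likelihood on the eigenbasis of K, after which BLUPs are a single solve.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


class MixedModelSolution:
    """Eigen-based solver state for y = W f + g + e at a given delta."""

    def __init__(self, y, K, W, delta, U, S):
        self.delta = float(delta)
        self.U = U
        self.S = S
        d = S + delta
        yt = U.T @ y
        Wt = U.T @ W
        A = Wt.T @ (Wt / d[:, None])
        b = Wt.T @ (yt / d)
        self.fixed_effects = np.linalg.solve(A, b)
        r = yt - Wt @ self.fixed_effects
        n, q = len(y), W.shape[1]
        self.sigma_g2 = float(r @ (r / d)) / (n - q)
        self.sigma_e2 = self.delta * self.sigma_g2
        # H^{-1}(y - W f) with H = K + delta*I, kept for BLUP back-solves
        self.Hinv_resid = U @ (r / d)


def _neg_reml(log10_delta, yt, Wt, S, n, q):
    d = S + 10.0 ** log10_delta
    A = Wt.T @ (Wt / d[:, None])
    b = Wt.T @ (yt / d)
    try:
        f = np.linalg.solve(A, b)
        _, logdet_A = np.linalg.slogdet(A)
    except np.linalg.LinAlgError:
        return np.inf
    r = yt - Wt @ f
    rss = float(r @ (r / d))
    if rss <= 0:
        return np.inf
    sigma_g2 = rss / (n - q)
    ll = -0.5 * ((n - q) * np.log(sigma_g2) + np.sum(np.log(d))
                 + logdet_A + (n - q))
    return -ll


def fit_mixed_model(y: np.ndarray, K: np.ndarray, W: np.ndarray,
                    delta: float | None = None,
                    log10_bounds=(-6.0, 6.0)) -> MixedModelSolution:
    """REML-fit the variance ratio (unless ``delta`` is fixed) and solve.

    ``W`` is the fixed-effect design (must include the intercept column).
    """
    y = np.asarray(y, dtype=float)
    K = np.asarray(K, dtype=float)
    W = np.asarray(W, dtype=float)
    S, U = np.linalg.eigh(K)
    S = np.clip(S, 0.0, None)
    if delta is None:
        yt = U.T @ y
        Wt = U.T @ W
        n, q = len(y), W.shape[1]
        res = minimize_scalar(_neg_reml, bounds=log10_bounds, method="bounded",
                              args=(yt, Wt, S, n, q),
                              options={"xatol": 1e-6})
        delta = 10.0 ** res.x
    return MixedModelSolution(y, K, W, delta, U, S)
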