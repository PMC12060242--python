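"""Gaussian-kernel regression (RKHS) with REML-estimated regularization."""

from __future__ import annotations

import numpy as np

from ..errors import InvalidParameterError
from ._reml import fit_mixed_model
from .base import FittedModel, RKHSParams, default_hyper, register
from .linear import _Y_CONST_TOL, _split_design


def mean_sq_dist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Mean squared dosage distance between rows of A and rows of B."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    sq = (np.sum(A * A, axis=1)[:, None] + np.sum(B * B, axis=1)[None, :]
          - 2.0 * A @ B.T)
    return np.clip(sq, 0.0, None) / A.shape[1]


def gaussian_kernel(A: np.ndarray, B: np.ndarray, bandwidth: float) -> np.ndarray:
    """K(u, v) = exp(-h * d2(u, v)) on the mean squared distance scale."""
    if bandwidth <= 0:
        raise InvalidParameterError("bandwidth must be > 0")
    return np.exp(-bandwidth * mean_sq_dist(A, B))


def median_heuristic_bandwidth(Z: np.ndarray) -> float:
    """h = 1 / median off-diagonal pairwise mean squared distance."""
    D = mean_sq_dist(Z, Z)
    off = D[np.triu_indices_from(D, k=1)]
    med = float(np.median(off[off > 0])) if np.any(off > 0) else 1.0
    return 1.0 / med


class RKHSState:
    def __init__(self, Z_train, bandwidth, alpha, mu, fixed_cols, fixed_coefs,
                 extras=None):
        self.Z_train = Z_train
        self.bandwidth = float(bandwidth)
        self.alpha = alpha          # H^{-1} residual, kernel coefficients
        self.mu = float(mu)
        self.fixed_cols = tuple(fixed_cols)
        self.fixed_coefs = np.asarray(fixed_coefs, dtype=float)
        self.extras = extras or {}

    def _predict(self, X):
        rand_cols = [j for j in range(X.shape[1]) if j not in self.fixed_cols]
        Kx = gaussian_kernel(X[:, rand_cols], self.Z_train, self.bandwidth)
        out = self.mu + Kx @ self.alpha
        for c, f in zip(self.fixed_cols, self.fixed_coefs):
            out = out + f * X[:, c]
        return out


@register("rkhs")
def fit_rkhs(X, y, hyper: RKHSParams | None = None, seed: int = 0) -> FittedModel:
    """Kernel regression on the Gaussian kernel of marker dosages.

    The regularization level (variance ratio) is estimated by REML on the
    kernel eigenbasis; test-row predictions use the cross kernel against the
    training rows.
    """
    hyper = hyper or default_hyper("rkhs")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0] or len(y) < 2:
        raise InvalidParameterError("X/y shapes invalid or n < 2")
    if hyper.bandwidth is not None and hyper.bandwidth <= 0:
        raise InvalidParameterError("bandwidth must be > 0")
    Z, W, rand_cols, fixed_cols = _split_design(X, hyper.fixed_cols)
    if np.std(y) < _Y_CONST_TOL:
        state = RKHSState(Z, hyper.bandwidth or 1.0, np.zeros(len(y)),
                          float(np.mean(y)), (), ())
        return FittedModel(kind="rkhs", state=state, n_features=X.shape[1],
                           hyper=hyper, seed=seed)
    h = hyper.bandwidth if hyper.bandwidth is not None else \
        median_heuristic_bandwidth(Z)
    K = gaussian_kernel(Z, Z, h)
    sol = fit_mixed_model(y, K, W)
    mu, *fcoef = sol.fixed_effects
    state = RKHSState(Z, h, sol.Hinv_resid, mu, fixed_cols, fcoef,
                      extras={"delta": sol.delta, "sigma_g2": sol.sigma_g2,
                              "sigma_e2": sol.sigma_e2})
    return FittedModel(kind="rkhs", state=state, n_features=X.shape[1],
                       hyper=hyper, seed=seed)
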