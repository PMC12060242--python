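"""Ridge-BLUP and spike-and-slab (BayesB-style) marker-effect models.

The ridge model shrinks every marker effect equally (beta_j ~ N(0, s2*I));
the default fit is the deterministic REML closed form, with an optional Gibbs
sampler matching the MCMC configuration (12,000 iterations, 2,000 burn-in).
The spike-and-slab model gives each marker a point mass at zero with unknown
inclusion probability and a scaled-t slab via per-marker variances.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..errors import InvalidParameterError
from ._reml import fit_mixed_model
from .base import (BayesBParams, FittedModel, RRBlupParams, default_hyper,
                   register)

_Y_CONST_TOL = 1e-12


class LinearState:
    """Intercept + fixed-effect coefficients + per-marker effects."""

    def __init__(self, mu, beta, fixed_cols=(), fixed_coefs=(),
                 extras=None):
        self.mu = float(mu)
        self.beta = np.asarray(beta, dtype=float)
        self.fixed_cols = tuple(fixed_cols)
        self.fixed_coefs = np.asarray(fixed_coefs, dtype=float)
        self.extras = extras or {}

    def _predict(self, X):
        rand_cols = [j for j in range(X.shape[1]) if j not in self.fixed_cols]
        out = self.mu + X[:, rand_cols] @ self.beta
        for c, f in zip(self.fixed_cols, self.fixed_coefs):
            out = out + f * X[:, c]
        return out

    def full_effects(self, n_features):
        """Marker effects on the original column grid (fixed cols -> nan)."""
        eff = np.full(n_features, np.nan)
        rand_cols = [j for j in range(n_features) if j not in self.fixed_cols]
        eff[rand_cols] = self.beta
        return eff


def _split_design(X, fixed_cols):
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    fixed_cols = tuple(fixed_cols)
    rand_cols = [j for j in range(X.shape[1]) if j not in fixed_cols]
    W = np.column_stack([np.ones(n)] + [X[:, c] for c in fixed_cols])
    return X[:, rand_cols], W, rand_cols, fixed_cols


def _constant_fallback(kind, X, y, hyper, seed):
    warnings.warn(f"{kind}: response is constant; returning mean predictor")
    state = LinearState(mu=float(np.mean(y)), beta=np.zeros(X.shape[1]))
    return FittedModel(kind=kind, state=state, n_features=X.shape[1],
                       hyper=hyper, seed=seed)


@register("rrblup")
def fit_rrblup(X, y, hyper: RRBlupParams | None = None, seed: int = 0) -> FittedModel:
    """Equal-shrinkage ridge BLUP with data-estimated shrinkage.

    method="reml" (default) profiles the restricted likelihood for the
    variance ratio; method="fixed" uses ``hyper.lambda_`` directly (and then
    equals the explicit ridge closed form); method="mcmc" runs a Gibbs chain.
    """
    hyper = hyper or default_hyper("rrblup")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0] or len(y) < 2:
        raise InvalidParameterError("X/y shapes invalid or n < 2")
    if np.std(y) < _Y_CONST_TOL:
        return _constant_fallback("rrblup", X, y, hyper, seed)
    Z, W, rand_cols, fixed_cols = _split_design(X, hyper.fixed_cols)

    if hyper.method in ("reml", "fixed"):
        delta = None
        if hyper.method == "fixed":
            if hyper.lambda_ is None or hyper.lambda_ <= 0:
                raise InvalidParameterError("method='fixed' requires lambda_ > 0")
            delta = float(hyper.lambda_)
        sol = fit_mixed_model(y, Z @ Z.T, W, delta=delta)
        beta = Z.T @ sol.Hinv_resid
        mu, *fcoef = sol.fixed_effects
        state = LinearState(mu, beta, fixed_cols, fcoef,
                            extras={"delta": sol.delta, "sigma_g2": sol.sigma_g2,
                                    "sigma_e2": sol.sigma_e2})
    elif hyper.method == "mcmc":
        if hyper.n_iter <= hyper.burn_in or hyper.burn_in < 0:
            raise InvalidParameterError("need n_iter > burn_in >= 0")
        state = _gibbs_ridge(Z, W, y, hyper, seed)
        state.fixed_cols = fixed_cols
    else:
        raise InvalidParameterError(f"unknown rrblup method {hyper.method!r}")
    return FittedModel(kind="rrblup", state=state, n_features=X.shape[1],
                       hyper=hyper, seed=seed)


def _scaled_inv_chi2(rng, df, scale):
    return df * scale / rng.chisquare(df)


def _gibbs_ridge(Z, W, y, hyper, seed):
    """Gibbs sampler for the common-variance ridge prior (flat fixed effects)."""
    rng = np.random.default_rng(seed)
    n, p = Z.shape
    q = W.shape[1]
    cjj = np.einsum("ij,ij->j", Z, Z)
    wjj = np.einsum("ij,ij->j", W, W)
    var_y = float(np.var(y))
    msx = float(np.sum(np.var(Z, axis=0))) or 1.0
    df_b, df_e, r2 = 5.0, 5.0, 0.5
    S_b = r2 * var_y / msx * (df_b + 2.0) / df_b
    S_e = (1.0 - r2) * var_y * (df_e + 2.0) / df_e
    beta = np.zeros(p)
    fcoef = np.zeros(q)
    sigma_b2, sigma_e2 = S_b, S_e
    e = y.copy()
    beta_sum = np.zeros(p)
    f_sum = np.zeros(q)
    kept = 0
    for it in range(hyper.n_iter):
        for k in range(q):
            if wjj[k] < 1e-12:
                continue
            rhs = W[:, k] @ e + wjj[k] * fcoef[k]
            new = rng.normal(rhs / wjj[k], np.sqrt(sigma_e2 / wjj[k]))
            e -= W[:, k] * (new - fcoef[k])
            fcoef[k] = new
        for j in range(p):
            if cjj[j] < 1e-12:
                continue
            rhs = Z[:, j] @ e + cjj[j] * beta[j]
            c_post = cjj[j] + sigma_e2 / sigma_b2
            new = rng.normal(rhs / c_post, np.sqrt(sigma_e2 / c_post))
            e -= Z[:, j] * (new - beta[j])
            beta[j] = new
        sigma_b2 = _scaled_inv_chi2(rng, df_b + p,
                                    (beta @ beta + df_b * S_b) / (df_b + p))
        sigma_e2 = _scaled_inv_chi2(rng, df_e + n,
                                    (e @ e + df_e * S_e) / (df_e + n))
        if it >= hyper.burn_in:
            beta_sum += beta
            f_sum += fcoef
            kept += 1
    f_mean = f_sum / kept
    return LinearState(f_mean[0], beta_sum / kept, (), f_mean[1:],
                       extras={"sigma_e2": sigma_e2})


@register("bayesb")
def fit_bayesb(X, y, hyper: BayesBParams | None = None, seed: int = 0) -> FittedModel:
    """Gibbs sampler over a spike-and-slab per-marker prior.

    Each marker is null with probability 1-pi (point mass at zero) or drawn
    from a normal slab with its own scaled-inv-chi2 variance (a scaled-t
    marginal); pi itself carries a Beta prior and is updated from the
    inclusion counts. Posterior-mean effects are returned.
    """
    hyper = hyper or default_hyper("bayesb")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0] or len(y) < 2:
        raise InvalidParameterError("X/y shapes invalid or n < 2")
    if hyper.n_iter <= hyper.burn_in or hyper.burn_in < 0:
        raise InvalidParameterError("need n_iter > burn_in >= 0")
    if np.std(y) < _Y_CONST_TOL:
        return _constant_fallback("bayesb", X, y, hyper, seed)
    Z, W, rand_cols, fixed_cols = _split_design(X, hyper.fixed_cols)
    rng = np.random.default_rng(seed)
    n, p = Z.shape
    q = W.shape[1]
    cjj = np.einsum("ij,ij->j", Z, Z)
    wjj = np.einsum("ij,ij->j", W, W)
    var_y = float(np.var(y))
    msx = float(np.sum(np.var(Z, axis=0))) or 1.0
    df_b, df_e = hyper.df_effect, hyper.df_resid
    # slab scale: prior mode of sigma_j2 explains r2*var(y) via pi0*p markers
    mode_b = hyper.r2 * var_y / max(hyper.pi0 * msx, 1e-12)
    S_b = mode_b * (df_b + 2.0) / df_b
    S_e = (1.0 - hyper.r2) * var_y * (df_e + 2.0) / df_e
    a_pi = hyper.pi_counts * hyper.pi0
    b_pi = hyper.pi_counts * (1.0 - hyper.pi0)

    beta = np.zeros(p)
    delta = np.zeros(p, dtype=bool)
    sigma_j2 = np.full(p, S_b)
    fcoef = np.zeros(q)
    pi = hyper.pi0
    sigma_e2 = S_e
    e = y.copy()
    beta_sum = np.zeros(p)
    incl_sum = np.zeros(p)
    f_sum = np.zeros(q)
    kept = 0
    for it in range(hyper.n_iter):
        for k in range(q):
            if wjj[k] < 1e-12:
                continue
            rhs = W[:, k] @ e + wjj[k] * fcoef[k]
            new = rng.normal(rhs / wjj[k], np.sqrt(sigma_e2 / wjj[k]))
            e -= W[:, k] * (new - fcoef[k])
            fcoef[k] = new
        for j in range(p):
            if cjj[j] < 1e-12:
                continue
            old = beta[j] if delta[j] else 0.0
            rhs = Z[:, j] @ e + cjj[j] * old
            # marginal likelihood ratio for inclusion, beta_j integrated out
            v0 = sigma_e2 * cjj[j]
            v1 = v0 + sigma_j2[j] * cjj[j] ** 2
            log_odds = (np.log(pi) - np.log1p(-pi)
                        + 0.5 * (np.log(v0) - np.log(v1))
                        + 0.5 * rhs * rhs * (1.0 / v0 - 1.0 / v1))
            incl = rng.random() < 1.0 / (1.0 + np.exp(-log_odds))
            if incl:
                c_post = cjj[j] + sigma_e2 / sigma_j2[j]
                new = rng.normal(rhs / c_post, np.sqrt(sigma_e2 / c_post))
            else:
                new = 0.0
            e -= Z[:, j] * (new - old)
            beta[j] = new
            delta[j] = incl
        n_in = int(delta.sum())
        pi = rng.beta(a_pi + n_in, b_pi + p - n_in)
        pi = min(max(pi, 1e-6), 1.0 - 1e-6)
        b2 = np.where(delta, beta ** 2, 0.0)
        sigma_j2 = (df_b * S_b + b2) / rng.chisquare(df_b + delta, size=p)
        sigma_e2 = _scaled_inv_chi2(rng, df_e + n,
                                    (e @ e + df_e * S_e) / (df_e + n))
        if it >= hyper.burn_in:
            beta_sum += np.where(delta, beta, 0.0)
            incl_sum += delta
            f_sum += fcoef
            kept += 1
    f_mean = f_sum / kept
    state = LinearState(f_mean[0], beta_sum / kept, fixed_cols, f_mean[1:],
                        extras={"inclusion": incl_sum / kept, "pi": pi,
                                "sigma_e2": sigma_e2})
    return FittedModel(kind="bayesb", state=state, n_features=X.shape[1],
                       hyper=hyper, seed=seed)
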