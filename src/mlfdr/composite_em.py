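"""Composite-alternative mixture model and the two-step EM.

When the non-null effects themselves come from Gaussian mixtures, the scaled
estimates follow

    sqrt(n) alpha_hat_i ~ sum_u pi_{u.} N(mu_u, sigma_i1^2 + kappa_u)
    sqrt(n) beta_hat_i  ~ sum_v pi_{.v} N(theta_v, sigma_i2^2 + psi_v)

with component 0 pinned at the null (mu_0 = kappa_0 = 0).  Fitting the full
(d1+1)(d2+1)-component bivariate mixture at once is expensive, so estimation
is split: step 1 fits each univariate margin by EM (moments and marginal
weights); step 2 freezes all means and variances and re-estimates only the
joint proportion table pi_uv by a restricted EM whose M-step is a plain
responsibility average.  Model size per margin is chosen by AIC with
parameter count 3d (d free means, d extra variances, d free weights).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .mixture_em import (
    COLLAPSE_TOL,
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    PI_FLOOR,
    _update_mean_var,
)
from .regress import CoefSummary

__all__ = [
    "MarginalMixture",
    "CompositePrior",
    "fit_marginal_gmm",
    "select_components_aic",
    "fit_joint_proportions",
    "fit_composite",
]


@dataclass
class MarginalMixture:
    """One margin of the composite model: d+1 components, component 0 null."""

    weights: np.ndarray  # length d+1, sums to 1
    means: np.ndarray  # length d+1, means[0] == 0
    extra_vars: np.ndarray  # length d+1, extra_vars[0] == 0
    loglik: float = float("nan")
    converged: bool = True

    @property
    def d(self) -> int:
        return len(self.weights) - 1


@dataclass
class CompositePrior:
    """Joint composite prior: frozen marginal moments + joint proportions."""

    mu: np.ndarray  # length d1+1, a-margin means (mu[0]=0)
    kappa: np.ndarray  # length d1+1, a-margin extra variances
    theta: np.ndarray  # length d2+1, b-margin means
    psi: np.ndarray  # length d2+1, b-margin extra variances
    pi: np.ndarray  # (d1+1) x (d2+1) joint proportions
    marginal_weights_a: np.ndarray = field(default_factory=lambda: np.array([]))
    marginal_weights_b: np.ndarray = field(default_factory=lambda: np.array([]))
    loglik_step1_a: float = float("nan")
    loglik_step1_b: float = float("nan")
    loglik_path: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("joint proportions must sum to 1")

    @property
    def d1(self) -> int:
        return len(self.mu) - 1

    @property
    def d2(self) -> int:
        return len(self.theta) - 1

    @property
    def loglik(self) -> float:
        return float(self.loglik_path[-1]) if len(self.loglik_path) else float("nan")

    def to_json(self, path) -> None:
        payload = {
            "model": "composite",
            "mu": list(map(float, self.mu)),
            "kappa": list(map(float, self.kappa)),
            "theta": list(map(float, self.theta)),
            "psi": list(map(float, self.psi)),
            "pi": [list(map(float, row)) for row in self.pi],
            "loglik": self.loglik,
            "converged": bool(self.converged),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CompositePrior":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            mu=np.array(p["mu"]),
            kappa=np.array(p["kappa"]),
            theta=np.array(p["theta"]),
            psi=np.array(p["psi"]),
            pi=np.array(p["pi"]),
            loglik_path=np.array([p.get("loglik", np.nan)]),
            converged=p.get("converged", True),
        )


def _marginal_logdens(
    values: np.ndarray, variances: np.ndarray, means: np.ndarray, extra: np.ndarray
) -> np.ndarray:
    """m x (d+1) per-component log densities with heteroscedastic base vars."""
    tot = variances[:, None] + extra[None, :]
    return -0.5 * (np.log(2 * np.pi * tot) + (values[:, None] - means[None, :]) ** 2 / tot)


def _marginal_loglik(values, variances, weights, means, extra) -> float:
    logd = _marginal_logdens(values, variances, means, extra) + np.log(
        np.maximum(weights, 1e-300)
    )
    return float(np.sum(logsumexp(logd, axis=1)))


def fit_marginal_gmm(
    values: np.ndarray,
    variances: np.ndarray,
    d: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    n_restarts: int = 1,
    seed: int = 0,
) -> MarginalMixture:
    """EM fit of the (d+1)-component univariate margin, component 0 pinned null.

    Non-null component moments use the same alternating mean/extra-variance
    update as the simple model.  The default single start is the
    deterministic quantile-based one: with heavily overlapped components the
    likelihood is nearly flat in the weights, and jittered restarts can land
    on likelihood-equivalent but poorly identified configurations, so extra
    restarts are opt-in.
    """
    values = np.asarray(values, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if d < 1:
        raise ValueError("d must be >= 1")
    if len(values) < 10 * d:
        raise ValueError("need at least 10*d observations")
    rng = np.random.default_rng(seed)

    best: Optional[MarginalMixture] = None
    for r in range(max(n_restarts, 1)):
        w, mu, ev = _marginal_init(values, variances, d, rng, jitter=(r > 0))
        fit = _marginal_em_single(values, variances, w, mu, ev, tol, max_iter)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    if not best.converged:
        warnings.warn("marginal EM did not converge; returning best iterate")
    # fold components indistinguishable from the null (boundary
    # non-identifiability) back into component 0
    vbar = float(np.mean(variances))
    w, mu, ev = best.weights.copy(), best.means.copy(), best.extra_vars.copy()
    for u in range(1, len(w)):
        if (mu[u] ** 2 + ev[u]) / vbar < COLLAPSE_TOL:
            w[0] += w[u]
            w[u] = 0.0
    w = np.maximum(w, PI_FLOOR)
    w /= w.sum()
    return MarginalMixture(weights=w, means=mu, extra_vars=ev, loglik=best.loglik,
                           converged=best.converged)


def _marginal_init(values, variances, d, rng, jitter=False):
    w = np.full(d + 1, 0.4 / d)
    w[0] = 0.6
    # spread initial non-null means over outer quantiles of the data
    qs = np.linspace(0.05, 0.95, d + 2)[1:-1]
    mu = np.concatenate([[0.0], np.quantile(values, qs)])
    if d == 1:
        # single component: use the trimmed top-decile mean as in the simple model
        k = max(int(0.1 * len(values)), 1)
        mu[1] = float(np.mean(values[np.argsort(np.abs(values))[-k:]]))
    ev = np.concatenate(
        [[0.0], np.full(d, max(float(np.var(values) - np.mean(variances)), 0.1))]
    )
    if jitter:
        mu[1:] = mu[1:] + 0.3 * np.abs(mu[1:]).mean() * rng.standard_normal(d)
        ev[1:] = ev[1:] * rng.uniform(0.5, 2.0, size=d)
        logits = np.log(w) + 0.5 * rng.standard_normal(d + 1)
        w = np.exp(logits - logits.max())
        w /= w.sum()
    return w, mu, ev


def _marginal_em_single(values, variances, w, mu, ev, tol, max_iter):
    ll_old = -np.inf
    converged = False
    ll = -np.inf
    for _ in range(max_iter):
        logd = _marginal_logdens(values, variances, mu, ev) + np.log(
            np.maximum(w, 1e-300)
        )
        row = logsumexp(logd, axis=1)
        ll = float(np.sum(row))
        if ll - ll_old < tol * (abs(ll_old) + 1.0) and np.isfinite(ll_old):
            converged = True
            break
        ll_old = ll
        resp = np.exp(logd - row[:, None])
        w = resp.mean(axis=0)
        if np.any(w < PI_FLOOR):
            w = np.maximum(w, PI_FLOOR)
            w /= w.sum()
        for u in range(1, len(mu)):
            mu[u], ev[u] = _update_mean_var(values, variances, resp[:, u], mu[u], ev[u])
    return MarginalMixture(
        weights=w.copy(), means=mu.copy(), extra_vars=ev.copy(), loglik=ll,
        converged=converged,
    )


def select_components_aic(
    values: np.ndarray,
    variances: np.ndarray,
    d_max: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> int:
    """Pick the number of non-null components d in 1..d_max by AIC.

    AIC(d) = 2 * 3d - 2 * loglik(d); the free parameters per non-null
    component are a mean, an extra variance, and a weight.  Ties break to the
    smaller d; a failed member fit is skipped with a warning.
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    best_d, best_aic = None, np.inf
    for d in range(1, d_max + 1):
        try:
            fit = fit_marginal_gmm(values, variances, d, tol=tol, max_iter=max_iter,
                                   seed=seed)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"marginal fit with d={d} failed: {exc}")
            continue
        aic = 2 * 3 * d - 2 * fit.loglik
        if aic < best_aic - 1e-9:
            best_aic, best_d = aic, d
    if best_d is None:
        raise RuntimeError("all candidate component counts failed to fit")
    return best_d


def fit_joint_proportions(
    summary: CoefSummary,
    margin_a: MarginalMixture,
    margin_b: MarginalMixture,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CompositePrior:
    """Step-2 EM: freeze all moments, estimate only the joint table pi_uv.

    The per-component bivariate log densities factorize and are precomputed
    once; each EM sweep is a softmax E-step plus an averaging M-step.  The
    start is the independence table (outer product of marginal weights).
    """
    la = _marginal_logdens(summary.a, summary.var1, margin_a.means, margin_a.extra_vars)
    lb = _marginal_logdens(summary.b, summary.var2, margin_b.means, margin_b.extra_vars)
    # m x (d1+1) x (d2+1)
    logf = la[:, :, None] + lb[:, None, :]
    K1, K2 = la.shape[1], lb.shape[1]
    m = summary.m
    logf_flat = logf.reshape(m, K1 * K2)

    pi = np.outer(margin_a.weights, margin_b.weights).reshape(-1)
    ll_old = -np.inf
    path = []
    converged = False
    for _ in range(max_iter):
        logd = logf_flat + np.log(np.maximum(pi, 1e-300))
        row = logsumexp(logd, axis=1)
        ll = float(np.sum(row))
        path.append(ll)
        if ll - ll_old < tol * (abs(ll_old) + 1.0) and np.isfinite(ll_old):
            converged = True
            break
        ll_old = ll
        resp = np.exp(logd - row[:, None])
        pi = resp.mean(axis=0)
        if np.any(pi < PI_FLOOR):
            pi = np.maximum(pi, PI_FLOOR)
            pi /= pi.sum()
    if not converged:
        warnings.warn("joint-proportion EM did not converge; returning best iterate")
    return CompositePrior(
        mu=margin_a.means,
        kappa=margin_a.extra_vars,
        theta=margin_b.means,
        psi=margin_b.extra_vars,
        pi=pi.reshape(K1, K2),
        marginal_weights_a=margin_a.weights,
        marginal_weights_b=margin_b.weights,
        loglik_step1_a=margin_a.loglik,
        loglik_step1_b=margin_b.loglik,
        loglik_path=np.asarray(path),
        converged=converged,
    )


def fit_composite(
    summary: CoefSummary,
    d1: int | str = "auto",
    d2: int | str = "auto",
    d_max: int = 10,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
) -> CompositePrior:
    """Full two-step pipeline: marginal fits (with optional AIC selection of
    d1/d2) followed by the joint-proportion EM."""
    if d1 == "auto":
        d1 = select_components_aic(summary.a, summary.var1, d_max, seed=seed)
    if d2 == "auto":
        d2 = select_components_aic(summary.b, summary.var2, d_max, seed=seed)
    ma = fit_marginal_gmm(summary.a, summary.var1, int(d1), tol=tol,
                          max_iter=max_iter, seed=seed)
    mb = fit_marginal_gmm(summary.b, summary.var2, int(d2), tol=tol,
                          max_iter=max_iter, seed=seed + 1)
    return fit_joint_proportions(summary, ma, mb, tol=tol, max_iter=max_iter)
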