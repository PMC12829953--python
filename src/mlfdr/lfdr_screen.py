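"""Composite-null local FDR and the lfdr-based step-up procedure.

The local FDR of unit i is the posterior probability that the composite null
alpha_i * beta_i = 0 holds given (a_i, b_i):

    lfdr(a_i, b_i) = [pi00 f00 + pi10 f10 + pi01 f01] / f,

where f is the full mixture density.  Under the composite-alternative model
the null mass generalizes to every component with a zero mean on either
margin (u = 0 or v = 0).  The rejection region {lfdr <= delta} is thresholded
adaptively: sort the lfdr values ascending and reject the largest prefix
whose running mean stays at or below the nominal level alpha.  The running
mean of the k smallest lfdr values is an estimate of the marginal FDR of
rejecting exactly those k hypotheses, so the procedure is a plug-in step-up
rule; `threshold_sup_form` evaluates the equivalent sup-over-thresholds
formulation and exists to cross-check `step_up`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.special import logsumexp

from .composite_em import CompositePrior, _marginal_logdens
from .mixture_em import MixturePrior, _component_logdens
from .regress import CoefSummary

__all__ = [
    "LfdrScreenResult",
    "OracleDiagnostics",
    "compute_lfdr",
    "step_up",
    "threshold_sup_form",
    "oracle_diagnostics",
    "screen",
]

DENSITY_FLOOR = 1e-300


@dataclass
class LfdrScreenResult:
    """Outcome of the lfdr screen at nominal level alpha."""

    lfdr: np.ndarray
    order: np.ndarray  # permutation sorting lfdr ascending
    running_mean: np.ndarray  # running_mean[k-1] = mean of k smallest lfdr
    k_reject: int
    delta_hat: float
    rejected: np.ndarray  # boolean flags in original unit order
    alpha: float

    @property
    def n_reject(self) -> int:
        return self.k_reject


@dataclass
class OracleDiagnostics:
    """Counting processes on a threshold grid, given simulation truth."""

    grid: np.ndarray
    Vm: np.ndarray  # false rejections
    Rm: np.ndarray  # total rejections
    Pm: np.ndarray  # missed true alternatives
    Wm: np.ndarray  # sum of lfdr over rejections
    G: np.ndarray  # empirical CDF of lfdr
    G_jk: dict  # empirical CDF within each latent stratum
    Q_tilde: np.ndarray  # plug-in mFDR Vm/Rm (0 where Rm = 0)


def compute_lfdr(
    summary: CoefSummary, prior: Union[MixturePrior, CompositePrior]
) -> np.ndarray:
    """Posterior null probability per unit, computed in log-space.

    Accepts either the simple four-component prior or a composite prior; the
    composite case reduces exactly to the simple one when d1 = d2 = 1 with
    matching parameters.
    """
    if isinstance(prior, MixturePrior):
        logd = _component_logdens(summary, prior) + np.log(
            np.maximum(prior.pi, DENSITY_FLOOR)
        )
        null_cols = [0, 1, 2]  # (0,0), (1,0), (0,1)
        log_null = logsumexp(logd[:, null_cols], axis=1)
        log_all = logsumexp(logd, axis=1)
    else:
        la = _marginal_logdens(summary.a, summary.var1, prior.mu, prior.kappa)
        lb = _marginal_logdens(summary.b, summary.var2, prior.theta, prior.psi)
        logf = la[:, :, None] + lb[:, None, :] + np.log(
            np.maximum(prior.pi, DENSITY_FLOOR)
        )[None, :, :]
        m = summary.m
        K1, K2 = prior.pi.shape
        flat = logf.reshape(m, K1 * K2)
        null_mask = np.zeros((K1, K2), dtype=bool)
        null_mask[0, :] = True
        null_mask[:, 0] = True
        log_null = logsumexp(flat[:, null_mask.reshape(-1)], axis=1)
        log_all = logsumexp(flat, axis=1)
    if not (np.all(np.isfinite(log_all)) and np.all(np.isfinite(log_null))):
        bad = int(np.argmax(~(np.isfinite(log_all) & np.isfinite(log_null))))
        raise ValueError(f"non-finite lfdr statistic for unit {summary.unit_ids[bad]!r}")
    return np.clip(np.exp(log_null - log_all), 0.0, 1.0)


def step_up(
    lfdr: np.ndarray,
    alpha: float,
    tie_break: str = "group",
    seed: Optional[int] = None,
) -> LfdrScreenResult:
    """Adaptive step-up: reject the largest prefix of sorted lfdr values whose
    running mean is <= alpha.

    With the default ``tie_break="group"`` the cutoff index may only fall on
    a tie-group boundary, so equal lfdr values at the threshold are either
    all rejected or none — the rejection set is exactly {lfdr <= delta_hat}
    and coincides with the sup-over-thresholds rule on every input,
    including ties.  ``tie_break="random"`` instead applies the raw prefix
    rule after a seeded random shuffle of tied values, which can split a tie
    group.  For distinct lfdr values (the almost-sure case with continuous
    statistics) the two variants are identical.
    """
    lfdr = np.asarray(lfdr, dtype=float)
    if np.any((lfdr < 0) | (lfdr > 1)) or not np.all(np.isfinite(lfdr)):
        raise ValueError("lfdr values must lie in [0, 1]")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if tie_break not in ("group", "random"):
        raise ValueError("tie_break must be 'group' or 'random'")
    m = len(lfdr)
    if tie_break == "random":
        rng = np.random.default_rng(seed)
        jitter = rng.random(m)
        order = np.lexsort((jitter, lfdr))
    else:
        order = np.argsort(lfdr, kind="stable")
    sorted_vals = lfdr[order]
    running = np.cumsum(sorted_vals) / np.arange(1, m + 1)
    feasible = running <= alpha
    if tie_break == "group":
        # k may only stop where the next value is strictly larger
        boundary = np.empty(m, dtype=bool)
        boundary[:-1] = sorted_vals[:-1] < sorted_vals[1:]
        boundary[-1] = True
        feasible &= boundary
    ok = np.nonzero(feasible)[0]
    k = int(ok[-1]) + 1 if len(ok) else 0
    delta_hat = float(sorted_vals[k - 1]) if k > 0 else 0.0
    rejected = np.zeros(m, dtype=bool)
    if k > 0:
        rejected[order[:k]] = True
    return LfdrScreenResult(
        lfdr=lfdr,
        order=order,
        running_mean=running,
        k_reject=k,
        delta_hat=delta_hat,
        rejected=rejected,
        alpha=alpha,
    )


def threshold_sup_form(lfdr: np.ndarray, alpha: float):
    """Largest candidate threshold t with Q_hat(t) <= alpha, scanning every
    observed lfdr value; returns None when no threshold is feasible.

    Q_hat(t) = sum_{lfdr_i <= t} lfdr_i / #{lfdr_i <= t}.  Equivalent to
    `step_up`; kept as an independent check.
    """
    lfdr = np.asarray(lfdr, dtype=float)
    if np.any((lfdr < 0) | (lfdr > 1)) or not np.all(np.isfinite(lfdr)):
        raise ValueError("lfdr values must lie in [0, 1]")
    best = None
    for t in np.unique(lfdr):
        sel = lfdr <= t
        q = lfdr[sel].sum() / sel.sum()
        if q <= alpha and (best is None or t > best):
            best = float(t)
    return best


def oracle_diagnostics(lfdr: np.ndarray, truth, grid: np.ndarray) -> OracleDiagnostics:
    """Counting processes V, R, P, W and stratum CDFs over a threshold grid.

    ``truth`` needs a boolean ``is_alt`` (xi = (1,1)) and an m x 2 ``xi``
    array; used in tests and benchmarks only.
    """
    lfdr = np.asarray(lfdr, dtype=float)
    grid = np.asarray(grid, dtype=float)
    is_alt = np.asarray(truth.is_alt, dtype=bool)
    xi = np.asarray(truth.xi)
    m = len(lfdr)
    le = lfdr[None, :] <= grid[:, None]  # grid x m
    Rm = le.sum(axis=1)
    Vm = (le & ~is_alt[None, :]).sum(axis=1)
    Pm = ((~le) & is_alt[None, :]).sum(axis=1)
    Wm = (le * lfdr[None, :]).sum(axis=1)
    G = Rm / m
    G_jk = {}
    for j in (0, 1):
        for k in (0, 1):
            stratum = (xi[:, 0] == j) & (xi[:, 1] == k)
            cnt = stratum.sum()
            G_jk[(j, k)] = (
                le[:, stratum].sum(axis=1) / cnt if cnt else np.zeros_like(grid)
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        Q = np.where(Rm > 0, Vm / np.maximum(Rm, 1), 0.0)
    return OracleDiagnostics(grid=grid, Vm=Vm, Rm=Rm, Pm=Pm, Wm=Wm, G=G, G_jk=G_jk,
                             Q_tilde=Q)


def screen(
    summary: CoefSummary,
    prior: Union[MixturePrior, CompositePrior],
    alpha: float = 0.05,
) -> LfdrScreenResult:
    """Convenience wrapper: compute lfdr under ``prior`` and run the step-up."""
    return step_up(compute_lfdr(summary, prior), alpha)
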