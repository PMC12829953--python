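"""Synthetic mediation scenarios with known ground truth, plus scoring.

Each scenario draws latent states xi_i i.i.d. from the sparsity proportions,
draws non-null coefficients around tau-scaled centers, and builds the data
matrices per the scenario's structural equations:

- ``linear``:        M_i = X a_i + e,  Y_i = M_i b_i + X g_i + eps
- ``confounder``:    adds a measured confounder Z ~ N(0,1) to both equations
- ``binary``:        logistic outcome, logit P(Y_i=1) = M_i b_i + X g_i
- ``interaction``:   hidden exposure-mediator interactions X * sum_S theta_j M_j
- ``latent_pleiotropy``: two unmeasured confounders (loadings 0.4, 0.5 on M
  and -0.5 on Y) plus dense pleiotropy sum_S M_j kappa_j on every outcome
- ``composite``:     coefficients drawn from two-component Gaussian mixtures
  per margin (composite alternatives)

Non-null effects are alpha_i = 0.05 tau + h_i with h ~ N(0, 1/n) and
beta_i = -0.5 tau + g_i with g ~ N(0, 4/n), so on the sqrt(n) scale the true
prior is N(0.05 tau sqrt(n), 1) x N(-0.5 tau sqrt(n), 4).  The default
exposure is standard normal, which puts the conditional variances of the
scaled estimates at sigma_i1^2 ~= sigma_i2^2 ~= 1 — the scale on which the
prior spreads (1 and 4) and the composite-alternative moments (kappa, psi of
order one) are meaningful, and the regime in which the tau grid sweeps power
from near zero to moderate.  A Bernoulli(p) exposure is available via
``exposure_dist="bernoulli"``; note that with p = 0.1 the exposure carries
an order of magnitude less information per sample (sigma_i1^2 ~= 1/p(1-p)),
leaving every screening method essentially powerless on the same tau grid.
All randomness flows from a single seed via spawned substreams.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import composite_em, lfdr_screen, mixture_em
from .lfdr_screen import LfdrScreenResult
from .regress import CoefSummary, MediationDataset, fit_structural_models, write_summary

__all__ = [
    "ScenarioConfig",
    "SimTruth",
    "EvalMetrics",
    "generate",
    "evaluate",
    "oracle_prior",
    "run_pipeline",
    "run_grid",
    "SPARSITY_PROPORTIONS",
]

SCENARIOS = (
    "linear",
    "confounder",
    "binary",
    "interaction",
    "latent_pleiotropy",
    "composite",
)

SPARSITY_PROPORTIONS = {
    "dense": (0.4, 0.2, 0.2, 0.2),  # (pi00, pi10, pi01, pi11)
    "sparse": (0.88, 0.05, 0.05, 0.02),
}

# Composite-alternative generator settings: two non-null components per margin.
COMPOSITE_WEIGHTS_A = (0.54, 0.18, 0.28)
COMPOSITE_WEIGHTS_B = (0.60, 0.05, 0.35)
COMPOSITE_KAPPA = (0.0, 1.0, 2.0)
COMPOSITE_PSI = (0.0, 1.5, 2.0)


def _composite_means(tau: float):
    mu = (0.0, 0.05 * tau, -0.5 * tau)
    theta = (0.0, 0.9 * tau, -0.01 * tau)
    return mu, theta


@dataclass
class ScenarioConfig:
    """Generator settings for one synthetic scenario."""

    scenario: str = "linear"
    sparsity: str = "dense"
    n: int = 300
    m: int = 1000
    tau: float = 1.0
    seed: int = 0
    exposure_dist: str = "normal"  # "normal" (unit variance) or "bernoulli"
    exposure_prob: float = 0.1  # carrier probability for the bernoulli option
    s_size: int = 20  # |S| for interaction / pleiotropy sets
    interaction_range: tuple = (0.3, 0.6)  # theta_j ~ U(low, high)
    pleiotropy_range: tuple = (0.3, 0.6)  # kappa_j ~ U(low, high)
    error_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if self.sparsity not in SPARSITY_PROPORTIONS:
            raise ValueError("sparsity must be 'dense' or 'sparse'")
        if self.tau < 0 or self.n <= 0 or self.m <= 0:
            raise ValueError("tau must be >= 0 and n, m positive")
        if self.exposure_dist not in ("normal", "bernoulli"):
            raise ValueError("exposure_dist must be 'normal' or 'bernoulli'")

    @property
    def proportions(self) -> tuple:
        return SPARSITY_PROPORTIONS[self.sparsity]


@dataclass
class SimTruth:
    """Latent truth of one generated dataset.

    ``var1_true`` / ``var2_true`` are the true conditional variances of the
    scaled estimates given the realized design (sigma_i1^2 = n sigma_a^2 / sxx
    and sigma_i2^2 = n sigma_b^2 / M_i' P M_i), available for continuous
    outcomes; the oracle procedure evaluates densities at these rather than
    at their estimates.
    """

    xi: np.ndarray  # m x 2 latent state indices
    alpha_true: np.ndarray
    beta_true: np.ndarray
    var1_true: Optional[np.ndarray] = None
    var2_true: Optional[np.ndarray] = None

    @property
    def is_alt(self) -> np.ndarray:
        return (self.xi[:, 0] >= 1) & (self.xi[:, 1] >= 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "xi1": self.xi[:, 0],
                "xi2": self.xi[:, 1],
                "alpha_true": self.alpha_true,
                "beta_true": self.beta_true,
                "is_alt": self.is_alt.astype(int),
            }
        )


@dataclass
class EvalMetrics:
    """FDP and power of one screened replicate."""

    fdp: float
    power: float
    n_reject: int
    replicate: int = 0


def _draw_states(rng, m, probs4):
    """Sample xi pairs from the four-cell table (00, 10, 01, 11)."""
    cells = rng.choice(4, size=m, p=np.asarray(probs4))
    xi = np.column_stack([np.isin(cells, (1, 3)), np.isin(cells, (2, 3))]).astype(int)
    return xi


def generate(config: ScenarioConfig) -> tuple[MediationDataset, SimTruth]:
    """Generate one dataset and its latent truth from ``config``.

    Deterministic given the seed; distinct seeds give independent draws.
    """
    rng = np.random.default_rng(config.seed)
    n, m, tau = config.n, config.m, config.tau
    root_n = np.sqrt(n)
    if config.exposure_dist == "normal":
        X = rng.standard_normal(n)
    else:
        X = (rng.random(n) < config.exposure_prob).astype(float)

    if config.scenario == "composite":
        mu, theta = _composite_means(tau)
        u = rng.choice(3, size=m, p=np.asarray(COMPOSITE_WEIGHTS_A))
        v = rng.choice(3, size=m, p=np.asarray(COMPOSITE_WEIGHTS_B))
        alpha = np.where(
            u > 0,
            (np.take(mu, u) + np.sqrt(np.take(COMPOSITE_KAPPA, u)) * rng.standard_normal(m))
            / root_n,
            0.0,
        )
        beta = np.where(
            v > 0,
            (np.take(theta, v) + np.sqrt(np.take(COMPOSITE_PSI, v)) * rng.standard_normal(m))
            / root_n,
            0.0,
        )
        xi = np.column_stack([u, v])
    else:
        xi = _draw_states(rng, m, config.proportions)
        alpha = np.where(
            xi[:, 0] == 1, 0.05 * tau + rng.normal(0.0, 1.0 / root_n, m), 0.0
        )
        beta = np.where(
            xi[:, 1] == 1, -0.5 * tau + rng.normal(0.0, 2.0 / root_n, m), 0.0
        )

    gamma = rng.normal(1.0, np.sqrt(0.5), m)  # direct exposure effects
    e = rng.normal(0.0, config.error_sd, (n, m))
    eps = rng.normal(0.0, config.error_sd, (n, m))
    truth = SimTruth(xi=xi, alpha_true=alpha, beta_true=beta)
    covariates = None
    outcome_type = "continuous"

    scen = config.scenario
    if scen in ("linear", "composite"):
        M = np.outer(X, alpha) + e
        Y = M * beta + np.outer(X, gamma) + eps
    elif scen == "confounder":
        Z = rng.standard_normal(n)
        theta_i = rng.uniform(0.0, 0.5, m)
        delta_i = rng.uniform(0.0, 0.5, m)
        M = np.outer(X, alpha) + np.outer(Z, theta_i) + e
        Y = M * beta + np.outer(X, gamma) + np.outer(Z, delta_i) + eps
        covariates = Z[:, None]
    elif scen == "binary":
        M = np.outer(X, alpha) + e
        logits = M * beta + np.outer(X, gamma)
        Y = (rng.random((n, m)) < 1.0 / (1.0 + np.exp(-logits))).astype(float)
        outcome_type = "binary"
    elif scen == "interaction":
        Z = rng.standard_normal(n)
        delta_i = rng.uniform(0.0, 0.5, m)
        zeta_i = rng.uniform(0.0, 0.5, m)
        M = np.outer(X, alpha) + np.outer(Z, delta_i) + e
        S = rng.choice(m, size=min(config.s_size, m), replace=False)
        theta_S = rng.uniform(*config.interaction_range, size=len(S))
        inter = X * (M[:, S] @ theta_S)  # hidden during fitting
        Y = M * beta + np.outer(X, gamma) + np.outer(Z, zeta_i) + inter[:, None] + eps
        covariates = Z[:, None]
    elif scen == "latent_pleiotropy":
        Z = rng.standard_normal(n)
        Z1 = rng.standard_normal(n)
        Z2 = rng.standard_normal(n)
        theta_i = rng.uniform(0.0, 0.5, m)
        delta_i = rng.uniform(0.0, 0.5, m)
        M = (
            np.outer(X, alpha)
            + np.outer(Z, theta_i)
            + 0.4 * Z1[:, None]
            + 0.5 * Z2[:, None]
            + e
        )
        S = rng.choice(m, size=min(config.s_size, m), replace=False)
        kappa_S = rng.uniform(*config.pleiotropy_range, size=len(S))
        pleio = M[:, S] @ kappa_S
        Y = (
            M * beta
            + np.outer(X, gamma)
            + np.outer(Z, delta_i)
            - 0.5 * Z1[:, None]
            + pleio[:, None]
            + eps
        )
        covariates = Z[:, None]  # Z1, Z2 stay unmeasured
    else:  # pragma: no cover
        raise ValueError(f"unknown scenario {scen!r}")

    data = MediationDataset(
        exposure=X,
        mediators=M,
        outcomes=Y,
        covariates=covariates,
        outcome_type=outcome_type,
    )
    if outcome_type == "continuous":
        # true conditional variances given the realized design
        W = np.ones((n, 1)) if covariates is None else np.hstack([np.ones((n, 1)), covariates])
        coef, *_ = np.linalg.lstsq(W, X[:, None], rcond=None)
        x_res = X - (W @ coef)[:, 0]
        sxx = float(x_res @ x_res)
        Wx = np.hstack([W, X[:, None]])
        coefM, *_ = np.linalg.lstsq(Wx, M, rcond=None)
        M_res = M - Wx @ coefM
        smm = np.einsum("ij,ij->j", M_res, M_res)
        truth.var1_true = np.full(m, n * config.error_sd**2 / sxx)
        truth.var2_true = n * config.error_sd**2 / smm
    return data, truth


def oracle_prior(config: ScenarioConfig):
    """The TRUE prior implied by the generator, for oracle screening.

    On the sqrt(n) scale the non-null centers are 0.05 tau sqrt(n) and
    -0.5 tau sqrt(n) with spreads 1 and 4.  For the composite scenario the
    joint table is the independence product of the margin weights.
    """
    root_n = np.sqrt(config.n)
    if config.scenario == "composite":
        mu, theta = _composite_means(config.tau)
        return composite_em.CompositePrior(
            mu=np.array(mu),
            kappa=np.array(COMPOSITE_KAPPA),
            theta=np.array(theta),
            psi=np.array(COMPOSITE_PSI),
            pi=np.outer(COMPOSITE_WEIGHTS_A, COMPOSITE_WEIGHTS_B),
        )
    return mixture_em.MixturePrior(
        pi=np.asarray(config.proportions, dtype=float),
        mu=0.05 * config.tau * root_n,
        psi=1.0,
        theta=-0.5 * config.tau * root_n,
        kappa=4.0,
    )


def evaluate(result: LfdrScreenResult, truth: SimTruth, replicate: int = 0) -> EvalMetrics:
    """FDP and power of a screen against simulation truth.

    FDP is 0 by convention when nothing is rejected; power is the fraction of
    true alternatives (xi with both components non-null) rejected.
    """
    rej = np.asarray(result.rejected, dtype=bool)
    is_alt = truth.is_alt
    if len(rej) != len(is_alt):
        raise ValueError("result and truth lengths differ")
    n_rej = int(rej.sum())
    false_rej = int((rej & ~is_alt).sum())
    n_alt = int(is_alt.sum())
    return EvalMetrics(
        fdp=false_rej / max(n_rej, 1),
        power=int((rej & is_alt).sum()) / max(n_alt, 1),
        n_reject=n_rej,
        replicate=replicate,
    )


def run_pipeline(
    config: ScenarioConfig,
    alpha: float = 0.05,
    prior_mode: str = "em",
    em_restarts: int = 1,
    em_seed: int = 0,
    d1: int | str = 1,
    d2: int | str = 1,
):
    """Generate -> regress -> prior -> screen for one replicate.

    ``prior_mode``: "oracle" uses the generator's true prior, "em" fits the
    simple model, "composite" runs the two-step EM.  Returns
    (result, truth, summary, prior).
    """
    data, truth = generate(config)
    summary = fit_structural_models(data)
    if prior_mode == "oracle":
        prior = oracle_prior(config)
        if truth.var1_true is not None:
            # true oracle: evaluate densities at the true conditional variances
            summary = CoefSummary(
                a=summary.a, b=summary.b, var1=truth.var1_true,
                var2=truth.var2_true, n=summary.n, unit_ids=list(summary.unit_ids),
            )
    elif prior_mode == "em":
        prior = mixture_em.em_fit(summary, n_restarts=em_restarts, seed=em_seed)
    elif prior_mode == "composite":
        prior = composite_em.fit_composite(summary, d1=d1, d2=d2, seed=em_seed)
    else:
        raise ValueError(f"unknown prior_mode {prior_mode!r}")
    result = lfdr_screen.screen(summary, prior, alpha)
    return result, truth, summary, prior


def _run_baseline(
    command_template: str, summary: CoefSummary, workdir: Path
) -> np.ndarray:
    """Run an external baseline command on an exported summary table.

    The template receives {summary} and {out}; the command must write a TSV
    with a 'rejected' column (0/1) aligned with the input rows.  The exported
    table carries two-sided normal p-values for each margin alongside the
    coefficient summary.
    """
    spath = workdir / "summary_for_baseline.tsv"
    frame = summary.to_frame()
    from scipy.stats import norm

    frame["p_alpha"] = 2 * norm.sf(np.abs(summary.a) / np.sqrt(summary.var1))
    frame["p_beta"] = 2 * norm.sf(np.abs(summary.b) / np.sqrt(summary.var2))
    frame.to_csv(spath, sep="\t", index=False, float_format="%.17g")
    opath = workdir / "baseline_out.tsv"
    cmd = command_template.format(summary=shlex.quote(str(spath)),
                                  out=shlex.quote(str(opath)))
    subprocess.run(cmd, shell=True, check=True, capture_output=True)
    out = pd.read_csv(opath, sep="\t")
    if "rejected" not in out.columns or len(out) != summary.m:
        raise ValueError("baseline output must have a 'rejected' column, one row per unit")
    return out["rejected"].to_numpy() != 0


def run_grid(
    scenarios: Sequence[str],
    taus: Sequence[float],
    n_values: Sequence[int],
    reps: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    m: int = 1000,
    sparsities: Sequence[str] = ("dense", "sparse"),
    prior_mode: str = "em",
    baselines: Optional[dict] = None,
    em_restarts: int = 1,
) -> pd.DataFrame:
    """Run the full simulation grid; one row per (cell, method, replicate).

    ``baselines`` maps method name -> shell command template invoked on the
    exported summary table (see `_run_baseline`).  Replicate substreams are
    spawned from the root seed so each cell is independently reproducible.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    root = np.random.SeedSequence(seed)
    cells = [
        (sc, sp, n, t)
        for sc in scenarios
        for sp in sparsities
        for n in n_values
        for t in taus
    ]
    cell_seeds = root.spawn(len(cells))
    for (sc, sp, n, t), cell_ss in zip(cells, cell_seeds):
        rep_seeds = cell_ss.spawn(reps)
        for r, rep_ss in enumerate(rep_seeds):
            rs = int(rep_ss.generate_state(1)[0] % (2**31))
            cfg = ScenarioConfig(scenario=sc, sparsity=sp, n=n, m=m, tau=t, seed=rs)
            try:
                result, truth, summary, _ = run_pipeline(
                    cfg, alpha=alpha, prior_mode=prior_mode,
                    em_restarts=em_restarts, em_seed=rs,
                )
            except Exception as exc:
                rows.append(
                    dict(scenario=sc, sparsity=sp, n=n, tau=t, replicate=r,
                         method="mlfdr", fdp=np.nan, power=np.nan,
                         n_reject=-1, error=str(exc))
                )
                continue
            met = evaluate(result, truth, r)
            rows.append(
                dict(scenario=sc, sparsity=sp, n=n, tau=t, replicate=r,
                     method="mlfdr", fdp=met.fdp, power=met.power,
                     n_reject=met.n_reject, error="")
            )
            for name, template in (baselines or {}).items():
                with tempfile.TemporaryDirectory() as td:
                    try:
                        rej = _run_baseline(template, summary, Path(td))
                    except Exception as exc:
                        rows.append(
                            dict(scenario=sc, sparsity=sp, n=n, tau=t, replicate=r,
                                 method=name, fdp=np.nan, power=np.nan,
                                 n_reject=-1, error=str(exc))
                        )
                        continue
                fake = LfdrScreenResult(
                    lfdr=np.zeros(summary.m), order=np.arange(summary.m),
                    running_mean=np.zeros(summary.m), k_reject=int(rej.sum()),
                    delta_hat=0.0, rejected=rej, alpha=alpha,
                )
                bmet = evaluate(fake, truth, r)
                rows.append(
                    dict(scenario=sc, sparsity=sp, n=n, tau=t, replicate=r,
                         method=name, fdp=bmet.fdp, power=bmet.power,
                         n_reject=bmet.n_reject, error="")
                )
    return pd.DataFrame(rows)
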