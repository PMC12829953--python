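"""Per-unit structural equation fits.

For each candidate mediator (unit) *i* the mediation model is a pair of
regressions,

    M_i = X alpha_i + e_i          (exposure -> mediator)
    Y_i = M_i beta_i + X gamma_i + eps_i   (mediator -> outcome, exposure adjusted)

optionally with measured covariates Z in both designs and an intercept always
included.  The sufficient statistics passed downstream are the sqrt(n)-scaled
coefficient estimates a_i = sqrt(n) alpha_hat_i, b_i = sqrt(n) beta_hat_i
together with their conditional variances sigma_i1^2 = n Var(alpha_hat_i) and
sigma_i2^2 = n Var(beta_hat_i).  Conditional on the design, a_i and b_i are
independent normals centred at the scaled true coefficients, which is what the
downstream mixture model assumes.

Binary outcomes replace the outcome-side OLS with a per-unit logistic
maximum-likelihood fit (Newton iterations); the mediator model stays linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MediationDataset",
    "CoefSummary",
    "fit_structural_models",
    "summary_from_table",
    "write_summary",
]

SUMMARY_COLUMNS = ["unit_id", "alpha_hat", "beta_hat", "se_alpha", "se_beta", "n"]

# Logistic-fit controls: convergence on the log-likelihood, hard iteration cap,
# and the standardized-coefficient magnitude treated as separation.
LOGIT_TOL = 1e-8
LOGIT_MAX_ITER = 100
LOGIT_SEPARATION_BOUND = 50.0


class DegenerateUnitError(ValueError):
    """A unit's design is singular, separated, or has zero residual variance."""


@dataclass
class MediationDataset:
    """Raw matrices for n samples and m mediation units.

    ``exposure`` is an (n,) vector shared across units or an (n, m) matrix of
    unit-specific exposures.  ``outcomes`` is (n, m) or a single (n,) vector
    shared across units.  ``covariates`` is an optional (n, q) matrix; an
    intercept is always added internally and must not be supplied.
    """

    exposure: np.ndarray
    mediators: np.ndarray
    outcomes: np.ndarray
    covariates: Optional[np.ndarray] = None
    outcome_type: str = "continuous"
    unit_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.exposure = np.asarray(self.exposure, dtype=float)
        self.mediators = np.atleast_2d(np.asarray(self.mediators, dtype=float))
        if self.mediators.shape[0] == 1 and self.mediators.shape[1] > 1:
            pass  # a single sample row is legal only for toy inputs
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        n, m = self.mediators.shape
        if self.exposure.ndim == 1:
            if self.exposure.shape[0] != n:
                raise ValueError("exposure length does not match mediator rows")
        elif self.exposure.shape != (n, m):
            raise ValueError("per-unit exposure must be n x m")
        if self.outcomes.ndim == 1:
            if self.outcomes.shape[0] != n:
                raise ValueError("outcome length does not match mediator rows")
        elif self.outcomes.shape != (n, m):
            raise ValueError("outcome matrix must be n x m")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                raise ValueError("covariate rows do not match sample count")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        if self.outcome_type == "binary":
            vals = np.unique(self.outcomes)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("binary outcomes must take values in {0, 1}")
        for name, arr in (
            ("exposure", self.exposure),
            ("mediators", self.mediators),
            ("outcomes", self.outcomes),
        ):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains missing or non-finite values")
        if self.covariates is not None and not np.all(np.isfinite(self.covariates)):
            raise ValueError("covariates contain missing or non-finite values")
        if self.unit_ids is None:
            self.unit_ids = [f"unit_{i}" for i in range(m)]
        elif len(self.unit_ids) != m:
            raise ValueError("unit_ids length does not match number of units")

    @property
    def n_samples(self) -> int:
        return self.mediators.shape[0]

    @property
    def n_units(self) -> int:
        return self.mediators.shape[1]

    def outcome_column(self, i: int) -> np.ndarray:
        return self.outcomes if self.outcomes.ndim == 1 else self.outcomes[:, i]

    def exposure_column(self, i: int) -> np.ndarray:
        return self.exposure if self.exposure.ndim == 1 else self.exposure[:, i]


@dataclass
class CoefSummary:
    """sqrt(n)-scaled per-unit coefficient estimates and conditional variances."""

    a: np.ndarray  # sqrt(n) * alpha_hat
    b: np.ndarray  # sqrt(n) * beta_hat
    var1: np.ndarray  # n * Var(alpha_hat)
    var2: np.ndarray  # n * Var(beta_hat)
    n: int
    unit_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.var1 = np.asarray(self.var1, dtype=float)
        self.var2 = np.asarray(self.var2, dtype=float)
        m = self.a.shape[0]
        if not (self.b.shape[0] == self.var1.shape[0] == self.var2.shape[0] == m):
            raise ValueError("CoefSummary field lengths disagree")
        if np.any(self.var1 <= 0) or np.any(self.var2 <= 0):
            raise ValueError("conditional variances must be strictly positive")
        if not len(self.unit_ids):
            self.unit_ids = [f"unit_{i}" for i in range(m)]
        elif len(self.unit_ids) != m:
            raise ValueError("unit_ids length mismatch")

    @property
    def m(self) -> int:
        return self.a.shape[0]

    def to_frame(self) -> pd.DataFrame:
        root_n = np.sqrt(self.n)
        return pd.DataFrame(
            {
                "unit_id": list(self.unit_ids),
                "alpha_hat": self.a / root_n,
                "beta_hat": self.b / root_n,
                "se_alpha": np.sqrt(self.var1 / self.n),
                "se_beta": np.sqrt(self.var2 / self.n),
                "n": self.n,
            }
        )


def _residual_maker(W: np.ndarray) -> np.ndarray:
    """Annihilator matrix of the column space of W (assumed full rank)."""
    Q, R = np.linalg.qr(W)
    rank = np.sum(np.abs(np.diag(R)) > 1e-10 * max(abs(np.diag(R)).max(), 1.0))
    if rank < W.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    return np.eye(W.shape[0]) - Q @ Q.T


def _residualize(W: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Residuals of the columns of A after projecting out span(W)."""
    coef, *_ = np.linalg.lstsq(W, A, rcond=None)
    return A - W @ coef


def _check_full_rank(W: np.ndarray, what: str) -> None:
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise DegenerateUnitError(f"singular design for {what}")


def fit_structural_models(
    data: MediationDataset,
    extra_mediator_covariates: Optional[np.ndarray] = None,
    extra_outcome_covariates: Optional[np.ndarray] = None,
) -> CoefSummary:
    """Fit both structural regressions for every unit.

    The mediator model regresses M_i on [1, X_i, Z (, extra_mediator_covariates)]
    and takes the exposure coefficient; the outcome model regresses Y_i on
    [1, M_i, X_i, Z (, extra_outcome_covariates)] and takes the mediator
    coefficient.  Residual variances use the unbiased RSS/(n - p) denominator.
    The ``extra_*`` hooks carry estimated latent-factor scores for the
    confounder-adjusted pipeline.

    Returns the sqrt(n)-scaled :class:`CoefSummary`.
    """
    n, m = data.n_samples, data.n_units
    blocks = [np.ones((n, 1))]
    if data.covariates is not None:
        blocks.append(data.covariates)
    Zm = blocks[0] if len(blocks) == 1 else np.hstack(blocks)
    if extra_mediator_covariates is not None and extra_mediator_covariates.size:
        Zmed = np.hstack([Zm, extra_mediator_covariates])
    else:
        Zmed = Zm
    if extra_outcome_covariates is not None and extra_outcome_covariates.size:
        Zout = np.hstack([Zmed, extra_outcome_covariates])
    else:
        Zout = Zmed

    shared_exposure = data.exposure.ndim == 1

    a = np.empty(m)
    var1 = np.empty(m)
    b = np.empty(m)
    var2 = np.empty(m)

    if shared_exposure:
        X = data.exposure
        # alpha side, vectorized: alpha_hat_i is the slope of X residualized
        # on the rest of the mediator design.
        Wm = np.hstack([Zmed, X[:, None]])
        _check_full_rank(Wm, "mediator model (shared exposure)")
        x_res = _residualize(Zmed, X[:, None])[:, 0]
        sxx = float(x_res @ x_res)
        M_res = _residualize(Zmed, data.mediators)
        alpha_hat = (x_res @ data.mediators) / sxx
        resid_M = M_res - np.outer(x_res, alpha_hat)
        df_m = n - Wm.shape[1]
        if df_m < 1:
            raise ValueError("not enough samples for the mediator model")
        rss_m = np.einsum("ij,ij->j", resid_M, resid_M)
        sigma2_a = rss_m / df_m
        if np.any(sigma2_a <= 1e-12):
            bad = int(np.argmin(sigma2_a))
            raise DegenerateUnitError(
                f"zero residual variance for mediator unit {data.unit_ids[bad]!r}"
            )
        a[:] = np.sqrt(n) * alpha_hat
        var1[:] = n * sigma2_a / sxx
    else:
        for i in range(m):
            Xi = data.exposure_column(i)
            Wm = np.hstack([Zmed, Xi[:, None]])
            _check_full_rank(Wm, f"mediator model of unit {data.unit_ids[i]!r}")
            x_res = _residualize(Zmed, Xi[:, None])[:, 0]
            sxx = float(x_res @ x_res)
            Mi = data.mediators[:, i]
            alpha_hat_i = float(x_res @ Mi) / sxx
            resid = _residualize(Zmed, Mi[:, None])[:, 0] - alpha_hat_i * x_res
            df_m = n - Wm.shape[1]
            sigma2_a = float(resid @ resid) / df_m
            if sigma2_a <= 1e-12:
                raise DegenerateUnitError(
                    f"zero residual variance for mediator unit {data.unit_ids[i]!r}"
                )
            a[i] = np.sqrt(n) * alpha_hat_i
            var1[i] = n * sigma2_a / sxx

    if data.outcome_type == "continuous":
        if shared_exposure and data.outcomes.ndim == 2:
            # beta side vectorized via Frisch-Waugh: residualize M_i and Y_i on
            # the non-mediator outcome design, then a simple slope per unit.
            Wbase = np.hstack([Zout, data.exposure[:, None]])
            _check_full_rank(Wbase, "outcome model base design")
            M_res = _residualize(Wbase, data.mediators)
            Y_res = _residualize(Wbase, data.outcomes)
            smm = np.einsum("ij,ij->j", M_res, M_res)
            if np.any(smm <= 1e-12):
                bad = int(np.argmin(smm))
                raise DegenerateUnitError(
                    f"mediator unit {data.unit_ids[bad]!r} is collinear with the design"
                )
            beta_hat = np.einsum("ij,ij->j", M_res, Y_res) / smm
            resid_Y = Y_res - M_res * beta_hat
            df_y = n - (Wbase.shape[1] + 1)
            if df_y < 1:
                raise ValueError("not enough samples for the outcome model")
            sigma2_b = np.einsum("ij,ij->j", resid_Y, resid_Y) / df_y
            b[:] = np.sqrt(n) * beta_hat
            var2[:] = n * np.maximum(sigma2_b, 1e-300) / smm
            if np.any(sigma2_b <= 1e-12):
                bad = int(np.argmin(sigma2_b))
                raise DegenerateUnitError(
                    f"zero residual variance for outcome unit {data.unit_ids[bad]!r}"
                )
        else:
            for i in range(m):
                Xi = data.exposure_column(i)
                Yi = data.outcome_column(i)
                Wbase = np.hstack([Zout, Xi[:, None]])
                _check_full_rank(Wbase, f"outcome model of unit {data.unit_ids[i]!r}")
                Mi = data.mediators[:, i]
                m_res = _residualize(Wbase, Mi[:, None])[:, 0]
                y_res = _residualize(Wbase, Yi[:, None])[:, 0]
                smm = float(m_res @ m_res)
                if smm <= 1e-12:
                    raise DegenerateUnitError(
                        f"mediator unit {data.unit_ids[i]!r} is collinear with the design"
                    )
                beta_hat_i = float(m_res @ y_res) / smm
                resid = y_res - beta_hat_i * m_res
                df_y = n - (Wbase.shape[1] + 1)
                sigma2_b = float(resid @ resid) / df_y
                if sigma2_b <= 1e-12:
                    raise DegenerateUnitError(
                        f"zero residual variance for outcome unit {data.unit_ids[i]!r}"
                    )
                b[i] = np.sqrt(n) * beta_hat_i
                var2[i] = n * sigma2_b / smm
    else:
        for i in range(m):
            Xi = data.exposure_column(i)
            Yi = data.outcome_column(i)
            D = np.hstack([Zout, data.mediators[:, i : i + 1], Xi[:, None]])
            _check_full_rank(D, f"logistic design of unit {data.unit_ids[i]!r}")
            med_col = Zout.shape[1]
            coef, cov = _logistic_newton(D, Yi, data.unit_ids[i])
            b[i] = np.sqrt(n) * coef[med_col]
            var2[i] = n * cov[med_col, med_col]

    return CoefSummary(a=a, b=b, var1=var1, var2=var2, n=n, unit_ids=list(data.unit_ids))


def _logistic_newton(D: np.ndarray, y: np.ndarray, unit_id: str):
    """Newton-Raphson logistic MLE; returns (coef, covariance).

    Separation is flagged when any coefficient exceeds LOGIT_SEPARATION_BOUND
    on the column-standardized scale.
    """
    scale = D.std(axis=0)
    scale[scale == 0] = 1.0
    coef = np.zeros(D.shape[1])
    ll_old = -np.inf
    for _ in range(LOGIT_MAX_ITER):
        eta = D @ coef
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        w = np.maximum(p * (1 - p), 1e-12)
        H = D.T @ (D * w[:, None])
        g = D.T @ (y - p)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise DegenerateUnitError(
                f"singular logistic information for unit {unit_id!r}"
            ) from exc
        coef = coef + step
        if np.any(np.abs(coef * scale) > LOGIT_SEPARATION_BOUND):
            raise DegenerateUnitError(
                f"separation detected in logistic fit for unit {unit_id!r}"
            )
        if abs(ll - ll_old) < LOGIT_TOL * (abs(ll_old) + 1.0):
            cov = np.linalg.inv(H)
            return coef, cov
        ll_old = ll
    raise DegenerateUnitError(
        f"logistic fit did not converge for unit {unit_id!r}"
    )


def summary_from_table(table) -> CoefSummary:
    """Build a :class:`CoefSummary` from precomputed regression output.

    ``table`` is a DataFrame or a path to a delimited file with columns
    unit_id, alpha_hat, beta_hat, se_alpha, se_beta, n.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep=None, engine="python", comment="#")
    missing = [c for c in SUMMARY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"summary table is missing columns {missing}; expected {SUMMARY_COLUMNS}"
        )
    n_vals = table["n"].unique()
    if len(n_vals) != 1:
        raise ValueError("summary table mixes different sample sizes n")
    n = int(n_vals[0])
    se_a = table["se_alpha"].to_numpy(float)
    se_b = table["se_beta"].to_numpy(float)
    if np.any(se_a <= 0) or np.any(se_b <= 0):
        raise ValueError("standard errors must be strictly positive")
    root_n = np.sqrt(n)
    return CoefSummary(
        a=root_n * table["alpha_hat"].to_numpy(float),
        b=root_n * table["beta_hat"].to_numpy(float),
        var1=n * se_a**2,
        var2=n * se_b**2,
        n=n,
        unit_ids=[str(u) for u in table["unit_id"]],
    )


def write_summary(summary: CoefSummary, path) -> None:
    """Write a summary table readable by :func:`summary_from_table`.

    Floats use 17 significant digits so the round trip is exact.
    """
    summary.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
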