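"""Global latent-factor adjustment for unmeasured confounding and pleiotropy.

Unmodelled structured variation — hidden confounders, batch effects, or the
aggregate effect of other mediators on an outcome (pleiotropy) — biases the
per-unit regressions.  The adjustment is a two-step surrogate-variable
scheme: residualize the mediator matrix (and separately the outcome matrix,
with mediators excluded) on the measured design [1, X, Z], extract leading
principal components of the residuals as orthonormal factor scores, and
append them to the per-unit regression designs.  Mediator-derived factors
U_M enter both the mediator and outcome models; outcome-derived factors U_Y
enter the outcome model only.

Factor extraction is residual PCA: columns are centered and scaled, and the
number of factors is chosen by permutation parallel analysis — keep the
leading components whose singular values exceed the 95th percentile of the
corresponding singular values of column-permuted residual matrices.  This
realizes the "top principal components of the residual matrix" step without
the iterative reweighting of full surrogate-variable analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from sklearn.utils.extmath import randomized_svd

from .regress import CoefSummary, MediationDataset, _residualize, fit_structural_models

__all__ = ["LatentFactors", "estimate_surrogates", "adjusted_mediation_fit", "adjust"]

MAX_FACTORS = 10
PERMUTATIONS = 20
PERM_QUANTILE = 0.95


@dataclass
class LatentFactors:
    """Orthonormal factor-score matrices for the two model stages."""

    U_M: np.ndarray  # n x k_M
    U_Y: np.ndarray  # n x k_Y
    diagnostics: dict = field(default_factory=dict)

    @property
    def k_M(self) -> int:
        return self.U_M.shape[1]

    @property
    def k_Y(self) -> int:
        return self.U_Y.shape[1]


def estimate_surrogates(
    Y_like: np.ndarray,
    X: Optional[np.ndarray],
    Z: Optional[np.ndarray],
    k: Union[int, str] = "auto",
    seed: int = 0,
    max_factors: int = MAX_FACTORS,
    n_permutations: int = PERMUTATIONS,
) -> tuple[np.ndarray, dict]:
    """Estimate orthonormal surrogate-factor scores from a data matrix.

    Every column of ``Y_like`` (n x m) is residualized on [1, X, Z]; the
    residual columns are standardized and the top-k left singular vectors are
    returned as an n x k score matrix.  With ``k="auto"`` the rank is chosen
    by parallel analysis: component l is kept (sequentially) if its singular
    value exceeds the PERM_QUANTILE quantile of the l-th singular values of
    ``n_permutations`` independently column-permuted matrices.

    Returns (scores, diagnostics).
    """
    Y_like = np.atleast_2d(np.asarray(Y_like, dtype=float))
    n, m = Y_like.shape
    if m < 2:
        raise ValueError("need at least 2 columns to estimate factors")
    blocks = [np.ones((n, 1))]
    if X is not None:
        X = np.asarray(X, dtype=float)
        blocks.append(X[:, None] if X.ndim == 1 else X)
    if Z is not None:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        blocks.append(Z)
    W = np.hstack(blocks)
    if n <= W.shape[1] + 1:
        raise ValueError("not enough samples to residualize on the design")
    R = _residualize(W, Y_like)

    sd = R.std(axis=0)
    keep = sd > 1e-12
    diagnostics: dict = {}
    if not np.any(keep):
        return np.zeros((n, 0)), {"spectrum": np.array([]), "k": 0}
    Rs = (R[:, keep] - R[:, keep].mean(axis=0)) / sd[keep]

    k_cap = min(max_factors, min(Rs.shape) - 1)
    if isinstance(k, str):
        if k != "auto":
            raise ValueError("k must be an integer or 'auto'")
    elif k > min(n, int(keep.sum())):
        raise ValueError("k exceeds the rank bound min(n_samples, n_columns)")

    rng = np.random.default_rng(seed)
    if not isinstance(k, str):
        k_sel = int(k)
        diagnostics["k"] = k_sel
        if k_sel == 0:
            return np.zeros((n, 0)), diagnostics
        U, s, _ = randomized_svd(
            Rs, n_components=k_sel, random_state=int(rng.integers(2**31))
        )
        diagnostics["spectrum"] = s
        q, _ = np.linalg.qr(U[:, :k_sel])
        return q, diagnostics

    # Sequential parallel analysis with deflation: test the leading singular
    # value of the CURRENT residual matrix against column permutations of
    # that same matrix, deflate, repeat.  Without deflation a dominant factor
    # makes the permutation threshold wildly conservative for later
    # components.
    spectrum, thresholds, scores = [], [], []
    R_cur = Rs
    s_first = None
    for _ in range(k_cap):
        U1, s1, V1 = randomized_svd(
            R_cur, n_components=1, random_state=int(rng.integers(2**31))
        )
        if s_first is None:
            s_first = max(float(s1[0]), 1e-12)
        elif s1[0] < 1e-8 * s_first:  # residual numerically exhausted
            break
        perm_top = np.empty(n_permutations)
        for b in range(n_permutations):
            P = np.empty_like(R_cur)
            for j in range(R_cur.shape[1]):
                P[:, j] = R_cur[rng.permutation(n), j]
            perm_top[b] = randomized_svd(
                P, n_components=1, random_state=int(rng.integers(2**31))
            )[1][0]
        # 'higher' interpolation keeps the exceedance probability exactly
        # <= 1/(B+1) under exchangeability (conservative for i.i.d. noise)
        thr = float(np.quantile(perm_top, PERM_QUANTILE, method="higher"))
        spectrum.append(float(s1[0]))
        thresholds.append(thr)
        if s1[0] <= thr:
            break
        scores.append(U1[:, 0])
        R_cur = R_cur - (U1 * s1) @ V1
    diagnostics["spectrum"] = np.array(spectrum)
    diagnostics["permutation_quantiles"] = np.array(thresholds)
    k_sel = len(scores)
    diagnostics["k"] = k_sel
    if k_sel == 0:
        return np.zeros((n, 0)), diagnostics
    q, _ = np.linalg.qr(np.column_stack(scores))
    return q, diagnostics


def adjusted_mediation_fit(
    data: MediationDataset, U_M: np.ndarray, U_Y: np.ndarray
) -> CoefSummary:
    """Refit both structural models with factor scores in the designs.

    U_M is appended to the mediator-model design and (together with U_Y) to
    the outcome-model design; coefficient extraction and scaling are exactly
    as in the unadjusted fit, so k_M = k_Y = 0 reproduces it.
    """
    n = data.n_samples
    U_M = np.zeros((n, 0)) if U_M is None or U_M.size == 0 else np.atleast_2d(U_M)
    U_Y = np.zeros((n, 0)) if U_Y is None or U_Y.size == 0 else np.atleast_2d(U_Y)
    if U_M.shape[0] != n or U_Y.shape[0] != n:
        raise ValueError("factor matrices must have one row per sample")
    return fit_structural_models(
        data,
        extra_mediator_covariates=U_M,
        extra_outcome_covariates=U_Y,
    )


def adjust(
    data: MediationDataset,
    k_M: Union[int, str] = "auto",
    k_Y: Union[int, str] = "auto",
    seed: int = 0,
) -> tuple[CoefSummary, LatentFactors]:
    """Full two-step global factor adjustment.

    Step 1 extracts U_M from mediator residuals; step 2 extracts U_Y from
    outcome residuals (mediators excluded); step 3 refits every unit with
    the factors appended.  Returns the adjusted summary and the factors.
    """
    X = data.exposure if data.exposure.ndim == 1 else None
    if X is None:
        # per-unit exposures: residualize on their column mean as a shared proxy
        X = data.exposure.mean(axis=1)
    U_M, diag_M = estimate_surrogates(
        data.mediators, X, data.covariates, k=k_M, seed=seed
    )
    Y_mat = (
        data.outcomes if data.outcomes.ndim == 2 else data.outcomes[:, None]
    )
    if Y_mat.shape[1] >= 2:
        U_Y, diag_Y = estimate_surrogates(
            Y_mat, X, data.covariates, k=k_Y, seed=seed + 1
        )
    else:
        U_Y, diag_Y = np.zeros((data.n_samples, 0)), {"k": 0}
    factors = LatentFactors(U_M=U_M, U_Y=U_Y,
                            diagnostics={"mediators": diag_M, "outcomes": diag_Y})
    summary = adjusted_mediation_fit(data, U_M, U_Y)
    return summary, factors
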