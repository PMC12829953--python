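"""Structural-model fitting: agreement with direct solvers and invariances."""

import numpy as np
import pytest

from mlfdr.regress import (
    CoefSummary,
    DegenerateUnitError,
    MediationDataset,
    fit_structural_models,
    summary_from_table,
    write_summary,
)


def _normal_eq(design, y):
    return np.linalg.solve(design.T @ design, design.T @ y)


class TestContinuousFits:
    def test_exact_linear_dependence_recovers_slope_then_errors(self):
        # M = 2X exactly: the slope is 2 but the residual variance is zero,
        # which the fit must flag as degenerate.
        rng = np.random.default_rng(0)
        X = rng.standard_normal(30)
        M = 2 * X
        Y = rng.standard_normal(30)
        data = MediationDataset(exposure=X, mediators=M[:, None], outcomes=Y[:, None])
        with pytest.raises(DegenerateUnitError, match="zero residual variance"):
            fit_structural_models(data)

    def test_toy_design_matches_normal_equations(self):
        X = np.array([0.0, 0.0, 1.0, 1.0])
        M = np.array([0.0, 1.0, 1.0, 2.0])
        # Y = M + X fits exactly (zero residual variance), so perturb one
        # entry to keep the outcome model non-degenerate
        Y = np.array([0.0, 1.0, 2.0, 3.5])
        # independent normal-equations solve with intercepts included
        alpha_expect = _normal_eq(np.column_stack([np.ones(4), X]), M)[1]
        beta_expect = _normal_eq(np.column_stack([np.ones(4), M, X]), Y)[1]
        data = MediationDataset(exposure=X, mediators=M[:, None], outcomes=Y[:, None])
        summary = fit_structural_models(data)
        assert summary.a[0] / 2.0 == pytest.approx(alpha_expect, rel=1e-10)
        assert summary.b[0] / 2.0 == pytest.approx(beta_expect, rel=1e-10)

    def test_matches_generic_lstsq_on_random_designs(self, rng):
        n, m = 20, 5
        X = rng.standard_normal(n)
        Z = rng.standard_normal((n, 2))
        M = rng.standard_normal((n, m))
        Y = rng.standard_normal((n, m))
        data = MediationDataset(exposure=X, mediators=M, outcomes=Y, covariates=Z)
        summary = fit_structural_models(data)
        root_n = np.sqrt(n)
        for i in range(m):
            Dm = np.column_stack([np.ones(n), Z, X])
            alpha = np.linalg.lstsq(Dm, M[:, i], rcond=None)[0][-1]
            Do = np.column_stack([np.ones(n), Z, M[:, i], X])
            coef = np.linalg.lstsq(Do, Y[:, i], rcond=None)[0]
            beta = coef[3]
            resid = Y[:, i] - Do @ coef
            s2 = resid @ resid / (n - Do.shape[1])
            var_beta = s2 * np.linalg.inv(Do.T @ Do)[3, 3]
            assert summary.a[i] == pytest.approx(root_n * alpha, rel=1e-10)
            assert summary.b[i] == pytest.approx(root_n * beta, rel=1e-10)
            assert summary.var2[i] == pytest.approx(n * var_beta, rel=1e-8)

    def test_orthogonal_exposure_reduces_beta_to_simple_slope(self):
        n = 40
        rng = np.random.default_rng(1)
        X = np.tile([1.0, -1.0], n // 2)
        M0 = rng.standard_normal(n)
        # make the mediator exactly orthogonal to [1, X]
        D = np.column_stack([np.ones(n), X])
        M = M0 - D @ np.linalg.lstsq(D, M0, rcond=None)[0]
        Y = rng.standard_normal(n)
        data = MediationDataset(exposure=X, mediators=M[:, None], outcomes=Y[:, None])
        summary = fit_structural_models(data)
        # after projecting out [1, X], M is unchanged, so beta_hat is the
        # simple regression slope of (projected) Y on M
        y_res = Y - D @ np.linalg.lstsq(D, Y, rcond=None)[0]
        simple_slope = (M @ y_res) / (M @ M)
        assert summary.b[0] / np.sqrt(n) == pytest.approx(simple_slope, rel=1e-10)

    def test_outcome_scaling_equivariance(self, rng):
        n, m = 50, 3
        X = rng.standard_normal(n)
        M = rng.standard_normal((n, m))
        Y = rng.standard_normal((n, m))
        base = fit_structural_models(
            MediationDataset(exposure=X, mediators=M, outcomes=Y)
        )
        doubled = fit_structural_models(
            MediationDataset(exposure=X, mediators=M, outcomes=2 * Y)
        )
        np.testing.assert_allclose(doubled.b, 2 * base.b, rtol=1e-10)
        np.testing.assert_allclose(np.sqrt(doubled.var2), 2 * np.sqrt(base.var2),
                                   rtol=1e-10)
        np.testing.assert_allclose(
            doubled.b / np.sqrt(doubled.var2), base.b / np.sqrt(base.var2), rtol=1e-10
        )

    def test_null_data_gives_uncorrelated_a_and_b(self):
        # under the global null the two coefficient streams are independent
        rng = np.random.default_rng(7)
        n, m = 100, 3000
        X = rng.standard_normal(n)
        M = rng.standard_normal((n, m))
        Y = rng.standard_normal((n, m))
        summary = fit_structural_models(
            MediationDataset(exposure=X, mediators=M, outcomes=Y)
        )
        corr = np.corrcoef(summary.a, summary.b)[0, 1]
        assert abs(corr) < 3.0 / np.sqrt(m)


class TestBinaryOutcome:
    def test_logistic_beta_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n, m = 200, 4
        X = rng.standard_normal(n)
        M = rng.standard_normal((n, m))
        logits = 0.8 * M + 0.3 * X[:, None]
        Y = (rng.random((n, m)) < 1 / (1 + np.exp(-logits))).astype(float)
        data = MediationDataset(
            exposure=X, mediators=M, outcomes=Y, outcome_type="binary"
        )
        summary = fit_structural_models(data)
        for i in range(m):
            D = np.column_stack([np.ones(n), M[:, i], X])
            fit = sm.Logit(Y[:, i], D).fit(disp=0)
            assert summary.b[i] == pytest.approx(np.sqrt(n) * fit.params[1], rel=1e-5)
            assert summary.var2[i] == pytest.approx(n * fit.cov_params()[1, 1],
                                                    rel=1e-4)

    def test_separation_raises(self):
        n = 60
        X = np.linspace(-2, 2, n)
        M = np.linspace(-3, 3, n) + 0.01 * np.sin(np.arange(n))
        Y = (M > 0).astype(float)  # perfectly separated by the mediator
        data = MediationDataset(
            exposure=X, mediators=M[:, None], outcomes=Y[:, None],
            outcome_type="binary",
        )
        with pytest.raises(DegenerateUnitError):
            fit_structural_models(data)


class TestSummaryTable:
    def test_scaling_arithmetic(self, tmp_path):
        import pandas as pd

        table = pd.DataFrame(
            {
                "unit_id": ["u1", "u2"],
                "alpha_hat": [0.1, 0.0],
                "beta_hat": [0.2, 0.1],
                "se_alpha": [0.02, 1.0],
                "se_beta": [0.05, 0.5],
                "n": [100, 100],
            }
        )
        s = summary_from_table(table)
        assert s.a[0] == pytest.approx(1.0)
        assert s.var1[0] == pytest.approx(0.04)
        assert s.a[1] == 0.0
        assert s.var1[1] == pytest.approx(100.0)

    def test_round_trip(self, tmp_path, rng):
        m = 10
        summary = CoefSummary(
            a=rng.standard_normal(m),
            b=rng.standard_normal(m),
            var1=rng.uniform(0.5, 2, m),
            var2=rng.uniform(0.5, 2, m),
            n=250,
        )
        path = tmp_path / "summary.tsv"
        write_summary(summary, path)
        back = summary_from_table(path)
        np.testing.assert_allclose(back.a, summary.a, rtol=1e-12)
        np.testing.assert_allclose(back.var1, summary.var1, rtol=1e-12)
        np.testing.assert_allclose(back.var2, summary.var2, rtol=1e-12)
        assert back.n == summary.n

    def test_schema_errors(self):
        import pandas as pd

        with pytest.raises(ValueError, match="missing columns"):
            summary_from_table(pd.DataFrame({"unit_id": ["u"]}))
        bad = pd.DataFrame(
            {
                "unit_id": ["u"],
                "alpha_hat": [0.1],
                "beta_hat": [0.1],
                "se_alpha": [-1.0],
                "se_beta": [0.1],
                "n": [50],
            }
        )
        with pytest.raises(ValueError, match="positive"):
            summary_from_table(bad)


class TestAlternativeShapes:
    def test_per_unit_exposure_matches_shared_exposure(self, rng):
        n, m = 50, 4
        X = rng.standard_normal(n)
        M = rng.standard_normal((n, m))
        Y = rng.standard_normal((n, m))
        shared = fit_structural_models(
            MediationDataset(exposure=X, mediators=M, outcomes=Y)
        )
        tiled = fit_structural_models(
            MediationDataset(exposure=np.tile(X[:, None], (1, m)), mediators=M,
                             outcomes=Y)
        )
        np.testing.assert_allclose(tiled.a, shared.a, rtol=1e-10)
        np.testing.assert_allclose(tiled.b, shared.b, rtol=1e-10)
        np.testing.assert_allclose(tiled.var1, shared.var1, rtol=1e-8)

    def test_shared_outcome_vector_broadcasts(self, rng):
        n, m = 60, 3
        X = rng.standard_normal(n)
        M = rng.standard_normal((n, m))
        y = rng.standard_normal(n)
        shared = fit_structural_models(
            MediationDataset(exposure=X, mediators=M, outcomes=y)
        )
        stacked = fit_structural_models(
            MediationDataset(exposure=X, mediators=M,
                             outcomes=np.tile(y[:, None], (1, m)))
        )
        np.testing.assert_allclose(shared.b, stacked.b, rtol=1e-10)
        np.testing.assert_allclose(shared.var2, stacked.var2, rtol=1e-8)
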