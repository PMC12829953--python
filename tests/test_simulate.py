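"""Scenario generators, scoring, and the simulation grid."""

import numpy as np
import pytest
from scipy.stats import kstest

from mlfdr.lfdr_screen import LfdrScreenResult
from mlfdr.simulate import (
    ScenarioConfig,
    SimTruth,
    evaluate,
    generate,
    oracle_prior,
    run_grid,
    run_pipeline,
)


def _result_from_flags(rejected):
    rejected = np.asarray(rejected, dtype=bool)
    m = len(rejected)
    return LfdrScreenResult(
        lfdr=np.zeros(m), order=np.arange(m), running_mean=np.zeros(m),
        k_reject=int(rejected.sum()), delta_hat=0.0, rejected=rejected, alpha=0.05,
    )


class TestGenerate:
    def test_dense_proportions_law_of_large_numbers(self):
        cfg = ScenarioConfig(scenario="linear", sparsity="dense", n=50, m=100000,
                             tau=1.0, seed=0)
        _, truth = generate(cfg)
        frac00 = np.mean((truth.xi[:, 0] == 0) & (truth.xi[:, 1] == 0))
        assert frac00 == pytest.approx(0.4, abs=0.01)

    def test_tau_zero_gives_pure_noise_effects(self):
        cfg = ScenarioConfig(scenario="linear", sparsity="dense", n=400, m=20000,
                             tau=0.0, seed=1)
        _, truth = generate(cfg)
        nonnull = truth.alpha_true[truth.xi[:, 0] == 1]
        assert np.mean(nonnull) == pytest.approx(0.0, abs=3 / np.sqrt(len(nonnull) * 400))
        expect_absmean = np.sqrt(2 / np.pi) / np.sqrt(400)  # E|N(0, 1/n)|
        assert np.mean(np.abs(nonnull)) == pytest.approx(expect_absmean, rel=0.1)

    def test_determinism_and_seed_sensitivity(self):
        cfg = ScenarioConfig(scenario="confounder", sparsity="sparse", n=60, m=200,
                             tau=0.7, seed=42)
        d1, t1 = generate(cfg)
        d2, t2 = generate(cfg)
        np.testing.assert_array_equal(d1.mediators, d2.mediators)
        np.testing.assert_array_equal(t1.xi, t2.xi)
        d3, t3 = generate(ScenarioConfig(scenario="confounder", sparsity="sparse",
                                         n=60, m=200, tau=0.7, seed=43))
        assert not np.array_equal(t1.xi, t3.xi)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            ScenarioConfig(scenario="banana")

    def test_null_statistics_standard_normal_with_oracle_scaling(self):
        # under the double null, a_i / sigma_i1 and b_i / sigma_i2 (true
        # variances) are standard normal
        from mlfdr.regress import fit_structural_models

        cfg = ScenarioConfig(scenario="linear", sparsity="dense", n=200, m=5000,
                             tau=1.1, seed=5)
        data, truth = generate(cfg)
        s = fit_structural_models(data)
        null = (truth.xi[:, 0] == 0) & (truth.xi[:, 1] == 0)
        za = s.a[null] / np.sqrt(truth.var1_true[null])
        zb = s.b[null] / np.sqrt(truth.var2_true[null])
        assert kstest(za, "norm").pvalue > 0.01
        assert kstest(zb, "norm").pvalue > 0.01
        # independence of the two streams within the double-null stratum
        assert abs(np.corrcoef(za, zb)[0, 1]) < 3 / np.sqrt(null.sum())

    def test_binary_outcomes_are_binary(self):
        cfg = ScenarioConfig(scenario="binary", sparsity="dense", n=80, m=50,
                             tau=1.0, seed=2)
        data, _ = generate(cfg)
        assert set(np.unique(data.outcomes)) <= {0.0, 1.0}
        assert data.outcome_type == "binary"

    def test_composite_states_and_coefficients(self):
        cfg = ScenarioConfig(scenario="composite", sparsity="dense", n=100,
                             m=50000, tau=1.0, seed=3)
        _, truth = generate(cfg)
        # margin weights (0.54, 0.18, 0.28) and (0.6, 0.05, 0.35)
        assert np.mean(truth.xi[:, 0] == 0) == pytest.approx(0.54, abs=0.01)
        assert np.mean(truth.xi[:, 1] == 1) == pytest.approx(0.05, abs=0.01)
        assert np.all(truth.alpha_true[truth.xi[:, 0] == 0] == 0)
        assert np.all(truth.beta_true[truth.xi[:, 1] >= 1] != 0)


class TestEvaluate:
    def test_perfect_rejection(self):
        xi = np.array([[1, 1], [0, 1], [1, 0], [1, 1]])
        truth = SimTruth(xi=xi, alpha_true=np.zeros(4), beta_true=np.zeros(4))
        met = evaluate(_result_from_flags([True, False, False, True]), truth)
        assert met.fdp == 0.0 and met.power == 1.0

    def test_zero_rejections_convention(self):
        xi = np.array([[1, 1], [0, 0]])
        truth = SimTruth(xi=xi, alpha_true=np.zeros(2), beta_true=np.zeros(2))
        met = evaluate(_result_from_flags([False, False]), truth)
        assert met.fdp == 0.0 and met.power == 0.0 and met.n_reject == 0

    def test_matches_exhaustive_counting(self, rng):
        m = 50
        xi = rng.integers(0, 2, size=(m, 2))
        rej = rng.random(m) < 0.3
        truth = SimTruth(xi=xi, alpha_true=np.zeros(m), beta_true=np.zeros(m))
        met = evaluate(_result_from_flags(rej), truth)
        alt = (xi[:, 0] == 1) & (xi[:, 1] == 1)
        fd = sum(1 for i in range(m) if rej[i] and not alt[i])
        tp = sum(1 for i in range(m) if rej[i] and alt[i])
        assert met.fdp == fd / max(rej.sum(), 1)
        assert met.power == tp / max(alt.sum(), 1)


class TestRunGrid:
    def test_reproducible_table(self):
        kw = dict(scenarios=["linear"], taus=[1.9], n_values=[100], reps=2,
                  alpha=0.1, seed=9, m=100, sparsities=["dense"],
                  prior_mode="oracle")
        t1 = run_grid(**kw)
        t2 = run_grid(**kw)
        assert len(t1) == 2
        assert (t1["fdp"] == t2["fdp"]).all()
        assert (t1["power"] == t2["power"]).all()

    def test_power_increases_with_tau_oracle(self):
        table = run_grid(
            scenarios=["linear"], taus=[0.3, 0.9, 1.5, 1.9], n_values=[300],
            reps=4, alpha=0.05, seed=3, m=500, sparsities=["dense"],
            prior_mode="oracle",
        )
        from scipy.stats import spearmanr

        means = table.groupby("tau")["power"].mean()
        rho = spearmanr(means.index, means.values).statistic
        assert rho > 0

    def test_baseline_hook_runs_external_command(self, tmp_path):
        # a trivial baseline: reject nothing
        script = tmp_path / "null_baseline.py"
        script.write_text(
            "import sys, pandas as pd\n"
            "df = pd.read_csv(sys.argv[1], sep='\\t')\n"
            "df['rejected'] = 0\n"
            "df[['unit_id', 'rejected']].to_csv(sys.argv[2], sep='\\t', index=False)\n"
        )
        table = run_grid(
            scenarios=["linear"], taus=[1.9], n_values=[100], reps=1, alpha=0.05,
            seed=1, m=100, sparsities=["dense"], prior_mode="oracle",
            baselines={"none": f"python {script} {{summary}} {{out}}"},
        )
        row = table[table["method"] == "none"].iloc[0]
        assert row["n_reject"] == 0 and row["power"] == 0.0


class TestCompositePipeline:
    def test_composite_prior_screen_end_to_end(self):
        cfg = ScenarioConfig(scenario="composite", sparsity="dense", n=200,
                             m=600, tau=1.9, seed=17)
        result, truth, summary, prior = run_pipeline(
            cfg, alpha=0.1, prior_mode="composite", d1=2, d2=2, em_seed=0,
        )
        assert prior.pi.shape == (3, 3)
        assert np.all((result.lfdr >= 0) & (result.lfdr <= 1))
        met = evaluate(result, truth)
        assert 0 <= met.fdp <= 1 and 0 <= met.power <= 1
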