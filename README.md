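# mlfdr

Local-false-discovery-rate screening for high-dimensional mediation
analysis.

## The problem

Genome-wide mediation studies ask, for thousands of candidate mediators at
once, whether an exposure X (a SNP, smoking history) acts on an outcome Y
(gene expression) through an intermediate M (CpG methylation).  Unit i is a
mediator only if both the exposure→mediator slope αᵢ and the
mediator→outcome slope βᵢ are non-zero, so the hypothesis to reject is the
composite null αᵢβᵢ = 0 — the union of {α=0, β≠0}, {α≠0, β=0}, and
{α=0, β=0}.  p-value tests (Sobel, max-p) calibrate against the single-zero
states and lose most of their power when the double null dominates, as it
does genome-wide.

`mlfdr` instead works in the empirical-Bayes two-group tradition.  The
scaled estimates aᵢ = √n α̂ᵢ, bᵢ = √n β̂ᵢ follow a four-component bivariate
Gaussian mixture indexed by the latent state ξᵢ = (1{αᵢ≠0}, 1{βᵢ≠0}) with
proportions π_jk and non-null moments (μ, ψ), (θ, κ), all estimated by EM.
The evidence per unit is the local false discovery rate

    lfdr(aᵢ, bᵢ) = [π₀₀f₀₀ + π₁₀f₁₀ + π₀₁f₀₁](aᵢ, bᵢ) / f(aᵢ, bᵢ),

the posterior probability that the composite null holds.  Sorting lfdr
ascending and rejecting the largest prefix whose running mean stays ≤ α
controls the FDR at α while ranking hypotheses optimally — the advantage
over p-value ranking is largest when the alternative is asymmetric about
the null, which mediation effect sizes typically are.  Extensions cover
mixture-of-Gaussian alternatives per margin (fit by a two-step EM with AIC
model-size selection) and surrogate-factor adjustment for unmeasured
confounding and pleiotropy.

## Worked example

```python
import numpy as np
from mlfdr import ScenarioConfig, generate, fit_structural_models, em_fit, screen, evaluate

cfg = ScenarioConfig(scenario="linear", sparsity="dense", n=300, m=1000,
                     tau=1.9, seed=3)
data, truth = generate(cfg)                 # X, M (300x1000), Y (300x1000)
summary = fit_structural_models(data)       # per-unit a_i, b_i and variances
prior = em_fit(summary, n_restarts=1, seed=1)
print(np.round(prior.pi, 3), round(prior.mu, 2), round(prior.theta, 2))
result = screen(summary, prior, alpha=0.05)
met = evaluate(result, truth)
print(result.k_reject, round(met.fdp, 3), round(met.power, 3))
```

prints

```
[0.443 0.16  0.204 0.193] 1.98 -16.54
109 0.092 0.51
```

The EM recovers the dense mixture proportions (truth 0.4/0.2/0.2/0.2) and
the non-null centers (truth μ = 0.05·τ·√n ≈ 1.65, θ = −0.5·τ·√n ≈ −16.45).
At α = 0.05 the screen rejects 109 of 1000 units; against the generator's
truth that realization has a false discovery proportion of 0.092 and
recovers 51% of the true mediation signals.

The same workflow is available from the shell:

```
mlfdr simulate --scenario linear --n 300 --m 1000 --tau 1.9 --seed 3 --out-prefix sim/
mlfdr fit --mediators sim/M.tsv --outcomes sim/Y.tsv --exposure sim/X.tsv --out summary.tsv
mlfdr screen --summary summary.tsv --alpha 0.05 --out result.tsv
mlfdr adjust ... / mlfdr benchmark --config grid.yaml --out results.tsv
```

`screen` writes the per-unit table (unit_id, a, b, lfdr, rank, rejected)
plus JSON sidecars with the fitted prior and the realized threshold, so the
screen can be re-run at a new α without re-fitting.  Summary tables from
external regression workflows enter through `summary_from_table`
(columns: unit_id, alpha_hat, beta_hat, se_alpha, se_beta, n).

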