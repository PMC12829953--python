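# Methods

## The screening problem

For each of m candidate mediators the data follow a pair of structural
equations

    M_i = X alpha_i + e_i,
    Y_i = M_i beta_i + X gamma_i + eps_i,

with independent errors, optionally with measured covariates Z in both
designs and an always-included intercept.  A unit carries a mediation signal
only when both alpha_i and beta_i are non-zero; the null alpha_i beta_i = 0
is the union of three disjoint states, indexed by the latent pair
xi_i = (1{alpha_i != 0}, 1{beta_i != 0}).  The composite structure is what
defeats classical tests: Sobel and max-p calibrate against the single-zero
states and are far too conservative when the double null dominates, which it
does genome-wide.

All inference runs on the sqrt(n)-scaled coefficient estimates
a_i = sqrt(n) alpha_hat_i and b_i = sqrt(n) beta_hat_i with conditional
variances sigma_i1^2 = n Var(alpha_hat_i), sigma_i2^2 = n Var(beta_hat_i).
Conditional on the design, (a_i, b_i) are independent normals.  Residual
variances use the unbiased RSS/(n-p) denominator; the per-unit variances
are then treated as known (empirical-Bayes plug-in), ignoring their
estimation noise — the standard convention, and one of the finite-sample
approximations discussed under Limitations.  Binary outcomes swap the
outcome-side OLS for a per-unit logistic Newton fit (log-likelihood
tolerance 1e-8, 100 iterations, separation flagged when a standardized
coefficient passes 50); the mediator model stays linear.

## Mixture prior and EM

The working prior places mass pi_jk on each latent state and draws non-null
scaled effects from single normals: sqrt(n) alpha_i ~ N(mu, psi) when
xi_i1 = 1, sqrt(n) beta_i ~ N(theta, kappa) when xi_i2 = 1.  Marginally,

    (a_i, b_i) | xi_i ~ N(mu xi_i1, sigma_i1^2 + psi xi_i1)
                        x N(theta xi_i2, sigma_i2^2 + kappa xi_i2),

mixed over pi.  Parameters are estimated by EM.  Because the base variances
are unit-specific there is no closed-form M-step for (mu, psi): mu given psi
is a precision-weighted mean, and psi solves a monotone 1-D score equation
(warm-started Newton with a bisection bracket).  Each EM sweep performs two
such coordinate-maximization alternations per margin — a generalized EM
step, so the observed-data log-likelihood still ascends monotonically (a
property test asserts it).  With equal base variances one alternation
reproduces the textbook closed form, which serves as a unit-test oracle.

Defaults: convergence at relative log-likelihood change < 1e-8 or 1000
iterations; component proportions floored at 1e-6 (keeping the lfdr
well-defined); 5 restarts (first start deterministic and data-driven —
proportions (0.7, 0.1, 0.1, 0.1), non-null means from trimmed top-decile
magnitudes, excess variances from variance decomposition — the rest
jittered).  Simulation loops in this package use a single restart: the
deterministic start is reliable there and restart jitter mostly re-finds
likelihood ties.

Boundary non-identifiability: when a margin carries no real signal the
fitted non-null component collapses onto the null (mu ~ 0, psi ~ 0) and the
likelihood becomes exactly flat in how mass splits between the two — the
proportions are then arbitrary.  After fitting, any non-null component with
standardized separation (mu^2 + psi) / mean(sigma^2) below 0.1 is folded
into the null margin.  Pure-null fits settle at separations up to ~0.08 from
sampling kurtosis alone, and a true component below 0.1 is undetectable at
realistic m, so the merge only resolves likelihood ties — and it errs toward
the null, which is conservative for FDR.

## Composite alternatives: the two-step EM

When effect sizes are themselves heterogeneous, each margin gets a pinned-
null mixture with d non-null components (means mu_u, excess variances
kappa_u).  Fitting the full (d1+1)(d2+1)-component bivariate mixture jointly
is expensive, so estimation is split: step 1 fits each univariate margin by
EM; step 2 freezes all moments and re-estimates only the joint proportion
table pi_uv (responsibility averaging from the independence start).  Only
the joint table is updated in step 2; the step-1 marginal weights are kept
for diagnostics.  d is selected by AIC with parameter count 3d (mean,
excess variance, and weight per non-null component), ties to the smaller d;
the default cap is d <= 10.  Marginal fits default to the single
deterministic quantile-spread start: with heavily overlapped components the
likelihood is nearly flat in the weights and jittered restarts land on
likelihood-equivalent but poorly identified configurations.

At d1 = d2 = 1 the composite lfdr reduces exactly to the simple one with
matching parameters (tested), and the two-step and standard EM screens
agree to within a 2% rejection-set symmetric difference on shared data.

## Local FDR and the step-up screen

The lfdr of unit i is the posterior null probability

    lfdr(a_i, b_i) = [pi00 f00 + pi10 f10 + pi01 f01] / f,

computed in log-space with densities floored at 1e-300 and the ratio
clipped to [0, 1]; under the composite model the null mass is every
component with u = 0 or v = 0.  The screen sorts lfdr ascending and rejects
the largest prefix whose running mean is at or below alpha — the running
mean of the k smallest lfdr values estimates the marginal FDR of rejecting
exactly those k units.  The realized threshold is reported as the k-th
order statistic, so "reject iff lfdr <= delta_hat" reproduces the set.

Ties: the raw prefix scan can split a group of equal lfdr values at the
boundary, which breaks the threshold characterization and the equivalence
with the sup-over-thresholds form.  The default therefore lets the cutoff
index stop only at tie-group boundaries (equal values are all in or all
out); a seeded random tie-break is available for strict fidelity to the
randomized description.  For continuous statistics ties have probability
zero and the variants coincide.

The oracle variant evaluates the lfdr at the true prior AND the true
conditional variances given the realized design (the generator records
them).  Plugging estimated variances into an otherwise-true prior already
costs ~+0.01 of FDR at n = 300 — tail densities are exponentially sensitive
to an 8%-noisy variance.

## Latent-factor adjustment

Unmeasured structured variation — batch effects, hidden confounders, or
pleiotropy (other mediators feeding the outcome) — biases the per-unit
fits.  The adjustment residualizes the mediator matrix (and the outcome
matrix, mediators excluded) on [1, X, Z], standardizes residual columns,
and extracts leading principal components as orthonormal factor scores;
mediator factors U_M enter both models, outcome factors U_Y only the
outcome model.  This is a residual-PCA realization of surrogate-variable
adjustment; the iteratively reweighted variant is deliberately out of
scope.  Its validity leans on each single mediator contributing little
outcome variance, which the generator respects.

Dimension selection is permutation parallel analysis with sequential
deflation: the leading singular value of the current residual matrix is
kept if it exceeds the 95th percentile (conservative 'higher' quantile —
exceedance <= 1/(B+1) under exchangeability) of B = 20 column-permuted
copies of that same matrix, the component is deflated, and the test
repeats (cap 10).  Deflation matters: after a dominant factor, permuting
the original matrix yields thresholds far above any later singular value.

A limit worth knowing: a confounder that loads on every mediator with the
same vector w shifts every alpha_hat by the common amount X'w / X'X — the
chance in-sample correlation between the randomized exposure and w.  Factor
scores estimated from X-residualized residuals are orthogonal to X by
construction, so no global adjustment can absorb this shift (sd ~0.64 on
the scaled axis at n = 300 with Var(w) = 0.41).  In replicates where the
draw is large the EM misreads the shifted null and the FDR degrades; the
adjustment still cuts mean FDP by a factor of ~3 relative to no adjustment
in that scenario, but does not reach the nominal level there.

## Synthetic scenarios

`simulate` draws latent states i.i.d. from dense (0.4, 0.2, 0.2, 0.2) or
sparse (0.88, 0.05, 0.05, 0.02) proportions; non-null effects are
alpha_i = 0.05 tau + h_i, h ~ N(0, 1/n) and beta_i = -0.5 tau + g_i,
g ~ N(0, 4/n), so on the sqrt(n) scale the true prior is
N(0.05 tau sqrt(n), 1) x N(-0.5 tau sqrt(n), 4) — strongly asymmetric
between margins, the regime where lfdr ranking beats p-value ranking.
Direct effects gamma_i ~ N(1, 0.5) (0.5 a variance).  Scenarios: plain
linear; measured confounder Z ~ N(0,1) with U(0, 0.5) loadings; binary
logistic outcome (intercept 0, baseline prevalence 1/2); hidden
exposure-mediator interactions X * sum_{j in S} theta_j M_j with |S| = 20
and theta_j ~ U(0.3, 0.6) (a distribution the source conditions leave
open; configurable); unmeasured confounding (loadings 0.4, 0.5 on M and
-0.5 on Y) plus dense pleiotropy sum_S M_j kappa_j, kappa_j ~ U(0.3, 0.6)
(same status); and composite alternatives with margin weights
(0.54, 0.18, 0.28) / (0.6, 0.05, 0.35), means (0.05 tau, -0.5 tau) and
(0.9 tau, -0.01 tau), excess variances (1, 2) and (1.5, 2).  Error SDs
default to 1 everywhere and are configurable.

The exposure deserves a note.  The default is standard normal, which makes
sigma_i1^2 ~= sigma_i2^2 ~= 1 — the scale on which the prior spreads (1 and
4) and the composite excess variances (order one) are meaningful, and the
regime in which the tau grid sweeps power from near zero to moderate while
FDR sits near nominal.  A Bernoulli(p) exposure is available
(`exposure_dist="bernoulli"`); at p = 0.1 it carries an order of magnitude
less information per sample (sigma_i1^2 ~= 1/(p(1-p)) ~= 11), which leaves
the alpha-margin z below 0.5 across the whole tau grid and every screening
method — including the oracle — without a single rejection at alpha = 0.05.

One root seed spawns per-cell and per-replicate substreams, so any grid
cell reproduces independently.  Scoring: FDP = false rejections / max(R, 1)
(zero when nothing is rejected), power = rejected true alternatives / their
count.  What passing these simulations does NOT show about real data:
mediators here are independent across units, effects are exactly Gaussian
around tau-scaled centers, and variances are homogeneous — correlated CpG
blocks, heavy-tailed effects, and variance heterogeneity are untested.

## Problem sizes used by the test suite and acceptance script

FDR-control checks run the linear model at n = 300, m = 1000 with 100
replicates per cell (tests) or 50 (acceptance script); EM recovery uses
m = 5000 over 20 seeds (10 in the script); the factor-adjustment comparison
runs 50 (25) replicates; the global-null permutation check 100 (60); the
power comparison against max-p + BH runs a reduced grid (tau in {1.1, 1.5,
1.9}, both sparsities, 4 replicates per cell).  All stochastic bounds are
alpha + 2 Monte-Carlo standard errors computed from the replicates run.

## Known limitations

- Adaptive FDR control is asymptotic.  At the weakest signal on the grid
  (tau = 0.5) the EM-plug-in screen is measurably anti-conservative at
  m = 1000 (mean FDP ~0.08 dense, ~0.14 sparse at alpha = 0.05) even with
  exact base variances; the effect shrinks with tau and with m.
- The common-loading confounder shift described above caps what factor
  adjustment can deliver in the pleiotropy scenario.
- The prior assumes a and b independent given xi and zero-correlation
  bivariate normals; with covariates and logistic outcomes this holds only
  asymptotically.
- p-values are not produced; the method is lfdr-native.
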