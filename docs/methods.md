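# Methods

This note records the models the package implements, the conventions and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Phylogeny and units

Branch lengths are in millions of years (mya) throughout; Markov switch
rates, Brownian variances and OU pull strengths are therefore per mya, and
phylogenetic half-lives come out in mya. The OU likelihood is invariant
under jointly rescaling the tree by c and (alpha, sigma²) by 1/c (a tested
property), so conclusions do not depend on the absolute calibration.
Simulated trees default to a height of 30 mya — a configurable,
genus-scale choice, not an empirical estimate.

Newick parsing and writing are backed by dendropy; quoted labels and
comments are accepted, polytomies are allowed everywhere (the covariance
formulas do not require bifurcation). Zero-length internal edges are
collapsed on parse to avoid exactly singular covariances; zero-length
terminal edges are kept. Pruning is implemented in-package because
stochastic regime maps must be carried through a prune: each retained edge
records which original edges were concatenated into it, and a chain of
edges absorbed above the new root becomes a stem (`root_length`) so that
root-to-tip distances — and hence the covariance submatrix — are exactly
preserved.

## Elevational regimes and stochastic maps

Species at or below 1500 m a.s.l. median elevation are "low", above it
"high" (closed-low boundary convention; deterministic and affecting only
measure-zero inputs). The 2-state Mk likelihood uses the pruning recursion
with closed-form 2×2 transition matrices and a flat (1/2, 1/2) root prior —
flat rather than stationary so that ER and ARD are compared on the same
prior. ML rates are found by bounded quasi-Newton on log rates from an
8-point multi-start grid over [1e-6, 100] per mya.

One boundary behavior is worth knowing: when every tip is in one state, the
ER maximum is at the rate floor with log-likelihood log(1/2), but ARD can
push the rate out of the unobserved state toward the upper bound, making an
instantaneous "flicker" from the other root state and logL → 0. This is the
genuine maximum under a flat root prior, not an optimizer artifact; the
test suite documents it.

Stochastic maps draw node states from their conditional distribution given
the tips (root-to-tip, using pruning partials), then fill each branch with
an endpoint-conditioned path: rejection sampling (forward simulation,
capped at 1000 attempts) with an exact uniformization fallback, so
termination is guaranteed even for long branches with incompatible
endpoints. Samplers were checked against conditioned forward simulation
(jump counts) and against the pruning marginals (total variation < 0.02
over 10,000 maps).

## Trait-evolution models

Five models, with free-parameter counts fixed as WN:2, BM1:2, BMM:3,
OU1:3, OUM:4 so AICc values are self-consistent within the package:

* WN: mean mu, covariance sigma² I.
* BM1: mean x0, covariance sigma² C (C = shared-time matrix).
* BMM: each branch contributes sigma²_state × duration summed over its map
  segments; mean x0.
* OU1/OUM (ultrametric trees only): V_ij = sigma²/(2 alpha) ·
  exp(−alpha d_ij) (1 − exp(−2 alpha s_ij)) with s_ij shared time and
  d_ij = 2(T − s_ij). OUM shifts only the optimum between regimes; alpha
  and sigma² are shared. The OUM mean integrates the optima along each
  root-to-tip regime history: each segment [t0, t1] in state s contributes
  theta_s (e^{−alpha (T−t1)} − e^{−alpha (T−t0)}), plus x0 e^{−alpha T}.

The OU root state x0 is pinned to the optimum of the root's regime rather
than estimated: the paper-scale data (T ≈ 30, alpha ≳ 0.1) leave the root
term weak, and this keeps OUM at four parameters ("two optima"). Regime-
specific alpha or sigma² for OU, and correlated multi-trait models, are
deliberately out of scope.

Measurement error is a known diagonal: SE of the species mean across sowing
rounds, squared, added to every model covariance. It is never estimated;
single-round species get the trait's median SE imputed (flagged upstream).

Fitting profiles the location parameters (mu, x0, theta, or the OUM optima
via their design matrix) by GLS at each evaluation of the variance
parameters, which are optimized on the log scale by L-BFGS-B. OU fits start
from a 10-point log-spaced alpha grid on [1e-4, 1e2]; all starts are
scored and the best three refined, which preserves the multi-start
robustness at a third of the cost. The MVN log-density is an in-package
Cholesky implementation, cross-checked in tests against an independent
dense evaluation to 1e-8 over all five models. A constant trait vector with
zero SE is rejected as degenerate.

## Model selection and half-life

AICc = −2 logL + 2k + 2k(k+1)/(n−k−1). Because ancestral regimes are
uncertain, the five models are fitted per stochastic map and summarized by
consensus: the modal per-map winner (ties toward fewer parameters), the
median across maps of (winner − runner-up) AICc, and the |ΔAICc| ≤ 2
equivalence rule for "among the best" support. Mean AICc per model across
maps is also reported, since modal vote and mean AICc are both defensible
aggregations.

Half-life t1/2 = ln(2)/alpha. Its uncertainty comes from refitting after
randomly removing a third of the species (default 200 replicates at desk
scale; the rule itself is unchanged at any replicate count), with
significance declared when mean − 1.64 SD > 0. Half-life bootstrap
distributions are heavy-tailed — a few weak-pull (alpha ≈ 0) refits can
inflate the mean by orders of magnitude — which is exactly why the
significance rule subtracts 1.64 SD rather than trusting the mean.

The growth-environment effect on evolutionary lability is a linear mixed
model on log half-life with treatment fixed (baseline Mild) and trait as a
random intercept, fitted by ML (statsmodels MixedLM), with 90% percentile
intervals from bootstrapping over traits. A contrast of log(0.5) ≈ −0.693
corresponds to a 50% half-life reduction.

## Growth curves and tolerance

The logistic fit is nonlinear least squares (scipy `least_squares`, TRF)
with self-starting values: ASYM₀ = 1.05 max y, XMID₀ = first day reaching
half of max y, scal₀ from the 25–75% rise interval divided by 2.2 (the
logistic rises 25→75% over ≈2.2 scale units). Fits whose ASYM reaches the
(generous, 100 × max y) upper bound never saturate and are flagged
non-converged; they are excluded from species means rather than imputed.
IGR is the OLS slope over the first 7 days of treatment (the window is a
package convention, configurable). Tolerance is (stress − mild)/mild,
undefined when the mild estimate is zero; it is scale-invariant, which the
suite checks property-based.

## Phylogenetic mixed model

The response (identity, log, or logit scale; logit with the boundary
shrinkage y' = (y(n−1)+0.5)/n for proportion data) is modeled with fixed
effects {treatment contrasts, mean-centered elevation, interaction} and
random effects {sowing round, phylogenetic species effect with covariance
proportional to C normalized to unit mean diagonal}. Estimation is ML:
fixed effects profiled by GLS inside a bounded search over variance-
component ratios; the residual variance has a closed-form profile. This is
a deliberate likelihood-based re-design of what is usually run as a
Bayesian MCMC model: 90% parametric-bootstrap percentile intervals play the
role of credible intervals, probability-of-direction tiers ((.) > 95%,
* > 97.5%, ** > 99.5%, *** > 99.95%) are computed from the bootstrap draws,
and the phylogeny's contribution is judged by AICc with/without the effect
instead of cross-validation scores. When generating bootstrap data the ML
residual variance is rescaled by n/(n−p) (degrees-of-freedom correction);
without it the intervals are measurably anticonservative. Null coverage of
the 90% intervals was verified at ≥ 85% across 100 synthetic datasets.
Maternal-line and block random effects are not modeled at the species-mean
level; only round and phylogeny enter.

## Multivariate screening

Standardization uses the sample (n−1) SD — this changes standardized
fixtures, hence documented. VIF pruning recomputes VIF_j = 1/(1−R²_j) by
direct regression and drops the largest while any exceeds 10; ties break
toward the earlier column, making the result deterministic and row-order
invariant; perfectly collinear columns (infinite VIF) go first. DAPC is
PCA (on the standardized matrix) → linear discriminant on the retained
scores → discriminant vector mapped back to trait space; contributions are
its squared entries normalized to 1, applied per discriminant axis with
the selection quantile (default the third quartile) recomputed from the
data at hand. PC retention is chosen by repeated stratified holdout
(default 10% per group, at least one species) minimizing mean squared
assignment error with ties to highest success then fewer PCs. Note the
standardized-data caveat: after z-scoring, all columns have variance 1, so
a discriminating direction is not guaranteed to lie in the top few PCs;
retaining too few PCs can cost accuracy even on separable data. In-sample
DAPC accuracy under permuted labels retains a small optimism bias above
0.5, as expected for LDA. Species with any missing value are excluded from
DAPC; correlations are pairwise-complete (≥ 3 pairs) with p from
t = r sqrt((n−2)/(1−r²)) and stars at 0.05/0.01/0.001, deliberately
without multiple-testing correction.

## Synthetic data: what it emulates, and what not

The generator reproduces the study's structure: a pure-birth tree
(ultrametric, rescaled to a configurable height), regimes evolving forward
under asymmetric switch rates (defaults 0.030 low→high and 0.910 high→low
per mya; stationary low fraction ≈ 0.97), species asymptotic sizes evolving
under OUM toward regime-dependent optima per treatment (defaults: frost
57.15/30.44, mild 64.85/38.72, heat 70.16/23.65 mm — realistic magnitudes
used as inputs, never asserted as recoverable truth of any real study),
maternal-line and residual noise, logistic growth series on a day grid to
day 35, logit-normal resistance scores in (0,1), and elevations drawn
uniformly within each regime's band. The default design yields exactly
100 × 6 × 3 = 1800 individuals, with the six lines split across two sowing
rounds so that between-round SEs exist.

It does not emulate: germination failure and replacement (every plant
exists), block effects (present but default 0), trait correlations beyond
those induced by shared regimes, non-Gaussian trait noise, or any spatial
structure in elevation. Passing recovery tests therefore show the
estimators work under the model's own assumptions at realistic sizes — not
that real data meet those assumptions.

Two study-condition choices deserve emphasis. First, recovery and
validation experiments for the two-optimum model simulate the regime
history with symmetric rates (0.05/mya) so both regimes are represented at
the tips: under the strongly asymmetric default rates the minority regime
collapses to a handful of tips, theta_HIGH becomes unidentifiable and its
"recovery" meaningless — whereas a real species panel for such a study is
deliberately selected to represent the whole gradient. The asymmetric
defaults remain in force for the design emulation and for switch-rate
recovery itself. Second, ML estimates of a fast switching rate (0.91/mya
on a 30-mya tree) are upward-biased at a hundred tips — the acceptance
script reports the median estimate as computed, bias included.

## Scale of the shipped checks

Desk-scale defaults keep the full test suite within minutes: half-life
bootstraps default to 200 replicates (the 10,000-replicate setting is one
argument away), cross-validation to hundreds rather than 10,000 repeats,
and the validation grid to tens of replicates per cell. The acceptance
script uses 8–25 replicates per quantity and states each problem size in
its output (`n`).
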