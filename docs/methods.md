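# Methods

## The problem

Gene–environment (GxE) interaction studies ask whether the association
between a continuous exposure X (e.g. cigarettes per day) and a binary
disease outcome D differs across genotype groups G (0/1 carrier coding
or 0/1/2 allele dosage), adjusting for confounders Z. The standard
analysis fits the prospective logistic model

    logit Pr(D=1 | G, X, Z) = α₀ + m(Z) + αx·X + αg·G + αgx·G·X

and tests H₀: αgx = 0 with the 1-df Wald statistic τα² = α̂gx²/Var̂(α̂gx).
exp(αgx) is the ratio of odds ratios (ROR): the X–D odds ratio at G=g+1
divided by that at G=g.

## The reverse test

This package implements the *reverse* formulation: treat the exposure
as the response,

    X = β₀ + h(Z) + βg·G + βd·D + βgd·G·D + ε,   ε ~ N(0, σ²),

fit by OLS, and test H₀: βgd = 0 with τβ² = β̂gd²/Var̂(β̂gd), referred to
the χ²₁ upper tail. When ε is homoskedastic normal, the logistic and
linear models can hold simultaneously with αx = βd/σ² and αgx = βgd/σ²,
so the two tests address the same null, and ROR = exp(βgd/σ²) is
estimable from the linear fit. Two weaker interaction scales require no
normality at all: the difference of mean differences DMD = βgd, and the
difference of exposure–disease correlations across genotype groups —
βgd = 0 remains a valid interaction null for the DMD scale under
arbitrary error distributions. The practical draws are power (the
linear-discriminant style use of the exposure distribution) and speed
(a closed-form statistic against an iterative IRLS fit per variant).

Under heteroskedasticity the model-based Var̂(β̂gd) is invalid; a
heteroskedasticity-consistent sandwich covariance is provided (HC0
default, HC1/HC3 options) and `wald_gd(..., variance="sandwich")`
keeps the test's size. Residual diagnostics (`diagnostics`) report
Jarque–Bera normality, a White heteroskedasticity test and residual
skewness. The White test here is an in-package rank-aware LM version:
the textbook auxiliary design (regressors, squares, cross-products) is
rank deficient by construction whenever the design contains binary
columns, so collinear directions are dropped by QR and the χ² df is
the post-reduction rank minus one.

### ROR confidence interval

The reference derivation of SE(ROR̂) is not printed; we use the delta
method on log ROR̂ = β̂gd/σ̂², treating β̂gd and σ̂² as independent (exact
under normal theory) with Var(σ̂²) = 2σ̂⁴/df:

    SE(log ROR̂)² = Var̂(β̂gd)/σ̂⁴ + 2·β̂gd²/(σ̂⁴·df_resid).

### Measurement error

Classical additive error X* = X + δ, δ ~ N(0, σδ²) independent of
everything, leaves every coefficient of the linear model unchanged
(the error is absorbed into ε, now with variance σ² + σδ²), so the
reverse test of βgd = 0 needs no correction; ROR̂ is attenuated because
σ̂² is inflated. On the logistic side the naive α̂gx* is attenuated by
the reliability ρ = Var(X)/Var(X*); `calibrate_attenuation` applies
regression calibration α̂gx ≈ α̂gx*/ρ̂ with ρ̂ = (Var̂(X*) − σδ²)/Var̂(X*),
valid for rare disease with normal X|G,Z or small Var(X|X*,G,Z).

### Transformations

Right-skewed exposures can be symmetrised before the reverse fit with
the nonnegative-branch power transform T(x) = ((x+1)^γ − 1)/γ
(log(x+1) at γ = 0). γ is estimated by bounded scalar search of the
normal profile log-likelihood over [−2, 2]; the branch for negative x
is out of scope.

## Confounder adjustment

Continuous confounders enter through spline bases: a cubic B-spline
with k interior knots at evenly spaced percentiles (k+3 columns, no
intercept column; boundary knots at the observed min/max — a
convention, since no boundary rule is stated in the source material),
or a restricted cubic spline (M total knots → M−1 columns; M=2 is the
plain linear term). Bases can be frozen at fit time and re-evaluated on
subsets, which the scan uses so all variants share one basis. Optional
robustness blocks add confounder-by-gene products (both models),
confounder-by-disease products (reverse model) and
confounder-by-exposure products (logistic model); under ordinal dosage
with confounder-by-gene adjustment a G² column is added.

## The compatible simulator

Simulations use the joint model (all defaults are the stated
experimental conditions of the reference tables):

    logit Pr(D=1|G,X,Z) = α₀ + α₁Z₁ + α₂Z₁² + α₃Z₂ + αg·G + αx·X + αgx·G·X
    X = β₀ + β₁Z₁ + β₂Z₁² + β₃Z₂ + βg·G + βd·D + βgd·G·D + ε,  ε ~ N(0,1)

with generation order Z → G → D|G,Z → X|D,G,Z. The D|G,Z law is the
unique logit making both models exact by Bayes' rule:

    c(G,Z) = α₀ + m(Z) + αg·G + Δ(G)·(β₀ + h(Z) + βg·G)/σ² + Δ(G)²/(2σ²),
    Δ(G) = βd + βgd·G.

Scenario knobs map to coefficients as: α₀ = logit(p₀);
αg, αx, αgx = log of OR(D|G,X=0), OR(D|X,G=0), ROR; α₁=α₂=α₃ = log 1.2;
β₀=0, β₁=β₂=0.03; β₃ = Corr₀(X,Z₂)·√(1/Var Z₂);
βg = Corr₀(X,G)·√(1/Var G); βd = αx, βgd = αgx, σ² = 1.

Marginals not pinned down by the printed description: Z₁ ~ N(0,1),
Z₂ ~ Bernoulli(0.5), and G ~ Binomial(2, 0.3) (0/1/2 dosage),
independent of Z. The ordinal genotype marginal is this package's
reconstruction: the source describes gene effects per unit increase of
G in the simulation settings, and the printed relative-power table is
reproduced under Binomial(2, 0.3) but not under a Bernoulli(0.3)
carrier coding (which yields e.g. 1.28 instead of 1.48 in the
strong-exposure cell). A binary coding remains available.

Measurement error is injected at reliability ρ by sizing
σδ² = Var̂(X)·(1−ρ)/ρ from the generated cohort's marginal exposure
variance. Two misspecification families break compatibility on
purpose: Scenario I replaces the compatible D|G,Z law with a plain
logistic one, Scenario II replaces ε with a rectified Gaussian
max(W,0), W ~ N(0,1), centred and scaled to unit variance (the
standardisation is our choice, so that power comparisons are not
confounded by scale). Each comes in a "linear generation" variant
(linear model correct) and a "logistic generation" variant (X drawn
marginally, then D | X,G,Z — a reconstruction, since the supplementary
procedure is not printed).

What the simulator does *not* emulate: linkage disequilibrium between
variants, genotype–covariate dependence, non-classical (differential)
measurement error, and missingness mechanisms. A green Monte-Carlo
test therefore establishes calibration and relative efficiency under
the stated generative world, not robustness to those features.

## The experiment harness

Each replicate simulates a 100,000-subject cohort, draws 1000 cases +
1000 controls (frequency matching on outcome counts only), builds both
designs with a cubic B-spline (3 interior knots) on Z₁ and a linear Z₂
term, fits both models on the same data (on X* when ρ < 1), and
records both 1-df Wald statistics. Summaries: empirical rejection at
each nominal level with the binomial band p ± 1.96√(p(1−p)/B), and the
relative-efficiency measure χ̄²rev/χ̄²log (paired means over successful
replicates). Replicate failures (separation, collinearity,
non-convergence) are excluded and counted; >1% failures flags the
experiment. Reference results use 500,000 replicates; the desk-scale
defaults here are 10,000 replicates for 5%-level size and 5,000 per
ratio cell, which resolve the 5% rows and ratio values but not
0.01%-level tails. Randomness: one integer seed spawns per-replicate
SeedSequence substreams, so results are reproducible and independent
of chunking. As an implementation shortcut for the compatible model
only, exposure noise is realised just for the sampled 2000 subjects
(X is conditionally iid given D,G,Z and selection depends only on D,
so this is distributionally identical to simulating the full cohort's
exposures).

## Numerical choices

- OLS via Cholesky of X'X with an explicit pivot check (pivot² ≤
  1e-12 × column scale → collinearity error naming the offending
  column, located by QR).
- IRLS: start at the intercept-only fit; step-halving enforces a
  non-decreasing log-likelihood; convergence needs relative
  log-likelihood change < 1e-10 *and* max score component < 1e-6·√n;
  max 50 iterations; |coef| > 30 or a singular information matrix
  raises a separation error rather than returning a fragile fit.
- Wald p-values use the χ²₁ upper tail (asymptotic), not t/F.
- Genomic inflation λ = median(χ²obs)/0.4549; variant filters are
  strict inequalities (MAF > 1%, call rate > 95%); missing dosages are
  complete-case per variant (mean imputation by flag).
- Case-control data are fitted with the ordinary prospective logistic
  likelihood (valid for interaction ORs under outcome-based sampling);
  the reverse test is likewise valid under this design.

## Known limitations

- The bootstrap-refined sandwich (BICS), exact/Firth logistic,
  penalised splines, automatic knot selection, genotype imputation and
  LD analysis are out of scope.
- The correlation-difference (DCC) statistic is not implemented; its
  operationalisation of conditioning on Z is not printed in the source
  material.
- The ROR interval treats β̂gd and σ̂² as exactly independent, which is
  an approximation outside exact normal theory.
- Desk-scale replication cannot resolve 0.01%-level type I error.
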