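# Methods

## Problem and model

A black-bloom survey measures p = 14 aquatic factors at n sites (the
reference survey: n = 58). For each of the three bloom state variables
— Fe(II), S(−II), SSC — the screen fits

    y = μ1 + Xβ + ε,  ε ~ N(0, σ²ε I),

where X holds the standardised candidate main effects plus every
pairwise product of them, each product column re-standardised. Factors
nearly collinear with the response are excluded up front: S(−II) and
SSC when Fe(II) is the response, Fe(II) and SSC for S(−II), nothing for
SSC. That yields 11 + 55 = 66 candidate columns for Fe(II)/S(−II) and
13 + 78 = 91 for SSC — oversaturated relative to n = 58, so OLS is
ill-posed and sparsity is supplied by the prior.

Products are taken of the *standardised* mains and then re-standardised
(the source analysis does not fix the order of the two operations).
This keeps every design column unit-variance, so the explanation ratios
below compare main and interaction terms on one scale.

## Prior and fitting

Each coefficient has the three-level NEG hierarchy

    βj | σj² ~ N(0, σj²),  σj² | λ ~ Exp(λ),  λ ~ Gamma(shape a, rate b).

Integrating λ out leaves p(σj²) = a bᵃ / (b + σj²)^(a+1); integrating
σj² out at fixed λ leaves the Laplace marginal with rate √(2λ) — the L1
penalty in Bayesian form. Note the parameterisation: b is the gamma
*rate* (inverse scale), so E[λ] = a/b and *smaller* b (or larger a)
means a heavier penalty. a = −1 switches the hyperprior term off
entirely, leaving pure evidence maximisation.

Fitting is empirical Bayes by greedy coordinate ascent on the marginal
log-posterior of the variance parameters (β integrated out):

    L(σ²) = log N(y; μ1, σ²ε I + X diag(σ²) Xᵀ) − (a+1) Σj log(b + σj²).

Holding all other parameters fixed, the restricted objective in one
σj² depends on the standard sparse-Bayesian quantities sj (sparsity)
and qj (quality); its stationary points solve the quadratic

    s²(2a+3) t² + [s(4a+5) + s²b − q²] t + [2(a+1) + b(s − q²)] = 0,

and the update keeps the best positive root only if it improves on
t = 0, otherwise the coefficient is pruned exactly. Sweeps run in fixed
design order from the empty model; μ is the response mean; σ²ε is
re-estimated once per sweep from the residual sum of squares divided by
n minus the summed effective degrees of freedom γj = 1 − Σjj/σj².
Everything is computed from Gram matrices (XᵀX, Xᵀy), so cost per sweep
is independent of n after the one-off O(np²) precomputation.

Numerical choices: convergence when the largest absolute change in
(μ, posterior β, σ²ε) falls below tol = 1e−6, max 10⁴ sweeps (typical:
20–40); support capped at n − 2; columns numerically in the span of the
active set (s ≤ 1e−14) are pruned, so among exact duplicates the first
in design order wins. The fit contains no randomness.

Conditional on the selected variances the posterior of the retained β
is Gaussian with covariance σ²ε (X_AᵀX_A + σ²ε D⁻¹)⁻¹. Significance
uses t = mean/SD with df = n − k − 1 (k retained terms) — the OLS
analogy, which also reproduces the reference adjusted-R² convention
(0.841, n=58, k=3 → 0.832 exactly; the two reference equations whose
printed adjusted R² differ from this formula in the third decimal,
0.602 vs 0.600 and 0.778 vs 0.776, are attributed to rounding in the
printed R² — no alternative formula is used).

The reported equation keeps the significant terms (p < 0.05), matching
the reference analysis in which every printed term is significant; if
no term passes, the single most significant one is kept rather than
reporting an empty equation.

## Hyperparameter selection

(a, b) are picked by k-fold CV (default k = 5, seeded balanced folds,
fold sizes differing by ≤ 1) over the grid a ∈ {−0.9, −0.6, −0.3,
−0.1, 0.01, 0.1, 0.5, 1} × b ∈ {0.01, 0.1, 0.5, 1}, which brackets the
optima reported for the reference survey. Selection is plain minimum
mean held-out MSE (reported with the SE of fold MSEs; no one-SE rule),
MSE on the standardised response scale. Held-out predictions are kept
per grid point so the bookkeeping is exactly recomputable. Without CV
the default prior is the weakly informative gamma(0.1, 0.1).

## Reporting

* Explanation ratio ERᵢ = |βᵢ| / Σⱼ|βⱼ| over the equation's
  non-intercept terms. The intercept is excluded from the denominator —
  the convention that reproduces the reference percentages (e.g. 76.1%
  for TP from coefficients 0.959/0.134/0.167).
* Coefficient CV = posterior SD / |posterior mean|.
* Posterior density curves are the closed-form Gaussians on mean ± 4 SD,
  with P(coefficient < 0) reported to quantify sign uncertainty.
* Pearson table: pairwise r with two-sided p from t = r√(n−2)/√(1−r²),
  df = n − 2; stars ** (p<0.01) and * (p<0.05).
* Equations are printed with terms in descending |coefficient|, three
  decimals, trailing intercept; interaction names use the canonical
  factor order of the schema.

## Synthetic data

The generator emulates the reference survey: per-factor means and SDs,
and the published 14×14 pairwise correlation matrix (repaired to the
nearest PSD correlation matrix by Higham's alternating projections if
needed — the published matrix happens to be PSD already). Sites are iid
correlated Gaussian vectors rescaled to the target moments; one integer
seed drives all draws. Gaussian marginals are the default because the
regression model assumes Gaussian *errors*, not Gaussian predictors;
they do allow physically nonnegative factors (notably SSC) to go
negative, which the I/O layer flags with a warning rather than an
error. An optional lognormal mode moment-matches the skewed factors and
stays positive, at the cost of slightly distorted correlations.

Equation-driven responses rebuild y on the standardised scale as the
reference equation's linear predictor over sample-standardised columns
plus Gaussian noise of variance Var(linpred)(1 − R²)/R², so the
population R² equals the published target. The stored response column
is an exact affine embedding of that y (survey mean/SD of the
response), inverted via the recorded truth sidecar when refitting:
recovery fits use the equation-scale response (centred, not rescaled),
because under the published correlations Var(linpred) ≈ 0.97 ≠ R², so
rescaling y to unit variance would change the recoverable coefficients
by ~7% and break comparability with the published values.

What the generator does *not* emulate: skewness and heavy tails of the
real marginals (in Gaussian mode), any beyond-pairwise dependence, and
spatial autocorrelation of the fan-shaped site layout. Passing
recovery benchmarks therefore show the method works under the survey's
second-order structure at the stated noise levels, not that the
original field inference is correct.

## Benchmarks and problem sizes

The recovery benchmark simulates under a generating equation, refits,
and scores per-term recovery, coefficient bias/RMSE, exact-support
rate, and spurious terms per replicate. Defaults: n = 5000 per
replicate, 100 replicates without CV or 20 with full CV — sizes at
which the suite completes comfortably while keeping Monte-Carlo error
small. A caveat discovered by the benchmark itself: at n = 5000 the
0.05 t-screen across ~63 null candidates admits on average ~1.5 tiny
false positives (|coef| ≈ 0.02, ER < 2%), so "exact support" is rare
(~30%) even though all true terms are recovered essentially always and
the three dominant terms match the truth in ~100% of replicates. That
is the expected behaviour of an FDR-uncontrolled per-term screen, and
the benchmark reports both notions separately.

## Known limitations

* The screen inherits EB-LASSO's lack of multiplicity control; treat
  small-ER significant terms with caution.
* CV of the posterior is meaningless for coefficients with mean ≈ 0
  (returned as NaN).
* The quantitative CV/MSE values of the reference survey (its Table of
  optima, the posterior CVs 0.10/0.45/0.39, the S(−II)/SSC equation
  coefficients) are functions of the undeposited raw data and are not
  reproducible; only their qualitative patterns (e.g. TP's coefficient
  having the lowest posterior CV) are checked on synthetic refits.
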