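# Methods

## Screening statistic

Let Y be the scalar response and x = (X₁, …, X_p)ᵀ the feature vector, each
feature scaled so that (1/n)Σᵢ X_ik = 0 and (1/n)Σᵢ X²_ik = 1 (the
*population*, 1/n, convention — not 1/(n−1) — so the mean-square condition
holds exactly). The marginal utility of feature k is the sample statistic

ω̂_k = (1/n) Σⱼ { (1/n) Σᵢ X_ik · 1(Y_i < Y_j) }² ,

a plug-in estimate of E{Ω_k(Y)²} with Ω(y) = E{x·P(Y < y | x)}. Under the
scaling convention Cauchy–Schwarz bounds each inner sum by 1, so
ω̂_k ∈ [0, 1]. Properties that the test suite verifies directly: invariance
under strictly monotone transforms of Y, equivariance under joint sample
permutation, and exact agreement with the naive O(n²p) double loop.

Conventions chosen where the formula is silent:

- **Ties in Y** use the strict inequality exactly as written: tied pairs
  contribute 0. A heavily tied response therefore attenuates ω̂ (a fully
  constant response gives ω̂ = 0 for every feature); callers with heavily
  discretised responses should be aware of this.
- The i = j term is included in the inner sum (it contributes 0).
- Constant features are rejected loudly at standardization rather than being
  assigned ω̂ = 0; the CLI offers `--drop-constant-features` to drop them
  instead.
- Rank ties are broken by ascending feature index, for determinism.
- The PCC screening baseline uses the absolute correlation: screening cares
  about strength of association, not sign.

## Iterative selection (ISIRS)

Target size d; K₁ = ⌊2d/3⌋ (deliberately < d so the first pass cannot
satisfy the stopping rule).

1. A₁ = top-K₁ features by ω̂ on (X, Y); M₁ = features with nonzero lasso
   coefficients when A₁ is fit to Y.
2. Residuals come from an **unpenalized OLS refit** on M₁ (not from the
   lasso fit), since the lasso's shrunken coefficients would leave signal in
   the residuals.
3. A₂ = top-(d − |M₁|) features by ω̂ of the residuals among {1..p}\M₁, so
   the next lasso candidate pool A₂ ∪ M₁ has size exactly d and the
   |M_s| = d stop is reachable. Residuals steer screening only; each lasso
   always fits the original response.
4. Stop when |M_s| = d, when |M_s| = |M_{s−1}| (sizes, not memberships —
   membership may in principle churn at constant size, which the rule
   ignores), or after 50 iterations as a safety cap.
5. If a lasso retains nothing, the event is recorded, screening falls back to
   the centered response, and a second consecutive empty pass stops the run.

The lasso objective is Σᵢ(Yᵢ − β₀ − Σ_k β_k X_ik)² + λΣ_k|β_k| with an
unpenalized intercept, solved by scikit-learn coordinate descent
(λ = 2n·α in scikit-learn's per-sample parametrisation). λ is chosen by
internal 5-fold cross-validation over a 100-point log-spaced path from the
smallest all-zero λ down to 10⁻³ of it, minimum-CV-error rule; a fixed λ can
be supplied instead. All CV splits are seeded explicitly.

The final model is OLS on the selected set with two-sided t-tests on
n − |set| − 1 degrees of freedom, significance at α = 0.01. A rank-deficient
design is an error naming the collinear features (QR with column pivoting);
an exactly interpolating fit returns coefficients with the tests flagged
undefined rather than fabricating infinite t-statistics.

### Baselines

- **STF** (simple top features): the top-d features by ω̂, no iteration.
- **Single-pass SIRS**: one ω̂ screen of size d, one lasso refit, padded back
  to d by ω̂ rank among the screened set. The screen size is d rather than K₁
  so the baseline can actually return d features; the iterative
  feature-residual variant of SIRS is deliberately out of scope, and this
  comparator is labelled single-pass for that reason.
- **PCC screen**: top-d by absolute Pearson correlation.

## Evaluation protocol

10-fold cross-validation with uniformly random, seeded fold assignment
(fold sizes differ by at most 1). Standardization parameters, screening
scores, the selected set, and the OLS fit are all computed on the nine
training folds only and applied to the held-out fold — a leakage-free
protocol, which may be stricter than analyses that standardize once
globally. Columns constant within a training fold (possible for sparse
binary mutation features) are dropped for that fold and logged. Out-of-fold
predictions are averaged across repeats *before* computing the Pearson
correlation and MSE (pooled, not per-fold-averaged). If selection returns an
empty set on a fold, that fold predicts the training mean.

d is tuned on the grid {2, 4, …, 50} with 10 repeats of 10-fold CV by
default, taking the d with the largest PCC; ties go to the smallest d
(parsimony).

Redundancy of a selected set is the mean over unordered feature pairs of
either |PCC| or the plug-in mutual information: each column discretized into
10 equal-width bins over its own range, MI in nats from the joint histogram.
Absolute PCC is used so anticorrelated redundancy counts as redundancy. The
plug-in MI estimator has a known positive bias of order (bins−1)²/(2n) for
independent columns; bin count is configurable. Sample skewness is
m₃/m₂^{3/2} with 1/n moments, for relating response asymmetry to prediction
error.

## Synthetic data

The generators emulate the *statistical* structure of an integrated
cancer-cell-line profile, not its biology:

- `generate_linear`: iid (or equicorrelated) Gaussian design, sparse linear
  signal Y = Σβ_k X_k + ε. Defaults n=200, p=1000, five active features with
  β=1, σ=1 — a regime where marginal screening succeeds.
- `generate_hidden_predictor`: the scenario iterative selection exists for.
  X₄ = √ρ(Z₁+Z₂+Z₃)/√3 + √(1−ρ)Z₄ and
  Y = β(X₁+X₂+X₃) − β√(3ρ)X₄ + ε, coefficients chosen so cov(X₄, Y) = 0
  *exactly* while X₄ is jointly essential. Study conditions β=2, ρ=0.5,
  n=200, p=500, d=10. (The construction is this package's own
  formalisation of the marginally-weak-but-jointly-important setting.)
- `generate_multiomics_like`: Gaussian expression columns, Bernoulli
  mutation columns (default prevalence 0.2), integer copy-number columns in
  {−2..2} peaked at 0. Binary and integer columns are standardized downstream
  like any other column, mirroring the uniform treatment of an integrated
  feature vector. No gene–gene correlation structure, batch effects, or
  dose-response curve simulation are attempted — passing tests demonstrate
  the statistical mechanism, not performance on real pharmacogenomic data,
  where correlated features and non-Gaussian noise will lower all methods'
  numbers.

All generators are pure functions of their parameters including the seed.

## Problem sizes and numerics

The test suite and the acceptance script run reduced-scale versions of the
method's natural setting (p up to 1000, n up to 300, 25–50 replicate seeds)
— sizes chosen so each statistical property is tested with adequate power on
a single CPU. Tolerances: 1e−12 for identities checked against brute-force
oracles, 1e−8 for OLS inference against the normal-equations closed form,
1e−6 for coordinate-descent lasso against soft-threshold closed forms
(iterative solver tolerance dominates). Columns are declared constant below
a 1e−12 mean-square deviation. Known limitations: the stopping rule's
size-only comparison (above), attenuation of ω̂ under heavy response ties,
and the plug-in MI bias for small n.
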