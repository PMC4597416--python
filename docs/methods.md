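# Methods

## Model

Ordinal labels `y_i ∈ {1..k}` arise from a latent continuous response
`l_i = w_iᵀθ + e_i` partitioned by non-decreasing thresholds
`γ = (γ_1 = −∞, γ_2, …, γ_k, γ_{k+1} = +∞)`: `y_i = j` iff
`γ_j ≤ l_i < γ_{j+1}`. The error is logistic, giving the cumulative-logit
(proportional-odds) link `P(y ≤ j | w) = F(γ_{j+1} − wᵀθ)` with
`F(x) = 1/(1+e^{−x})`. For posterior simulation the logistic error is
approximated by a Student-t with unknown degrees of freedom ν, represented
as a scale mixture: `l_i | Λ_i ~ N(w_iᵀθ, 1/Λ_i)`, `Λ_i ~ Gamma(ν/2, ν/2)`
(rate parameterization throughout). ν is estimated with the other unknowns,
so the error family spans heavy-tailed t through near-Gaussian shapes.

Sparsity is induced by independent Generalized Double Pareto priors
`θ_j ~ GDP(ζ = δ/ρ, ρ)`, equivalently `θ_j | τ_j ~ N(0, τ_j)`,
`τ_j ~ Exp(λ_j²/2)`, `λ_j ~ Gamma(ρ, δ)`. Generalized-Pareto hyperpriors
`π(ρ) = c/(1+cρ)²` and `π(δ) = c′/(1+c′δ)²` become uniform after the
transformations `u₁ = 1/(1+cρ)`, `u₂ = 1/(1+c′δ)`. Thresholds carry
independent uniform priors.

### Threshold identification

The latent predictor `wᵀθ` has no intercept, so the latent location is
identified and **all k−1 interior thresholds are sampled**. This is the
same model as the textbook construction "intercept plus first threshold
pinned at zero", written in the parameterization that keeps the coefficient
block free of location bookkeeping (an intercept would otherwise need to be
exempted from the shrinkage prior). Pinning a threshold *without* an
intercept would force the boundary between the first two classes to sit at
latent zero — impossible to satisfy for centred covariates — and in
experiments on the synthetic family below it costs roughly ten accuracy
points and collapses the second class into the first. The package therefore
samples γ_2 along with the rest.

## Gibbs sampler

All conditionals are standard or griddy:

| block | conditional |
| --- | --- |
| latents | `l_i ~ N(w_iᵀθ, 1/Λ_i)` truncated to `[γ_{y_i}, γ_{y_i+1})` |
| coefficients | `θ ~ MVN([WᵀΛW + T*]⁻¹ WᵀΛl, [WᵀΛW + T*]⁻¹)`, `T* = diag(1/τ_j)` |
| local scales | `τ_j⁻¹ ~ Inverse-Gaussian(λ_j/\|θ_j\|, λ_j²)` |
| mixing rates | `λ_j ~ Gamma(ρ+1, \|θ_j\| + δ)` |
| t precisions | `Λ_i ~ Gamma((ν+1)/2, ((l_i − w_iᵀθ)² + ν)/2)` |
| ν, u₁→ρ, u₂→δ | griddy Gibbs: evaluate the log conditional on a grid, normalize by max-subtraction, draw |
| thresholds | `γ_s ~ Uniform(max[max{l_i : y_i = s−1}, γ_{s−1}], min[min{l_i : y_i = s}, γ_{s+1}])`, s = 2..k |

### Update order (this matters)

The λ conditional `Gamma(ρ+1, |θ|+δ)` and the u₁/u₂ conditionals are
*partially collapsed*: they are derived with τ (and λ) integrated out of
the θ-prior, not from the full joint. A partially collapsed Gibbs sampler
is only valid when every marginalized draw precedes the redraw of the
quantities it marginalized, so a sweep scans

```
latents → θ → ν → u₁→ρ → u₂→δ → λ → τ⁻¹ → Λ → thresholds.
```

Steps ρ, δ form a Gibbs scan of the collapsed conditional p(ρ, δ | θ);
λ then τ⁻¹ reconstitute an exact joint draw from p(λ, τ | θ, ρ, δ). Placing
τ⁻¹ before λ, or the hyperparameters after them, breaks the λ–τ coupling.
The stationarity audit (below) is what caught this during development.

### Numerical choices

* **θ block**: Cholesky factorization of the precision `WᵀΛW + T*` (never an
  explicit inverse), with escalating relative diagonal jitter
  (0, 1e−10, 1e−8, 1e−6) before failing with diagnostics. p is moderate
  after screening (≤ ~400), so a dense p×p factorization per sweep is the
  right regime.
* **Truncated normals** via `scipy.stats.truncnorm` (tail-robust inverse
  CDF); draws are clipped into the half-open category interval so the
  latent/threshold invariant holds exactly in floating point.
* **Inverse-Gaussian** via `scipy.stats.invgauss` with the mean/shape →
  (mu, scale) mapping; `|θ_j|` floored at 1e−10 in the location so θ_j = 0
  cannot overflow.
* **Griddy weights** are computed wholly in log space and normalized by
  max-subtraction; a vectorized grid evaluation is used inside the sweep
  and is pinned to the scalar definitions by unit tests.
* **Thresholds**: drawn sequentially; a threshold whose conditional is
  improper (an empty edge category against an infinite sentinel) keeps its
  current value. The diagnostics replace the improper uniform prior by
  Uniform(−B, B) where a proper joint is required.
* **Degenerate inputs**: empty truncation intervals and non-monotone
  thresholds raise `InvariantViolation` with the sweep index attached.

### Defaults and tunables

| parameter | default | units / role |
| --- | --- | --- |
| c, c′ | 1 | scales of the generalized-Pareto hyperpriors on ρ, δ |
| ν grid | {1..30} ∪ {40, 50, 75, 100} | candidate t degrees of freedom |
| u grid | 99 points 0.01..0.99 | shared grid for u₁, u₂ |
| n_iter / burn_in / thin | 60 000 / 20 000 / 1 | reference run length |
| initialization | θ=0, τ=λ=Λ=1, ν=7, ρ=δ=1; γ at empirical logit quantiles; latents one truncated draw | |

c and c′ are not identified by any stated analysis; unit scale makes the
implied ρ, δ priors peak near the conventional default ρ = δ = 1. The ν
grid covers the heavy-tail regime densely and thins out where the t is
already near-Gaussian. ν = 7 at initialization is the usual t
approximation to the logistic. All grids and counts are configurable
through `SamplerConfig`.

## Screening and evaluation

Each gene is tested alone in a one-covariate proportional-odds model
(statsmodels `OrderedModel`, logit link, BFGS); the two-sided **Wald**
p-value for the slope is the default (cheapest at genome scale; a
likelihood-ratio test is available behind `use_lr=True`, and is the better
choice under near-separation where the Wald SE diverges). Non-convergent or
degenerate fits score p = 1 so a screen never aborts. BH adjustment uses
the step-up rule (statsmodels `multipletests`), checked exactly against a
brute-force implementation of the definition. Expression values are
z-scored per gene before fitting by default (`standardize=True`) — the
input scale of microarray matrices is arbitrary; this is a package choice,
flag-controlled.

Evaluation mirrors a balanced-resampling design: stratified 50/50 splits
(per-class train counts `round(frac·size)`, clipped so both halves keep
every class), a full fit on the training half, selection of the top-m genes
by |posterior mean θ|, a refit restricted to those genes, and plug-in
classification of the test half with posterior means (argmax of category
probabilities, ties to the lower category — the Bayes rule under 0–1 loss).
Selecting markers on the training fit only keeps the test half untouched.
Full posterior-predictive averaging is available (`predictive_average`) and
performed indistinguishably from plug-in in our experiments. Per-run seeds
are `seed + run index` so any single run can be replayed.

## Synthetic data

The generator emits exactly the structure the model assumes: `W` iid
standard normal; `n_signal` coefficients of magnitude `effect` with
**alternating signs** at random positions (a marginal mean shift cannot
recover them); latents `Wθ + e` with logistic or Student-t noise;
thresholds at empirical `j/k` latent quantiles, so classes are
near-balanced by construction, matching the balanced evaluation design.
The default study conditions used by the acceptance checks are n = 200,
p = 50, k = 4, five planted effects of magnitude 2, logistic noise.

What the generator does *not* emulate: probe-level noise, normalization
artifacts, correlated gene blocks, class imbalance. Passing tests on this
family show the sampler recovers the model it was built for; they do not
certify performance on real microarray data.

`bayes_accuracy` evaluates the true-parameter classifier and is the ceiling
against which fitted accuracy is compared (≈ 0.70 under the default
conditions; the fitted pipeline reaches ≈ 0.60–0.67 with top-10 refits on
100 training samples).

## Validation design

* **Moment oracles**: every conditional sampler is checked against closed
  forms (truncated-normal mean, MVN mean/covariance, inverse-Gaussian mean
  *and variance*, gamma means, uniform threshold mean) at 10⁵ draws within
  3 Monte-Carlo standard errors; griddy log-weights against direct
  product-form evaluation at 1e−10.
* **Conjugate limit**: with latents, τ, Λ ≡ 1 and thresholds held fixed the
  θ conditional collapses to a closed-form Gaussian (ridge) posterior; the
  chain must reproduce its mean within 3 MC SE.
* **Stationarity audit** ("getting it right"): alternating one Gibbs sweep
  with a regeneration of the data from the likelihood leaves the prior
  invariant, so prior-only and successive-conditional moments of every
  block must agree. The audit runs many short independent chains, each
  started from an exact prior draw — within-chain autocorrelation times
  exceed 2 500 sweeps on the audit instance, so independent chain means are
  the only honest source of standard errors. The audit instance restricts
  the u-grid so the implied GDP shape stays in [4, 9]; with heavier tails
  the comparison statistics have no usable CLT. Audit power was verified
  against deliberately seeded conditional bugs.
* **End-to-end**: planted-support recovery by ranking, screening
  calibration on null genes (KS against uniform p-values), and
  resampling accuracy bounded by the oracle ceiling.

Problem sizes in the acceptance checks (20 replicates × 2 000 sweeps for
recovery; 10 resampling runs × 1 500 sweeps; 30 × 350 audit sweeps) were
chosen so each check resolves its target within Monte-Carlo error at
desk scale.

## Known limitations

* The t-approximation has unit scale while the logistic error has standard
  deviation π/√3 ≈ 1.81; fitted θ and γ are correspondingly shrunk by a
  common factor relative to a logistic-scale fit. Classification is
  invariant to that common rescaling, but posterior means of θ are not on
  the generating scale.
* Threshold updates move between adjacent latent order statistics and mix
  slowly for large n; posterior summaries of γ need the long default run
  on real-data scales.
* Single chain only; no convergence pooling across parallel chains.
* The griddy steps confine ν, ρ, δ to their grids; posterior mass outside
  the grid range is truncated silently.
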