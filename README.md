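# sbgg — sparse Bayesian ordinal classification with a Generalized Double Pareto prior

`sbgg` implements a hierarchical Bayesian cumulative-logit model for
multi-category **ordinal** outcomes — progressive disease stages, tumour
grades — measured on high-dimensional expression profiles ("large p, small
n"). It is aimed at statisticians and computational biologists who need a
classifier that simultaneously **selects marker genes** and **respects the
ordering** of the response.

## The model

Each sample `i` carries an ordinal label `y_i ∈ {1, …, k}` and an expression
vector `w_i ∈ R^p`. A continuous latent response

```
l_i = w_iᵀ θ + e_i ,   e_i ~ Logistic(0, 1)
```

determines the label through ordered thresholds `γ`:
`y_i = j  ⇔  γ_j ≤ l_i < γ_{j+1}`, with `γ_1 = −∞`, `γ_{k+1} = +∞`, so that
`P(y_i ≤ j) = 1 / (1 + e^{−(γ_{j+1} − w_iᵀθ)})` (proportional odds). For
Gibbs sampling the logistic error is approximated by a Student-t with
unknown degrees of freedom ν, written as a gamma scale mixture of normals
(`Λ_i ~ Gamma(ν/2, ν/2)`).

Sparsity comes from independent **Generalized Double Pareto** (GDP) priors
on the coefficients,

```
f(θ | ζ, ρ) = 1/(2ζ) · (1 + |θ| / (ρζ))^−(1+ρ) ,   ζ = δ/ρ,
```

a density with a spike at zero and Student-t-like tails: small effects are
shrunk hard, large effects escape the over-shrinkage that lighter-tailed
(double-exponential) priors inflict. The GDP admits the hierarchy
`θ_j | τ_j ~ N(0, τ_j)`, `τ_j ~ Exp(λ_j²/2)`, `λ_j ~ Gamma(ρ, δ)`, which
makes every full conditional tractable; the hyperparameters ρ, δ and the
degrees of freedom ν are sampled by embedded griddy Gibbs. Genes are ranked
by `|posterior mean θ_j|`.

Around the sampler the package provides the standard workflow: per-gene
proportional-odds screening with Benjamini–Hochberg FDR control, a
synthetic-data generator with planted sparse ground truth, and a balanced
train/test resampling harness with top-m marker refits.

## Worked example

Simulate 200 samples × 50 genes with 4 ordinal classes and 5 planted
markers of effect ±2, screen, fit, and evaluate:

```bash
sbgg simulate --n 200 --p 50 --k 4 --n-signal 5 --effect 2.0 --seed 7 --out-prefix demo
# wrote demo.matrix.tsv (200x50, k=4)

sbgg screen --matrix demo.matrix.tsv --labels demo.labels.tsv --fdr 0.05 --out demo.ranking.tsv
# screened 50 features: 6 selected at FDR 0.05 (0 probes dropped on ingest)

sbgg fit --matrix demo.matrix.tsv --labels demo.labels.tsv \
     --iterations 2000 --burn-in 500 --seed 7 --out-summary demo.summary.json
# top genes by |posterior mean|: G37(+1.553), G38(-1.499), G45(+1.480), G29(-1.475), G21(+1.463)

sbgg evaluate --matrix demo.matrix.tsv --labels demo.labels.tsv \
     --top-m 10 --runs 5 --iterations 1500 --burn-in 500 --seed 3 --out demo.report.json
# mean overall accuracy 0.664 (sd 0.027) over 5 runs, top-10 genes
```

The five genes the sampler ranks first are exactly the five planted markers
(`G21, G29, G37, G38, G45`), with signs recovered; the posterior means
(≈ ±1.5) sit below the generating ±2 because the GDP prior shrinks and the
fitted t-error scale differs from the logistic one. The evaluation report
gives mean held-out accuracy 66% over balanced resampling runs against a 25%
chance level — close to the ≈ 70% ceiling of the true-parameter classifier
on this family (`sbgg.synthetic_data.bayes_accuracy`).

The same functionality is available as a library:

```python
from sbgg import generate, run_chain, rank_genes, SamplerConfig

data, truth = generate(n=200, p=50, k=4, n_signal=5, effect=2.0, seed=7)
summary = run_chain(data, SamplerConfig(n_iter=2000, burn_in=500, seed=7))
rank_genes(summary, 5)          # indices of the top 5 genes
```

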