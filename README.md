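# phyloprev

Bayesian binomial phylogenetic regression of species-level tumour
prevalence on log10 body mass and log10 maximum longevity.

Per-species case counts are modelled directly as binomial draws with a
logit link; a species-level random effect is constrained by a
phylogenetic correlation matrix derived from an ultrametric tree under
either an Ornstein–Uhlenbeck process (decay rate `alpha`) or Pagel's
lambda branch scaling. The package covers the full workflow:

- **`phyloprev.tree`** — Newick reading/validation, shared-path-time
  matrices, OU / lambda / BM / identity correlation structures,
  Cholesky jitter.
- **`phyloprev.model`** — dataset container, likelihood/priors, and an
  adaptive Metropolis-within-Gibbs sampler with non-centred species
  effects; the structure parameter can be estimated jointly or fixed.
- **`phyloprev.evaluation`** — split-chain R-hat, bulk/tail effective
  sample size, lag autocorrelation, WAIC, PSIS-LOO with Pareto-k
  diagnostics, OU-vs-lambda model comparison, and randomized-quantile
  posterior predictive checks.
- **`phyloprev.effects`** — odds-ratio summaries with credible
  intervals, marginal prevalence curves with 50/75/95% bands, Jeffreys
  intervals for raw prevalences, and exact expected-CI-width curves as
  a function of necropsy count.
- **`phyloprev.resampling`** — the necropsy-shuffling sensitivity
  study: permute sample sizes across species (preserving observed
  prevalences), refit, and summarize sign/significance stability.
- **`phyloprev.simulate`** — Yule trees, tree-correlated covariates and
  species effects, realistic necropsy-count distributions, and a
  parameter-recovery harness.
- **`phyloprev.cli`** — a `phyloprev` command with `simulate`, `fit`,
  `compare`, `resample`, `ci-width` and `run` (config-driven full
  analysis) subcommands.

## Data formats

Dataset CSV columns:
`species,n_necropsies,k_neoplasia,k_malignant,k_lethal,body_mass_kg,max_longevity_months`
(`k_*` columns optional per dataset). Trees are Newick with branch
lengths on all edges; tip labels are matched to the species column
after space/underscore normalization. Trees are depth-normalized to 1
before fitting so the OU decay rate is comparable across datasets.

## CLI examples

```sh
# write a synthetic dataset + tree + generating truth
phyloprev simulate --n-species 80 --beta-mass 0.5 --seed 1 --out-dir sim/

# fit one model
phyloprev fit --dataset sim/dataset.csv --tree sim/tree.nwk \
    --response neoplasia --predictors log10_mass --family OU --out-dir fit/

# full analysis: all predictor sets, OU vs lambda comparison
phyloprev run --dataset sim/dataset.csv --tree sim/tree.nwk --out-dir out/

# necropsy-shuffling sensitivity study (50 replicates)
phyloprev resample --dataset sim/dataset.csv --tree sim/tree.nwk \
    --replicates 50 --seed 1 --out resampling.json

# expected Jeffreys-interval width vs sample size
phyloprev ci-width --p-true 0.1 --n-grid 10,25,50,100,400
```

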