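# reefsharks

Hierarchical Bayesian estimation of reef-shark density baselines from
towed-diver surveys.

Reef sharks are scarce near human population centers and abundant on remote
Pacific reefs, but raw comparisons of survey densities confound human
pressure with oceanography: remote reefs also tend to be warmer or more
productive. This package implements the full analysis chain that separates
those influences and asks the counterfactual question conservation planners
actually need answered — *what shark density would this reef support if no
people lived within reach of it?* It is written for quantitative ecologists
working with large-area towed-diver (or comparable belt) survey counts and
island-level environmental covariates.

## The model

Counts are nested: tows within islands. For tow *t* at island *i*,

```
Y_t        ~ NegBin(mean = λ_t, overdispersion = k)      λ_t = μ_i · area_t
μ_i        ~ Normal(E_i, σ²/n_i) truncated to (0, ∞)
E_i        = α + Σ_j w_j β_j x_ij
```

* `Y_t` — sharks counted on the tow; the negative binomial (variance
  `λ + λ²/k`) absorbs the strong overdispersion of shark counts.
* `μ_i` — island mean density (sharks/ha), positive by truncation; its
  hypervariance `σ²` is weighted by the island's number of tows `n_i`.
* `x_ij` — standardized island covariates (log humans within 200 km,
  oceanic primary productivity, minimum monthly SST or log reef area, reef
  structural complexity). Human metrics are logged with a +1 offset so
  uninhabited islands (0 humans) are representable.
* `w_j` — Bernoulli(0.5) latent inclusion indicators; their joint MCMC
  frequencies give posterior model weights, their marginal frequencies give
  per-covariate inclusion probabilities (Kuo–Mallick variable selection).
* Priors: Normal(0, 100) on `α`, `β_j`; Gamma(0.01, 0.01) on `1/σ²` and `k`.

Inference is an adaptive Metropolis-within-Gibbs sampler (numba-compiled,
multiple chains, Gelman–Rubin convergence diagnostics). Model checking uses
a posterior-predictive Bayesian p-value with sum-of-squared-residual
discrepancy. The headline product is the **baseline**: at each retained
draw the human covariates are reset to the standardized score of *zero raw
humans* and the expected density (mean of the truncated normal) is
recomputed, yielding a credible interval for the human-free density of each
island and hence a **depletion ratio** (observed ÷ baseline, in percent).

Because the original survey data are not public, the package includes a
first-class synthetic-data generator that reproduces the survey design (46
islands in 5 regions, ~35 forereef tows per island, ~2.2 km tows, exact-zero
human populations, densities spanning ~0.1–7 sharks/ha) so every stage is
testable against known truth.

## Worked example

`examples/03_variable_selection.py` simulates a 46-island campaign with a
single true effect (humans within 200 km, standardized β = −1.2) plus two
null covariates, fits the selection model, and prints:

```
Model                                              Posterior weight
humans_200km                                       0.923*
humans_200km + min_sst                             0.047
humans_200km + productivity                        0.030
humans_200km + productivity + min_sst              0.000

inclusion probabilities: {'humans_200km': 1.0, 'productivity': 0.03, 'min_sst': 0.047}
Bayesian p-value: 0.635  (~0.5 indicates good fit)
```

The human-only model carries 92% of the posterior weight (asterisk marks
the best model), the true covariate is included in every retained iteration
while the nulls hover near their prior-discounted floor, and the
posterior-predictive p-value near 0.5 confirms the negative-binomial
hierarchy reproduces data like those observed. The other examples cover
simulation (`01`), plain fitting and parameter recovery (`02`),
baselines/depletion (`04` — uninhabited islands come out near 100% of
baseline, heavily populated ones near 1–12%), and effect curves with
doubling increments under the log link (`05`).

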