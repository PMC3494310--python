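# Methods

## Data model and exclusions

A tow record carries the surveyed area (GPS tow length × 10-m belt width;
1 km of tow = 1 ha), a 1–6 visual complexity score, and per-species counts
of sharks longer than 50 cm. Species codes absent from a record are
observed zeros, not missing values: towed surveys enumerate every large
fish in the belt. The analysis pool keeps forereef tows from the
standardized-observer years (2004–2010 by default) that are at least 1 km
long; all three thresholds are arguments of `io.filter_tows` so sensitivity
analyses can move them. The modeled response is a species-group total per
tow: either the pooled five reef-associated species (gray reef, whitetip
reef, blacktip reef, Galapagos, tawny nurse) or a single species. Tiger and
hammerhead sharks, which range far off reefs, are structurally excluded
from group membership.

When a tow file carries a stored `area_ha` column it is cross-checked
against length × width at 1% relative tolerance and the recomputed value is
used, so a stale derived column cannot silently drive densities.

## Covariates

Island-level predictors: humans within 200 km (the day-trip range of a
fishing vessel), humans per km² of reef, distance to the nearest population
center, oceanic primary productivity (mg C m⁻² day⁻¹), minimum monthly SST
(°C), reef area (km²), and mean tow complexity. Human metrics are
log-transformed with a +1 offset — several islands have exactly zero
inhabitants and log(0+1)=0 keeps them on the scale — and reef area and
distance use a plain log (always positive). Transforms precede
standardization (each column centered and scaled to unit SD over islands);
the per-column transform metadata is retained so any raw value, including
the counterfactual raw zero, can be mapped into standardized space and
back exactly. Per-island complexity is the arithmetic mean of tow scores —
the ordinary summary when an ordinal score is used as a continuous
covariate.

Collinearity handling: pairwise Pearson correlations with a configurable
|r| > 0.7 flag, variance inflation factors via the R² definition
(`1/(1−R²_j)`, infinite under exact collinearity), and a two-set candidate
enumeration in which minimum SST and log reef area never co-occur — the two
are strongly negatively confounded in Pacific data (large, cold-water
Hawaiian islands), so each anchors its own model set (A: temperature,
B: reef area).

## Hierarchical model

See the README for the generative equations. Numerical and structural
choices that were genuinely open:

* **NB parameterization.** Mean λ, variance λ + λ²/k (size-k form); at
  k = 1 it reduces to a geometric distribution and as k → ∞ to Poisson,
  which the tests exploit as closed-form oracles.
* **Hypervariance prior.** Gamma(0.01, 0.01) on the precision 1/σ², the
  conventional BUGS idiom for a vague variance prior; a gamma on σ²
  directly is available via `PriorSpec.hypervar_on_precision=False`. The
  prior on k mirrors it (Gamma(0.01, 0.01)), also configurable.
* **Variance weighting.** The island-level variance is σ²/n_i with n_i the
  island's tow count, so islands surveyed harder sit closer to their
  regression mean; `weight_variance_by_n=False` turns the weighting off.
* **Link.** Identity by default: the truncation of the hyperdistribution
  to positive densities is what makes an identity link on a positive
  quantity coherent. A log link (hyperdistribution located at exp(E_i)) is
  implemented with all other machinery shared; it is the natural choice
  when one wants constant doubling increments or power-law covariate
  responses, and `examples/05` uses it.
* **Sampler.** Adaptive random-walk Metropolis-within-Gibbs: scalar updates
  for α, each β_j, each μ_i, plus log-scale walks (with Jacobian) for σ²
  and k; indicator flips are Bernoulli–Metropolis moves, and a coefficient
  whose indicator is off is refreshed from its prior (its exact
  conditional). Step sizes adapt toward 0.44 acceptance during burn-in
  only and are frozen afterward, preserving detailed balance for the
  retained draws. Likelihood deltas are computed incrementally (island
  updates touch ~35 tows; only the k update scans all tows), and the
  kernel is numba-compiled, which is what makes 20,000-iteration fits on a
  46 × 35 design take seconds.
* **Iteration counts.** Library defaults are 20,000 iterations, 4,000
  burn-in, 2 chains — at these data sizes the chains mix within a few
  hundred iterations (R̂ ≈ 1.00 throughout the examples) and posterior
  summaries are stable at three significant figures. The published-scale
  protocol (500,000/100,000) is a parameter choice away.
* **Degenerate inputs.** All-zero counts on a degenerate design warn
  rather than fail; zero within-chain variance makes R̂ NaN with a
  warning; exact collinearity reports infinite VIF; a constant covariate
  column is a hard error (it cannot be standardized).

## Selection, fit checking, prediction

Posterior model weights are relative frequencies of *joint* indicator
configurations (not products of marginals): that is the direct reading of
an indicator-history chain, and it makes weights sum to one by
construction. Ties for the best model break toward fewer covariates, then
lexicographic order. The three human-pressure metrics are compared as
single-covariate selection fits ranked by |Bayesian p − 0.5|, mirroring
how one chooses among near-equivalent proxies. After selection the best
subset is refitted without indicators to get clean coefficient intervals.

The Bayesian p-value simulates a replicate count for every tow at every
retained draw (reusing observed tow areas) with discrepancy
Σ_t (y_t − λ_t)²; p is the fraction of draws where the replicate's
discrepancy exceeds the data's. It is deterministic given a seed and
batched so the full draw set is used without materializing a draws × tows
matrix.

Baseline prediction resets the human covariates to the standardized score
of **raw zero** (through the stored log(x+1) chain) — a standardized zero
would mean the sample-average human population, which is not "no humans".
The predicted density at a draw is the *mean* of the positive-truncated
normal, `E + s·φ(E/s)/Φ(E/s)`, not the location E: under a wide
hyperdistribution the truncation mass is substantial and the location can
even go negative while the implied mean density stays positive. The same
convention underlies effect curves (other covariates at their median
standardized values, predictive variance at the median per-island tow
count) and the intercept-only interpretation. Depletion ratios divide the
observed ratio-of-totals density by the baseline bounds and are returned
sorted. Doubling increments are `ln 2 · sd_x / β̂` under the log link
(exact and constant; in the transformed covariate's units for logged
covariates); under the identity link only a local increment at a stated
reference exists and is reported as such.

## Synthetic data: what it does and does not emulate

The generator draws covariates uniformly within per-region ranges matching
the published regional summary, with log-uniform human populations and a
per-region point mass at exactly zero (exercising the log(x+1) path), and
optionally induces the area–temperature correlation (target r = −0.66)
through a Gaussian copula for collinearity tests. Counts are drawn from the
model's own generative process with default truth α = 2.0,
β = (−1.2, +0.8, +0.5) for (log humans, productivity, min SST), σ² = 0.5,
k = 1.5, which yields island densities spanning roughly 0.1–7 sharks/ha —
the observed spread from urbanized to pristine reefs. Tow lengths are
normal around 2.2 km floored at 1 km.

Being model-generated, the synthetic data are exchangeable given covariates:
they contain no spatial autocorrelation, no observer effects, no
depth/time-of-day sampling bias, and no covariate measurement error. The
passing recovery/selection/calibration tests therefore demonstrate that the
*inference machinery* is correct and well-calibrated under the model's
assumptions, not that the model is correct for any particular reef system.
A deterministic fixture (`make_table1_fixture`) separately reproduces the
published effort and species totals exactly (46 reefs, 1607 surveys, 4620
sharks at 71/19/6/3/1% by species) for summary-arithmetic checks; its
covariate values are synthetic placeholders within the printed ranges.

## Known limitations

* The real survey data are not distributed; all empirical quantities in
  the test suite and acceptance script are computed on synthetic data, and
  the published baseline intervals for specific archipelagos are not
  reproducible here.
* Kuo–Mallick indicator flips rely on prior draws proposing plausible
  coefficients; with very diffuse coefficient priors and weak effects the
  indicator chain can mix slowly. At the effect sizes and survey scale
  modeled here mixing is fast (inclusion probabilities stable across
  chains), but much weaker signals would warrant longer chains.
* The quadrature oracle used to validate the sampler covers the 3-island,
  fixed-(σ², k) case; full-model correctness is established by
  simulation-based calibration (coverage) rather than exhaustive
  integration.
* Effect curves do not extrapolate beyond observed covariate ranges, and
  the package deliberately offers no carrying-capacity or management-target
  estimation.
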