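"""Single-covariate effect curves and doubling increments.

An effect curve sweeps one covariate over its observed raw range while the
others sit at representative (median) values, showing the expected density
response with credible bounds.  Under the log link the response to an
unlogged covariate is exponential, so a constant doubling increment exists:
the temperature or productivity increase over which expected density
doubles.
"""

from reefsharks import io, model, simulate
from reefsharks.baseline import doubling_increment, effect_curve
from reefsharks.covariates import transform_covariates
from reefsharks.records import species_group

islands = simulate.generate_islands(seed=6)
truth = simulate.TruthRecord(
    alpha=0.3,
    beta={"humans_200km": -0.6, "productivity": 0.5, "min_sst": 0.4},
    sigma2=0.2, k=1.5, link="log", seed=6,
)
records, truth = simulate.generate_tows(islands, truth, tows_per_island=35)
grouped = io.group_counts(records, species_group("all_reef_sharks"))
design = transform_covariates(islands, columns=list(truth.beta))
data = model.ModelData.from_frames(grouped, design)

fit = model.run_mcmc(
    data, model.ModelSpec(covariates=tuple(data.columns), link="log"),
    n_iter=20_000, n_burn=4_000, seed=6,
)

curve = effect_curve(fit, design, "min_sst", n_grid=8)
print("expected density vs minimum SST (others at medians):")
print(curve.to_frame().round(3).to_string(index=False))

for cov in ("min_sst", "productivity"):
    inc = doubling_increment(fit, design, cov)
    unit = "deg C" if cov == "min_sst" else "mg C m^-2 day^-1"
    print(f"density doubles per {inc:.1f} {unit} increase in {cov}")
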