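import numpy as np
import pytest

from reefsharks import io, model, simulate
from reefsharks.covariates import transform_covariates
from reefsharks.records import IslandCovariates, TowRecord, species_group


def make_islands(n: int = 6, seed: int = 0) -> list[IslandCovariates]:
    """Small hand-rolled island set spanning inhabited and empty islands."""
    rng = np.random.default_rng(seed)
    islands = []
    humans = [0.0, 0.0, 50.0, 5_000.0, 120_000.0, 900_000.0]
    for i in range(n):
        islands.append(
            IslandCovariates(
                island_id=f"I{i:02d}",
                region="PRIA" if humans[i % 6] == 0 else "MHI",
                humans_200km=humans[i % 6],
                humans_per_km2_reef=humans[i % 6] / 100.0,
                dist_pop_center_km=float(rng.uniform(10, 1500)),
                productivity=float(rng.uniform(130, 440)),
                min_sst=float(rng.uniform(20, 28)),
                reef_area_km2=float(rng.uniform(10, 2000)),
                mean_complexity=float(rng.uniform(1.5, 5.5)),
            )
        )
    return islands


def make_tow(tow_id="T1", island_id="I00", year=2006, habitat="forereef",
             length_km=2.2, complexity=3, counts=None, width_m=10.0):
    return TowRecord(
        tow_id=tow_id, island_id=island_id, year=year, habitat=habitat,
        length_km=length_km, complexity=complexity,
        counts=counts or {}, width_m=width_m,
    )


@pytest.fixture(scope="session")
def small_islands():
    return make_islands()


@pytest.fixture(scope="session")
def sim_fit():
    """A single moderate simulated data set with its fitted posterior,
    shared across tests that only need *a* valid fit."""
    islands = simulate.generate_islands(seed=11)
    truth = simulate.default_truth(seed=11)
    records, truth = simulate.generate_tows(islands, truth, tows_per_island=20,
                                            seed=11)
    grouped = io.group_counts(records, species_group("all_reef_sharks"))
    design = transform_covariates(
        islands, columns=["humans_200km", "productivity", "min_sst"]
    )
    data = model.ModelData.from_frames(grouped, design)
    spec = model.ModelSpec(covariates=tuple(data.columns), selection=False)
    fit = model.run_mcmc(data, spec, n_iter=6000, n_burn=1500, seed=11)
    return {
        "islands": islands, "truth": truth, "records": records,
        "grouped": grouped, "design": design, "data": data, "fit": fit,
    }
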