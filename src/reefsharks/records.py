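"""Domain records for towed-diver shark surveys.

A towed-diver survey is a belt survey in which a diver towed behind a small
boat records every fish longer than 50 cm inside a 10-m-wide swath; a 50-min
tow covers roughly 2.2 km, i.e. >1 ha of forereef.  The analysis operates on
one :class:`TowRecord` per survey plus one :class:`IslandCovariates` row per
island, and models species groups defined by :class:`SpeciesGroup`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "HABITATS",
    "REGIONS",
    "REEF_SHARK_CODES",
    "NON_REEF_CODES",
    "SPECIES_NAMES",
    "TowRecord",
    "IslandCovariates",
    "SpeciesGroup",
    "species_group",
    "ValidationError",
    "SchemaError",
    "ConfigurationError",
]

HABITATS = ("forereef", "backreef", "lagoon")
REGIONS = ("MHI", "NWHI", "Mariana", "AmSamoa", "PRIA")

# The five reef-associated species pooled into the "all reef sharks" group.
REEF_SHARK_CODES = ("GR", "WT", "BT", "GA", "NU")
# Wide-ranging species recorded on tows but never modeled as reef sharks.
NON_REEF_CODES = ("TI", "HH")

SPECIES_NAMES = {
    "GR": "gray reef shark (Carcharhinus amblyrhynchos)",
    "WT": "whitetip reef shark (Triaenodon obesus)",
    "BT": "blacktip reef shark (Carcharhinus melanopterus)",
    "GA": "Galapagos shark (Carcharhinus galapagensis)",
    "NU": "tawny nurse shark (Nebrius ferrugineus)",
    "TI": "tiger shark (Galeocerdo cuvier)",
    "HH": "hammerhead shark (Sphyrna spp.)",
}


class ValidationError(ValueError):
    """A record violates a structural invariant."""


class SchemaError(ValueError):
    """An on-disk table is missing or mistypes a required column."""


class ConfigurationError(ValueError):
    """An analysis configuration references something that does not exist."""


@dataclass
class TowRecord:
    """One towed-diver survey.

    ``counts`` maps species code to the non-negative number of individuals
    recorded on the tow.  A code absent from the map means none were seen
    (tow surveys record all individuals >50 cm, so absence is an observed
    zero, not missing data).
    """

    tow_id: str
    island_id: str
    year: int
    habitat: str
    length_km: float
    complexity: int
    counts: dict[str, int] = field(default_factory=dict)
    width_m: float = 10.0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def area_ha(self) -> float:
        """Swath area in hectares: length (km) x width (m) / 10."""
        return self.length_km * self.width_m / 10.0

    def validate(self) -> None:
        if self.habitat not in HABITATS:
            raise ValidationError(
                f"tow {self.tow_id}: habitat {self.habitat!r} not one of {HABITATS}"
            )
        if not (self.length_km > 0 and math.isfinite(self.length_km)):
            raise ValidationError(f"tow {self.tow_id}: length_km must be > 0")
        if not (self.width_m > 0 and math.isfinite(self.width_m)):
            raise ValidationError(f"tow {self.tow_id}: width_m must be > 0")
        if self.complexity not in range(1, 7):
            raise ValidationError(
                f"tow {self.tow_id}: complexity {self.complexity} not in 1..6"
            )
        for code, n in self.counts.items():
            if int(n) != n or n < 0:
                raise ValidationError(
                    f"tow {self.tow_id}: count for {code} must be a non-negative "
                    f"integer, got {n!r}"
                )
            self.counts[code] = int(n)


@dataclass
class IslandCovariates:
    """Island-level predictors of mean shark density.

    ``humans_200km`` is the number of people living within a 200-km radius of
    the reef (the achievable range of a fishing-boat day trip); it may be
    exactly zero for uninhabited islands.  ``productivity`` is oceanic primary
    productivity in mg C m^-2 day^-1, ``min_sst`` the climatological minimum
    monthly sea-surface temperature in deg C, ``reef_area_km2`` the shallow
    reef area, and ``mean_complexity`` the island mean of the divers' 1-6
    visual structural-complexity score.
    """

    island_id: str
    region: str
    humans_200km: float
    humans_per_km2_reef: float
    dist_pop_center_km: float
    productivity: float
    min_sst: float
    reef_area_km2: float
    mean_complexity: float = 3.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(
                f"island {self.island_id}: region {self.region!r} not one of {REGIONS}"
            )
        checks = {
            "humans_200km": (self.humans_200km, 0.0, True),
            "humans_per_km2_reef": (self.humans_per_km2_reef, 0.0, True),
            "dist_pop_center_km": (self.dist_pop_center_km, 0.0, False),
            "productivity": (self.productivity, 0.0, False),
            "reef_area_km2": (self.reef_area_km2, 0.0, False),
        }
        for name, (value, lo, inclusive) in checks.items():
            ok = value >= lo if inclusive else value > lo
            if not (ok and math.isfinite(value)):
                raise ValidationError(
                    f"island {self.island_id}: {name}={value!r} out of range"
                )
        if not math.isfinite(self.min_sst):
            raise ValidationError(f"island {self.island_id}: min_sst not finite")
        if not (1.0 <= self.mean_complexity <= 6.0):
            raise ValidationError(
                f"island {self.island_id}: mean_complexity {self.mean_complexity} "
                "not in [1, 6]"
            )


@dataclass(frozen=True)
class SpeciesGroup:
    """A named set of species codes whose counts are pooled for modeling."""

    name: str
    member_codes: frozenset[str]

    def __post_init__(self) -> None:
        bad = self.member_codes & set(NON_REEF_CODES)
        if bad:
            raise ConfigurationError(
                f"group {self.name!r} contains non-reef species {sorted(bad)}; "
                "tiger and hammerhead sharks are never modeled as reef sharks"
            )
        unknown = self.member_codes - set(SPECIES_NAMES)
        if unknown:
            raise ConfigurationError(
                f"group {self.name!r} contains unknown species codes {sorted(unknown)}"
            )


_GROUPS = {
    "all_reef_sharks": frozenset(REEF_SHARK_CODES),
    "gray_reef": frozenset({"GR"}),
    "whitetip_reef": frozenset({"WT"}),
}


def species_group(name: str) -> SpeciesGroup:
    """Return a predefined modeling group.

    ``all_reef_sharks`` pools the five reef-associated species (gray reef,
    whitetip reef, blacktip reef, Galapagos, tawny nurse); ``gray_reef`` and
    ``whitetip_reef`` are the two single-species groups modeled separately.
    """
    try:
        return SpeciesGroup(name, _GROUPS[name])
    except KeyError:
        raise ConfigurationError(
            f"unknown species group {name!r}; choose from {sorted(_GROUPS)}"
        ) from None
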