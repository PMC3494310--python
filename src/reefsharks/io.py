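"""Reading, validating, filtering and summarizing survey tables.

On-disk formats are plain CSV (UTF-8, header required):

* ``tows.csv`` — tow_id, island_id, year, habitat, length_km, width_m,
  complexity, then one column per species code (GR, WT, ...).
* ``islands.csv`` — island_id, region, humans_200km, humans_per_km2_reef,
  dist_pop_center_km, productivity, min_sst, reef_area_km2
  (optionally mean_complexity).

``filter_tows`` applies the analysis exclusions: forereef habitat only,
survey years restricted to the standardized-observer period, and tows at
least 1 km long (shorter tows indicate an anomalous dive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .records import (
    SPECIES_NAMES,
    ConfigurationError,
    IslandCovariates,
    SchemaError,
    SpeciesGroup,
    TowRecord,
    ValidationError,
)

__all__ = [
    "TOW_COLUMNS",
    "ISLAND_COLUMNS",
    "ExclusionReport",
    "read_tow_table",
    "write_tow_table",
    "read_island_table",
    "write_island_table",
    "filter_tows",
    "group_counts",
    "summarize_by_region",
]

TOW_COLUMNS = (
    "tow_id",
    "island_id",
    "year",
    "habitat",
    "length_km",
    "width_m",
    "complexity",
)
ISLAND_COLUMNS = (
    "island_id",
    "region",
    "humans_200km",
    "humans_per_km2_reef",
    "dist_pop_center_km",
    "productivity",
    "min_sst",
    "reef_area_km2",
)

# Default exclusion thresholds; configurable so sensitivity runs are possible.
DEFAULT_MIN_YEAR = 2004
DEFAULT_MAX_YEAR = 2010
DEFAULT_MIN_LENGTH_KM = 1.0
DEFAULT_HABITAT = "forereef"


def read_tow_table(path: str | Path) -> list[TowRecord]:
    """Parse ``tows.csv`` into validated :class:`TowRecord` objects.

    Columns beyond the required schema are treated as species-count columns.
    A stored ``area_ha`` column, if present, is cross-checked against
    length x width at 1% relative tolerance; the recomputed value wins.
    """
    df = pd.read_csv(path)
    missing = [c for c in TOW_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    species_cols = [c for c in df.columns if c not in TOW_COLUMNS and c != "area_ha"]
    records: list[TowRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        r = row._asdict()
        counts = {}
        for code in species_cols:
            value = r[code]
            n = int(value)
            if n != value or n < 0:
                raise ValidationError(
                    f"{path}: row {idx}: count {value!r} for species {code} "
                    "is not a non-negative integer"
                )
            counts[code] = n
        try:
            rec = TowRecord(
                tow_id=str(r["tow_id"]),
                island_id=str(r["island_id"]),
                year=int(r["year"]),
                habitat=str(r["habitat"]),
                length_km=float(r["length_km"]),
                width_m=float(r["width_m"]),
                complexity=int(r["complexity"]),
                counts=counts,
            )
        except ValidationError as err:
            raise ValidationError(f"{path}: row {idx}: {err}") from None
        if "area_ha" in df.columns:
            stored = float(r["area_ha"])
            if abs(stored - rec.area_ha) > 0.01 * max(abs(rec.area_ha), 1e-12):
                raise ValidationError(
                    f"{path}: row {idx}: stored area_ha={stored} disagrees with "
                    f"length x width = {rec.area_ha:.4f} ha by more than 1%"
                )
        records.append(rec)
    return records


def write_tow_table(records: list[TowRecord], path: str | Path) -> None:
    """Write tows to CSV; species columns are the union over records."""
    species = sorted({c for r in records for c in r.counts})
    rows = []
    for r in records:
        row = {
            "tow_id": r.tow_id,
            "island_id": r.island_id,
            "year": r.year,
            "habitat": r.habitat,
            "length_km": r.length_km,
            "width_m": r.width_m,
            "complexity": r.complexity,
        }
        for code in species:
            row[code] = r.counts.get(code, 0)
        rows.append(row)
    pd.DataFrame(rows, columns=list(TOW_COLUMNS) + species).to_csv(path, index=False)


def read_island_table(path: str | Path) -> list[IslandCovariates]:
    df = pd.read_csv(path)
    missing = [c for c in ISLAND_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    islands: list[IslandCovariates] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        r = row._asdict()
        iid = str(r["island_id"])
        if iid in seen:
            raise ValidationError(f"{path}: row {idx}: duplicate island_id {iid!r}")
        seen.add(iid)
        kwargs = {c: r[c] for c in ISLAND_COLUMNS if c != "island_id" and c != "region"}
        if "mean_complexity" in df.columns:
            kwargs["mean_complexity"] = float(r["mean_complexity"])
        islands.append(
            IslandCovariates(island_id=iid, region=str(r["region"]), **kwargs)
        )
    return islands


def write_island_table(islands: list[IslandCovariates], path: str | Path) -> None:
    cols = list(ISLAND_COLUMNS) + ["mean_complexity"]
    df = pd.DataFrame([{c: getattr(i, c) for c in cols} for i in islands])
    df.to_csv(path, index=False)


@dataclass
class ExclusionReport:
    """Counts of tows excluded per rule.

    A tow violating several rules is counted under each violated rule;
    ``n_excluded`` counts distinct excluded tows and ``n_kept`` the remainder.
    """

    habitat: int = 0
    year: int = 0
    length: int = 0
    n_excluded: int = 0
    n_kept: int = 0
    thresholds: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def filter_tows(
    records: list[TowRecord],
    min_year: int = DEFAULT_MIN_YEAR,
    max_year: int = DEFAULT_MAX_YEAR,
    min_length_km: float = DEFAULT_MIN_LENGTH_KM,
    habitat: str = DEFAULT_HABITAT,
) -> tuple[list[TowRecord], ExclusionReport]:
    """Apply the analysis exclusion rules and report per-rule counts."""
    report = ExclusionReport(
        thresholds={
            "min_year": min_year,
            "max_year": max_year,
            "min_length_km": min_length_km,
            "habitat": habitat,
        }
    )
    kept: list[TowRecord] = []
    for r in records:
        drop = False
        if r.habitat != habitat:
            report.habitat += 1
            drop = True
        if not (min_year <= r.year <= max_year):
            report.year += 1
            drop = True
        if r.length_km < min_length_km:
            report.length += 1
            drop = True
        if drop:
            report.n_excluded += 1
        else:
            kept.append(r)
    report.n_kept = len(kept)
    return kept, report


def group_counts(records: list[TowRecord], group: SpeciesGroup) -> pd.DataFrame:
    """Pool per-species counts into one response count per tow.

    Returns a frame with columns ``tow_id, island_id, area_ha, y`` in input
    order.  Species codes absent from a record's count map contribute zero.
    """
    observed_codes = {c for r in records for c in r.counts}
    unknown = group.member_codes - set(SPECIES_NAMES) - observed_codes
    if unknown:
        raise ConfigurationError(
            f"group {group.name!r} references unknown species codes {sorted(unknown)}"
        )
    rows = [
        {
            "tow_id": r.tow_id,
            "island_id": r.island_id,
            "area_ha": r.area_ha,
            "y": sum(r.counts.get(code, 0) for code in group.member_codes),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["tow_id", "island_id", "area_ha", "y"])


def summarize_by_region(
    records: list[TowRecord], islands: list[IslandCovariates]
) -> pd.DataFrame:
    """Per-region survey effort, covariate ranges and species totals.

    One row per region plus a ``Total`` row carrying reef/survey counts and
    species totals summed over regions.
    """
    by_island = {i.island_id: i for i in islands}
    orphans = sorted({r.island_id for r in records} - set(by_island))
    if orphans:
        raise ValidationError(f"tows reference unknown island_id(s): {orphans}")
    species = sorted({c for r in records for c in r.counts})
    range_vars = ("humans_200km", "productivity", "min_sst", "reef_area_km2")

    rows = []
    regions = []
    for i in islands:
        if i.region not in regions:
            regions.append(i.region)
    for region in regions:
        isl = [i for i in islands if i.region == region]
        ids = {i.island_id for i in isl}
        tows = [r for r in records if r.island_id in ids]
        row: dict = {
            "region": region,
            "n_reefs": len(isl),
            "n_surveys": len(tows),
        }
        for v in range_vars:
            vals = [getattr(i, v) for i in isl]
            row[f"{v}_min"] = min(vals)
            row[f"{v}_max"] = max(vals)
        for code in species:
            row[code] = sum(r.counts.get(code, 0) for r in tows)
        rows.append(row)
    total: dict = {
        "region": "Total",
        "n_reefs": sum(r["n_reefs"] for r in rows),
        "n_surveys": sum(r["n_surveys"] for r in rows),
    }
    for code in species:
        total[code] = sum(r[code] for r in rows)
    rows.append(total)
    return pd.DataFrame(rows).set_index("region")
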