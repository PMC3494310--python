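"""Design-matrix construction and collinearity screening.

Covariates enter the density model standardized (centered, unit standard
deviation) after optional log transforms.  The human-population metrics are
logged with a +1 offset so uninhabited islands (exactly zero humans) map to
log(1) = 0; reef area is logged plainly (all areas positive).  Because the
log of reef area and minimum temperature are strongly negatively correlated
in Pacific data, candidate models are enumerated in two sets that never mix
the two (set A carries temperature, set B reef area).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import ConfigurationError, IslandCovariates

__all__ = [
    "TransformSpec",
    "default_transform_spec",
    "load_transform_spec",
    "DesignMatrix",
    "CollinearityReport",
    "transform_covariates",
    "correlation_screen",
    "vif",
    "build_model_sets",
]

#: Per-column transform: (apply log, offset added before the log).
TransformSpec = dict[str, dict]


def default_transform_spec() -> TransformSpec:
    return {
        "humans_200km": {"log": True, "offset": 1.0},
        "humans_per_km2_reef": {"log": True, "offset": 1.0},
        "dist_pop_center_km": {"log": True, "offset": 0.0},
        "productivity": {"log": False, "offset": 0.0},
        "min_sst": {"log": False, "offset": 0.0},
        "reef_area_km2": {"log": True, "offset": 0.0},
        "mean_complexity": {"log": False, "offset": 0.0},
    }


def load_transform_spec(path: str | Path) -> TransformSpec:
    """Read a per-covariate ``{log: bool, offset: real}`` mapping from YAML."""
    spec = yaml.safe_load(Path(path).read_text())
    out: TransformSpec = {}
    for name, entry in spec.items():
        out[name] = {
            "log": bool(entry.get("log", False)),
            "offset": float(entry.get("offset", 0.0)),
        }
    return out


@dataclass
class DesignMatrix:
    """Standardized islands x covariates matrix plus inversion metadata.

    ``transform_meta[c]`` stores the log flag, offset, and the mean/sd of the
    transformed column, which is sufficient to map any raw covariate value to
    its standardized score (``standardize_raw``) and back (``raw_column``).
    ``raw`` retains the untransformed values for effect-curve grids.
    """

    island_ids: list[str]
    columns: list[str]
    X: np.ndarray
    transform_meta: dict[str, dict]
    raw: pd.DataFrame = field(repr=False, default=None)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.island_ids, columns=self.columns)

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.columns.index(name)]

    def standardize_raw(self, name: str, value: float | np.ndarray) -> np.ndarray:
        """Map raw covariate values through the stored transform chain."""
        m = self.transform_meta[name]
        v = np.asarray(value, dtype=float)
        t = np.log(v + m["offset"]) if m["log"] else v
        return (t - m["mean"]) / m["sd"]

    def raw_column(self, name: str) -> np.ndarray:
        """Invert standardization (and any log) back to raw values."""
        m = self.transform_meta[name]
        t = self.column(name) * m["sd"] + m["mean"]
        return np.exp(t) - m["offset"] if m["log"] else t

    def subset(self, columns: list[str]) -> "DesignMatrix":
        idx = [self.columns.index(c) for c in columns]
        return DesignMatrix(
            island_ids=self.island_ids,
            columns=list(columns),
            X=self.X[:, idx],
            transform_meta={c: self.transform_meta[c] for c in columns},
            raw=self.raw,
        )


def transform_covariates(
    islands: list[IslandCovariates],
    spec: TransformSpec | None = None,
    columns: list[str] | None = None,
) -> DesignMatrix:
    """Log-transform (where specified) then standardize island covariates.

    Raises on a log of a negative value (naming column and island) and on a
    column constant across islands (zero standard deviation cannot be
    standardized).
    """
    spec = default_transform_spec() if spec is None else spec
    if columns is None:
        columns = [c for c in default_transform_spec() if c in spec]
    ids = [i.island_id for i in islands]
    raw = pd.DataFrame(
        {c: [getattr(i, c) for i in islands] for c in columns}, index=ids
    )
    X = np.empty((len(islands), len(columns)))
    meta: dict[str, dict] = {}
    for j, c in enumerate(columns):
        entry = spec.get(c, {"log": False, "offset": 0.0})
        v = raw[c].to_numpy(dtype=float)
        if entry["log"]:
            shifted = v + entry["offset"]
            if np.any(shifted <= 0):
                bad = ids[int(np.argmax(shifted <= 0))]
                raise ConfigurationError(
                    f"log transform of column {c!r} undefined for island {bad} "
                    f"(value + offset <= 0)"
                )
            t = np.log(shifted)
        else:
            t = v
        mean, sd = float(np.mean(t)), float(np.std(t, ddof=0))
        if sd == 0.0:
            raise ConfigurationError(
                f"column {c!r} is constant across islands; cannot standardize"
            )
        X[:, j] = (t - mean) / sd
        meta[c] = {
            "log": entry["log"],
            "offset": entry["offset"],
            "mean": mean,
            "sd": sd,
        }
    return DesignMatrix(island_ids=ids, columns=list(columns), X=X,
                        transform_meta=meta, raw=raw)


@dataclass
class CollinearityReport:
    pairwise_r: pd.DataFrame
    flagged_pairs: list[tuple[str, str, float]]
    vif: dict[str, float]
    threshold: float

    def to_json(self, path: str | Path | None = None) -> str:
        import json

        payload = {
            "threshold": self.threshold,
            "pairwise_r": self.pairwise_r.to_dict(),
            "flagged_pairs": [list(p) for p in self.flagged_pairs],
            "vif": self.vif,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def correlation_screen(design: DesignMatrix, threshold: float = 0.7) -> CollinearityReport:
    """Pairwise Pearson correlations with |r| > threshold flagged, plus VIFs."""
    if len(design.island_ids) < 3:
        raise ValueError("correlation screen needs at least 3 islands")
    R = np.corrcoef(design.X, rowvar=False)
    R = np.atleast_2d(R)
    cols = design.columns
    flagged = [
        (cols[a], cols[b], float(R[a, b]))
        for a in range(len(cols))
        for b in range(a + 1, len(cols))
        if abs(R[a, b]) > threshold
    ]
    return CollinearityReport(
        pairwise_r=pd.DataFrame(R, index=cols, columns=cols),
        flagged_pairs=flagged,
        vif=vif(design),
        threshold=threshold,
    )


def vif(design: DesignMatrix, columns: list[str] | None = None) -> dict[str, float]:
    """Variance inflation factors, 1 / (1 - R^2_j).

    R^2_j is from the least-squares regression of column j on the other
    columns (with intercept).  Perfect collinearity yields ``inf`` rather
    than an exception.  A single column has VIF 1 by convention.
    """
    cols = design.columns if columns is None else list(columns)
    if len(design.island_ids) <= len(cols):
        raise ValueError("need more islands than columns to compute VIF")
    sub = design.X[:, [design.columns.index(c) for c in cols]]
    out: dict[str, float] = {}
    n = sub.shape[0]
    for j, c in enumerate(cols):
        if len(cols) == 1:
            out[c] = 1.0
            continue
        yj = sub[:, j]
        Xo = np.column_stack([np.ones(n), np.delete(sub, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ coef
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        out[c] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def build_model_sets(
    available: list[str],
    human: str = "humans_200km",
    productivity: str = "productivity",
    temperature: str = "min_sst",
    reef_area: str = "reef_area_km2",
    complexity: str = "mean_complexity",
) -> dict[str, list[tuple[str, ...]]]:
    """Enumerate the candidate covariate subsets for the two model sets.

    Set A draws subsets from {human, productivity, temperature, complexity},
    set B from {human, productivity, reef_area, complexity}; temperature and
    reef area never co-occur because their strong mutual correlation makes
    their effects inseparable.  Both sets include the null (empty) model.
    """

    def subsets(pool: list[str]) -> list[tuple[str, ...]]:
        pool = [c for c in pool if c in available]
        return list(
            chain.from_iterable(combinations(pool, r) for r in range(len(pool) + 1))
        )

    return {
        "A": subsets([human, productivity, temperature, complexity]),
        "B": subsets([human, productivity, reef_area, complexity]),
    }
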