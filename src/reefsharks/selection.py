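"""Bayesian variable selection and posterior-predictive model checking.

Variable selection follows the latent-indicator (Kuo–Mallick) scheme: each
coefficient is gated by a Bernoulli(0.5) indicator sampled inside the MCMC,
so the relative frequency of each joint indicator configuration among the
retained draws is the posterior weight of the corresponding covariate
subset, and the marginal frequency of an indicator is its covariate's
inclusion probability.  Goodness of fit is summarized by a posterior
predictive (Bayesian) p-value with sum-of-squared-residuals discrepancy:
a replicate data set is simulated at every retained draw and the p-value is
the fraction of draws whose replicate fits worse than the data; values near
0.5 indicate a well-calibrated model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import DesignMatrix, transform_covariates, default_transform_spec
from .model import ModelData, ModelSpec, PosteriorSamples, run_mcmc
from .records import IslandCovariates

__all__ = [
    "ModelWeightTable",
    "FitCheck",
    "posterior_model_weights",
    "bayesian_p_value",
    "compare_human_metrics",
    "refit_best",
]


@dataclass
class ModelWeightTable:
    """Posterior weights of covariate subsets from the indicator history."""

    rows: list[tuple[tuple[str, ...], float]]
    inclusion: dict[str, float]
    best: tuple[str, ...]
    #: tie-break: highest weight, then fewest covariates, then lexicographic
    tie_break: str = "fewest covariates, then lexicographic"

    def weight(self, subset: tuple[str, ...]) -> float:
        for s, wgt in self.rows:
            if s == subset:
                return wgt
        return 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": " + ".join(s) if s else "Null",
                    "weight": wgt,
                    "best": s == self.best,
                }
                for s, wgt in self.rows
            ]
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "rows": [{"subset": list(s), "weight": wgt} for s, wgt in self.rows],
            "inclusion": self.inclusion,
            "best": list(self.best),
            "tie_break": self.tie_break,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        """Human-readable table: subset label, weight, asterisk on best."""
        lines = [f"{'Model':<50s} Posterior weight"]
        for s, wgt in self.rows:
            label = " + ".join(s) if s else "Null"
            star = "*" if s == self.best else ""
            lines.append(f"{label:<50s} {wgt:.3f}{star}")
        return "\n".join(lines)


def posterior_model_weights(samples: PosteriorSamples) -> ModelWeightTable:
    """Subset weights = relative frequency of joint indicator configurations."""
    if not samples.spec.selection:
        raise ValueError(
            "posterior model weights require a fit with selection enabled"
        )
    w = samples.stacked("w")  # draws x covariates
    cols = samples.data.columns
    n = w.shape[0]
    counts: dict[tuple[str, ...], int] = {}
    codes, freq = np.unique(w, axis=0, return_counts=True)
    for row, c in zip(codes, freq):
        subset = tuple(name for name, inc in zip(cols, row) if inc == 1)
        counts[subset] = counts.get(subset, 0) + int(c)
    rows = sorted(
        ((s, c / n) for s, c in counts.items()),
        key=lambda item: (-item[1], len(item[0]), item[0]),
    )
    inclusion = {c: float(np.mean(w[:, j])) for j, c in enumerate(cols)}
    return ModelWeightTable(rows=rows, inclusion=inclusion, best=rows[0][0])


@dataclass
class FitCheck:
    bayesian_p: float
    discrepancy_observed: np.ndarray = field(repr=False)
    discrepancy_simulated: np.ndarray = field(repr=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "bayesian_p": self.bayesian_p,
            "n_iterations": int(len(self.discrepancy_observed)),
            "mean_discrepancy_observed": float(np.mean(self.discrepancy_observed)),
            "mean_discrepancy_simulated": float(np.mean(self.discrepancy_simulated)),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def bayesian_p_value(
    samples: PosteriorSamples,
    data: ModelData | None = None,
    seed: int = 0,
    batch: int = 512,
) -> FitCheck:
    """Posterior-predictive check with squared-residual discrepancy.

    At every retained draw, a replicate count is simulated for each tow from
    the negative binomial at that draw's island densities and overdispersion,
    over the observed tow areas; the discrepancy is sum_t (y_t - lambda_t)^2.
    Deterministic given ``seed``.
    """
    data = samples.data if data is None else data
    rng = np.random.default_rng(seed)
    mu = samples.stacked("mu")
    kdraws = samples.stacked("k")
    tow_island = np.repeat(np.arange(data.n_islands), np.diff(data.isl_start))
    y = data.y.astype(float)
    n = mu.shape[0]
    d_obs = np.empty(n)
    d_sim = np.empty(n)
    for start in range(0, n, batch):
        sl = slice(start, min(start + batch, n))
        lam = mu[sl][:, tow_island] * data.area  # draws x tows
        kk = kdraws[sl][:, None]
        y_rep = rng.negative_binomial(kk, kk / (kk + lam))
        d_obs[sl] = np.sum((y - lam) ** 2, axis=1)
        d_sim[sl] = np.sum((y_rep - lam) ** 2, axis=1)
    return FitCheck(
        bayesian_p=float(np.mean(d_sim > d_obs)),
        discrepancy_observed=d_obs,
        discrepancy_simulated=d_sim,
    )


def compare_human_metrics(
    grouped: pd.DataFrame,
    islands: list[IslandCovariates],
    metrics: tuple[str, ...] = (
        "humans_200km",
        "humans_per_km2_reef",
        "dist_pop_center_km",
    ),
    spec: ModelSpec | None = None,
    transform_spec: dict | None = None,
    seed: int = 0,
    **mcmc_kwargs,
) -> pd.DataFrame:
    """Rank alternative human-pressure metrics by goodness of fit.

    Each metric is fitted as a single-covariate selection model; the report
    gives its average inclusion probability and Bayesian p-value, ranked by
    |p - 0.5| (ties broken by metric name).  One row per requested metric.
    """
    tspec = default_transform_spec() if transform_spec is None else transform_spec
    rows = []
    for m, metric in enumerate(metrics):
        design = transform_covariates(islands, tspec, columns=[metric])
        data = ModelData.from_frames(grouped, design)
        base = spec if spec is not None else ModelSpec()
        fit_spec = ModelSpec(
            covariates=(metric,),
            link=base.link,
            priors=base.priors,
            weight_variance_by_n=base.weight_variance_by_n,
            selection=True,
            group=base.group,
        )
        fit = run_mcmc(data, fit_spec, seed=seed + m, **mcmc_kwargs)
        inclusion = float(np.mean(fit.stacked(f"w:{metric}")))
        check = bayesian_p_value(fit, seed=seed + 101 * (m + 1))
        rows.append(
            {
                "metric": metric,
                "inclusion_probability": inclusion,
                "bayesian_p": check.bayesian_p,
                "fit_distance": abs(check.bayesian_p - 0.5),
            }
        )
    report = pd.DataFrame(rows).sort_values(
        ["fit_distance", "metric"], kind="stable"
    )
    report["rank"] = range(1, len(report) + 1)
    return report.reset_index(drop=True)


def refit_best(
    data: ModelData,
    best_subset: tuple[str, ...],
    design: DesignMatrix,
    grouped: pd.DataFrame,
    spec: ModelSpec | None = None,
    **mcmc_kwargs,
) -> tuple[PosteriorSamples, pd.DataFrame]:
    """Refit the selected subset with indicators removed.

    Returns the fit and a coefficient table (posterior median and central
    95% interval on the standardized scale) with one row per subset member
    plus the intercept.  An empty subset is a legal intercept-only fit.
    """
    base = spec if spec is not None else ModelSpec()
    sub_data = ModelData.from_frames(grouped, design, covariates=tuple(best_subset))
    fit_spec = ModelSpec(
        covariates=tuple(best_subset),
        link=base.link,
        priors=base.priors,
        weight_variance_by_n=base.weight_variance_by_n,
        selection=False,
        group=base.group,
    )
    fit = run_mcmc(sub_data, fit_spec, **mcmc_kwargs)
    rows = []
    for name in ("alpha", *[f"beta:{c}" for c in best_subset]):
        draws = fit.stacked(name)
        lo, med, hi = np.percentile(draws, [2.5, 50, 97.5])
        rows.append({"parameter": name, "median": med, "lo95": lo, "hi95": hi})
    return fit, pd.DataFrame(rows).set_index("parameter")
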