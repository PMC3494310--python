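"""Hierarchical Bayesian model of shark counts from towed-diver surveys.

The generative model: the count on tow *t* at island *i* is negative
binomial with mean ``lambda_t = mu_i * area_t`` (``mu_i`` in sharks/ha,
``area_t`` the tow's swept hectares) and overdispersion ``k`` (variance
``lambda + lambda^2 / k``).  Island mean densities ``mu_i`` follow a normal
hyperdistribution truncated to positive values, centered on the linear
predictor ``E_i = alpha + sum_j w_j beta_j x_ij`` over standardized island
covariates, with variance ``sigma^2 / n_i`` (shrinking for islands with more
tows).  Under the optional log link the hyperdistribution is centered on
``exp(E_i)`` instead.  Priors: Normal(0, 100) on intercept and coefficients,
Gamma(0.01, 0.01) on the precision ``1/sigma^2`` and on ``k``, and
Bernoulli(0.5) on each inclusion indicator ``w_j`` when variable selection
is on.

Inference is by adaptive Metropolis-within-Gibbs (see ``_kernel``), run as
multiple independent chains; :func:`gelman_rubin` computes the potential
scale reduction factor for convergence checking.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from . import _kernel
from .covariates import DesignMatrix

__all__ = [
    "PriorSpec",
    "ModelSpec",
    "ParameterState",
    "ModelData",
    "PosteriorSamples",
    "nb_log_pmf",
    "tow_mean",
    "truncnorm_log_pdf",
    "truncnorm_mean",
    "linear_predictor",
    "log_posterior",
    "run_mcmc",
    "gelman_rubin",
]

# Desk-scale defaults; the published protocol (500,000 iterations, 100,000
# burn-in, 2 chains) is available by passing those values explicitly.
DEFAULT_N_ITER = 20_000
DEFAULT_N_BURN = 4_000
DEFAULT_CHAINS = 2


@dataclass
class PriorSpec:
    """Hyperparameters of the weakly informative priors."""

    coef_mean: float = 0.0
    coef_var: float = 100.0
    hypervar_gamma_shape: float = 0.01
    hypervar_gamma_rate: float = 0.01
    #: gamma prior placed on the precision 1/sigma^2 (the conventional BUGS
    #: idiom); set False to place it on sigma^2 directly
    hypervar_on_precision: bool = True
    k_gamma_shape: float = 0.01
    k_gamma_rate: float = 0.01
    indicator_prob: float = 0.5

    def __post_init__(self) -> None:
        for name in ("coef_var", "hypervar_gamma_shape", "hypervar_gamma_rate",
                     "k_gamma_shape", "k_gamma_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.indicator_prob < 1.0:
            raise ValueError("indicator_prob must lie in (0, 1)")


@dataclass
class ModelSpec:
    """What to fit: covariate set, link, priors, and the selection flag."""

    covariates: tuple[str, ...] = ()
    link: str = "identity"
    priors: PriorSpec = field(default_factory=PriorSpec)
    weight_variance_by_n: bool = True
    selection: bool = False
    group: str = "all_reef_sharks"

    def __post_init__(self) -> None:
        if self.link not in ("identity", "log"):
            raise ValueError("link must be 'identity' or 'log'")
        self.covariates = tuple(self.covariates)


@dataclass
class ParameterState:
    """One point in parameter space (one MCMC draw)."""

    alpha: float
    beta: np.ndarray
    sigma2: float
    k: float
    mu: np.ndarray
    w: np.ndarray

    def validate(self) -> None:
        if self.sigma2 <= 0 or self.k <= 0:
            raise ValueError("sigma2 and k must be strictly positive")
        if np.any(self.mu <= 0):
            raise ValueError("island mean densities must be strictly positive")


@dataclass
class ModelData:
    """Analysis-ready arrays: counts and areas sorted by island, plus the
    covariate sub-matrix for the islands actually surveyed."""

    y: np.ndarray
    area: np.ndarray
    isl_start: np.ndarray
    island_ids: list[str]
    n_per_island: np.ndarray
    X: np.ndarray
    columns: list[str]

    @classmethod
    def from_frames(cls, grouped: pd.DataFrame, design: DesignMatrix,
                    covariates: tuple[str, ...] | None = None) -> "ModelData":
        """Assemble model arrays from ``group_counts`` output and a design matrix.

        ``covariates`` restricts to a subset of design columns (the candidate
        model); islands with no tows are dropped from the design.
        """
        cols = list(design.columns if covariates is None else covariates)
        present = [i for i in design.island_ids if i in set(grouped["island_id"])]
        missing = set(grouped["island_id"]) - set(design.island_ids)
        if missing:
            raise ValueError(f"tows reference islands absent from design: {sorted(missing)}")
        order = {iid: r for r, iid in enumerate(present)}
        g = grouped.copy()
        g["_rank"] = g["island_id"].map(order)
        g = g.sort_values(["_rank"], kind="stable")
        counts = g.groupby("_rank").size()
        isl_start = np.zeros(len(present) + 1, dtype=np.int64)
        isl_start[1:] = np.cumsum(counts.to_numpy())
        rows = [design.island_ids.index(i) for i in present]
        col_idx = [design.columns.index(c) for c in cols]
        X = design.X[np.ix_(rows, col_idx)] if cols else np.zeros((len(present), 0))
        return cls(
            y=g["y"].to_numpy(dtype=np.int64),
            area=g["area_ha"].to_numpy(dtype=float),
            isl_start=isl_start,
            island_ids=present,
            n_per_island=counts.to_numpy(dtype=float),
            X=np.ascontiguousarray(X, dtype=float),
            columns=cols,
        )

    @property
    def n_islands(self) -> int:
        return len(self.island_ids)

    def island_slice(self, i: int) -> slice:
        return slice(self.isl_start[i], self.isl_start[i + 1])


def nb_log_pmf(y, lam, k):
    """Negative-binomial log pmf with mean ``lam`` and variance
    ``lam + lam^2/k`` (overdispersion ``k``)."""
    y = np.asarray(y)
    lam = np.asarray(lam, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lam must be >= 0")
    if np.any(k <= 0):
        raise ValueError("k must be > 0")
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("y must be a non-negative integer")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            special.gammaln(y + k)
            - special.gammaln(k)
            - special.gammaln(y + 1.0)
            + k * np.log(k / (k + lam))
            + np.where(lam > 0, y * np.log(lam / (k + lam)), 0.0)
        )
    # a zero mean makes zero counts certain and positive counts impossible
    out = np.where(lam == 0, np.where(y == 0, 0.0, -np.inf), out)
    return out if out.ndim else float(out)


def tow_mean(mu_i, area_ha):
    """Expected count on a tow: density (sharks/ha) times swept hectares."""
    return np.asarray(mu_i, dtype=float) * np.asarray(area_ha, dtype=float)


def truncnorm_log_pdf(mu, E, var):
    """log-density of Normal(E, var) truncated to (0, inf); -inf for mu <= 0."""
    if np.any(np.asarray(var) <= 0):
        raise ValueError("var must be > 0")
    mu = np.asarray(mu, dtype=float)
    s = np.sqrt(var)
    with np.errstate(divide="ignore"):
        lp = stats.norm.logpdf(mu, loc=E, scale=s) - special.log_ndtr(
            np.asarray(E, dtype=float) / s
        )
    out = np.where(mu > 0, lp, -np.inf)
    return out if out.ndim else float(out)


def truncnorm_mean(loc, scale):
    """Mean of Normal(loc, scale^2) truncated to (0, inf), closed form."""
    loc = np.asarray(loc, dtype=float)
    scale = np.asarray(scale, dtype=float)
    z = loc / scale
    out = loc + scale * np.exp(stats.norm.logpdf(z) - special.log_ndtr(z))
    return out if out.ndim else float(out)


def linear_predictor(alpha, beta, w, x):
    """E = alpha + sum_j w_j beta_j x_j (indicators gate effects)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    w = np.atleast_1d(np.asarray(w, dtype=float))
    x = np.atleast_2d(np.asarray(x, dtype=float))
    out = alpha + x @ (w * beta)
    return float(out[0]) if out.shape[0] == 1 and np.ndim(alpha) == 0 else out


def _location(E, link):
    return np.exp(E) if link == "log" else E


def log_posterior(state: ParameterState, data: ModelData, spec: ModelSpec) -> float:
    """Unnormalized log posterior of one parameter state (reference path).

    Sums the negative-binomial tow likelihood, the truncated-normal island
    terms with variance sigma^2/n_i, and all priors.  The compiled sampler
    targets exactly this density (up to state-independent constants).
    """
    if len(state.mu) != data.n_islands or len(state.beta) != len(data.columns):
        raise ValueError("state dimensions do not match data")
    if state.sigma2 <= 0 or state.k <= 0:
        return -np.inf
    if np.any(state.mu <= 0):
        return -np.inf
    pr = spec.priors
    lam = state.mu[np.repeat(np.arange(data.n_islands),
                             np.diff(data.isl_start))] * data.area
    total = float(np.sum(nb_log_pmf(data.y, lam, state.k)))
    E = linear_predictor(state.alpha, state.beta, state.w, data.X)
    n_i = data.n_per_island if spec.weight_variance_by_n else np.ones(data.n_islands)
    total += float(
        np.sum(truncnorm_log_pdf(state.mu, _location(E, spec.link),
                                 state.sigma2 / n_i))
    )
    total += float(
        stats.norm.logpdf(state.alpha, pr.coef_mean, np.sqrt(pr.coef_var))
    )
    total += float(
        np.sum(stats.norm.logpdf(state.beta, pr.coef_mean, np.sqrt(pr.coef_var)))
    )
    a, b = pr.hypervar_gamma_shape, pr.hypervar_gamma_rate
    if pr.hypervar_on_precision:
        total += float(a * np.log(b) - special.gammaln(a)
                       - (a + 1.0) * np.log(state.sigma2) - b / state.sigma2)
    else:
        total += float(stats.gamma.logpdf(state.sigma2, a, scale=1.0 / b))
    total += float(
        stats.gamma.logpdf(state.k, pr.k_gamma_shape, scale=1.0 / pr.k_gamma_rate)
    )
    if spec.selection:
        p = pr.indicator_prob
        total += float(np.sum(np.where(state.w == 1, np.log(p), np.log(1.0 - p))))
    return total


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, chains kept separate.

    Arrays are indexed ``[chain, iteration]`` (plus a trailing covariate or
    island axis).  ``stacked`` pools chains for posterior summaries.
    """

    spec: ModelSpec
    data: ModelData
    chains: int
    n_iter: int
    n_burn: int
    rng_seed: int
    alpha: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    k: np.ndarray
    w: np.ndarray
    accept: dict[str, float] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.chains * (self.n_iter - self.n_burn)

    def stacked(self, name: str) -> np.ndarray:
        """Pooled draws of one parameter; ``beta:<col>`` / ``mu:<island>``
        address components by name."""
        if ":" in name:
            base, key = name.split(":", 1)
            if base == "beta" or base == "w":
                j = self.data.columns.index(key)
                return getattr(self, base)[:, :, j].reshape(-1)
            if base == "mu":
                i = self.data.island_ids.index(key)
                return self.mu[:, :, i].reshape(-1)
            raise KeyError(name)
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def per_chain(self, name: str) -> np.ndarray:
        if ":" in name:
            base, key = name.split(":", 1)
            idx = (self.data.columns.index(key) if base in ("beta", "w")
                   else self.data.island_ids.index(key))
            return getattr(self, base)[:, :, idx]
        return getattr(self, name)

    def credible_interval(self, name: str, level: float = 0.95):
        x = self.stacked(name)
        lo, hi = np.percentile(x, [50 * (1 - level), 100 - 50 * (1 - level)], axis=0)
        return lo, hi

    def summary(self) -> pd.DataFrame:
        """Median and central 95% interval for every scalar parameter."""
        names = ["alpha", "sigma2", "k"]
        names += [f"beta:{c}" for c in self.data.columns]
        names += [f"mu:{i}" for i in self.data.island_ids]
        rows = []
        for name in names:
            x = self.stacked(name)
            lo, med, hi = np.percentile(x, [2.5, 50, 97.5])
            rows.append({"parameter": name, "median": med, "lo95": lo, "hi95": hi,
                         "mean": float(np.mean(x))})
        return pd.DataFrame(rows).set_index("parameter")

    def save(self, directory: str | Path) -> None:
        """One CSV per chain plus a JSON manifest; re-loadable losslessly."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        spec_dict = asdict(self.spec)
        manifest = {
            "chains": self.chains,
            "n_iter": self.n_iter,
            "n_burn": self.n_burn,
            "rng_seed": self.rng_seed,
            "spec": spec_dict,
            "spec_hash": hashlib.sha256(
                json.dumps(spec_dict, sort_keys=True).encode()
            ).hexdigest(),
            "columns": self.data.columns,
            "island_ids": self.data.island_ids,
            "accept": self.accept,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for c in range(self.chains):
            cols = {"alpha": self.alpha[c], "sigma2": self.sigma2[c], "k": self.k[c]}
            for j, name in enumerate(self.data.columns):
                cols[f"beta:{name}"] = self.beta[c, :, j]
                cols[f"w:{name}"] = self.w[c, :, j]
            for i, iid in enumerate(self.data.island_ids):
                cols[f"mu:{iid}"] = self.mu[c, :, i]
            # %.17g guarantees exact float round-trip through text
            pd.DataFrame(cols).to_csv(d / f"chain_{c}.csv", index=False,
                                      float_format="%.17g")

    @classmethod
    def load(cls, directory: str | Path, data: ModelData) -> "PosteriorSamples":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        spec_dict = manifest["spec"]
        spec_dict["priors"] = PriorSpec(**spec_dict["priors"])
        spec = ModelSpec(**spec_dict)
        chains = manifest["chains"]
        frames = [
            pd.read_csv(d / f"chain_{c}.csv", float_precision="round_trip")
            for c in range(chains)
        ]
        keep = len(frames[0])
        P, I = len(manifest["columns"]), len(manifest["island_ids"])
        out = cls(
            spec=spec, data=data, chains=chains,
            n_iter=manifest["n_iter"], n_burn=manifest["n_burn"],
            rng_seed=manifest["rng_seed"],
            alpha=np.stack([f["alpha"].to_numpy() for f in frames]),
            beta=np.stack(
                [f[[f"beta:{c}" for c in manifest["columns"]]].to_numpy()
                 for f in frames]
            ).reshape(chains, keep, P),
            mu=np.stack(
                [f[[f"mu:{i}" for i in manifest["island_ids"]]].to_numpy()
                 for f in frames]
            ).reshape(chains, keep, I),
            sigma2=np.stack([f["sigma2"].to_numpy() for f in frames]),
            k=np.stack([f["k"].to_numpy() for f in frames]),
            w=np.stack(
                [f[[f"w:{c}" for c in manifest["columns"]]].to_numpy()
                 for f in frames]
            ).reshape(chains, keep, P).astype(np.int8),
            accept=manifest.get("accept", {}),
        )
        return out


def _initial_state(data: ModelData, spec: ModelSpec) -> ParameterState:
    mu0 = np.empty(data.n_islands)
    for i in range(data.n_islands):
        sl = data.island_slice(i)
        mu0[i] = (data.y[sl].sum() + 0.5) / data.area[sl].sum()
    P = len(data.columns)
    sigma2_0 = max(float(np.var(mu0)), 0.1)
    return ParameterState(
        alpha=float(np.mean(mu0)),
        beta=np.zeros(P),
        sigma2=sigma2_0,
        k=1.0,
        mu=mu0,
        w=np.ones(P, dtype=np.int8),
    )


def run_mcmc(
    data: ModelData,
    spec: ModelSpec,
    n_iter: int = DEFAULT_N_ITER,
    n_burn: int = DEFAULT_N_BURN,
    chains: int = DEFAULT_CHAINS,
    seed: int = 0,
    fix_sigma2: float | None = None,
    fix_k: float | None = None,
    init: ParameterState | None = None,
) -> PosteriorSamples:
    """Sample the posterior with independent adaptive MwG chains.

    Deterministic given ``seed`` (chain c uses a seed derived from it).
    ``fix_sigma2`` / ``fix_k`` pin those parameters (used by oracles and by
    conditional analyses); ``init`` overrides the data-driven start.
    """
    if n_burn >= n_iter:
        raise ValueError("n_burn must be smaller than n_iter")
    if chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")
    if np.all(data.y == 0) and (len(data.columns) == 0 or np.allclose(data.X, 0)):
        warnings.warn("all counts are zero on a degenerate design; the "
                      "posterior is prior-dominated", RuntimeWarning)
    P = len(data.columns)
    I = data.n_islands
    keep = n_iter - n_burn
    start = _initial_state(data, spec) if init is None else init
    n_per = (data.n_per_island if spec.weight_variance_by_n
             else np.ones(I, dtype=float))

    alpha = np.empty((chains, keep))
    beta = np.empty((chains, keep, P))
    mu = np.empty((chains, keep, I))
    sigma2 = np.empty((chains, keep))
    k = np.empty((chains, keep))
    w = np.empty((chains, keep, P), dtype=np.int8)
    acc = np.zeros((chains, 5))

    pr = spec.priors
    for c in range(chains):
        chain_seed = int((seed + 1_000_003 * (c + 1)) % (2**31 - 1))
        out_w = np.empty((keep, P), dtype=np.int8)
        _kernel.run_chain(
            data.y.astype(np.float64),
            data.area,
            data.isl_start,
            n_per.astype(np.float64),
            data.X,
            1 if spec.link == "log" else 0,
            1 if spec.selection else 0,
            pr.coef_mean,
            pr.coef_var,
            pr.hypervar_gamma_shape,
            pr.hypervar_gamma_rate,
            1 if pr.hypervar_on_precision else 0,
            pr.k_gamma_shape,
            pr.k_gamma_rate,
            pr.indicator_prob,
            n_iter,
            n_burn,
            chain_seed,
            -1.0 if fix_sigma2 is None else float(fix_sigma2),
            -1.0 if fix_k is None else float(fix_k),
            float(start.alpha),
            start.beta.astype(np.float64),
            start.mu.astype(np.float64),
            float(start.sigma2),
            float(start.k),
            start.w.astype(np.int8),
            alpha[c],
            beta[c],
            mu[c],
            sigma2[c],
            k[c],
            out_w,
            acc[c],
        )
        w[c] = out_w
    accept = {
        name: float(acc[:, idx].mean())
        for idx, name in enumerate(["alpha", "beta", "mu", "sigma2", "k"])
    }
    return PosteriorSamples(
        spec=spec, data=data, chains=chains, n_iter=n_iter, n_burn=n_burn,
        rng_seed=seed, alpha=alpha, beta=beta, mu=mu, sigma2=sigma2, k=k, w=w,
        accept=accept,
    )


def gelman_rubin(samples: PosteriorSamples | np.ndarray, parameter: str | None = None):
    """Potential scale reduction factor (between/within-chain variance ratio).

    Accepts a fitted :class:`PosteriorSamples` plus a parameter name, or a
    raw ``chains x iterations`` array.  Returns NaN (with a warning) when the
    within-chain variance is zero, which makes the statistic degenerate.
    """
    if isinstance(samples, PosteriorSamples):
        chains = samples.per_chain(parameter)
    else:
        chains = np.asarray(samples, dtype=float)
    m, n = chains.shape
    if m < 2 or n < 2:
        raise ValueError("need >= 2 chains with >= 2 retained iterations")
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    means = chains.mean(axis=1)
    B = n * float(np.var(means, ddof=1))
    if W == 0.0:
        warnings.warn("zero within-chain variance; R-hat is degenerate",
                      RuntimeWarning)
        return float("nan")
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))
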