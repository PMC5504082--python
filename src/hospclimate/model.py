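"""Hierarchical pooling of the six 30-day mortality measures.

The core model treats each available hospital × measure cell as a
binomial draw::

    deaths[i] ~ Binomial(denominator[i], p[i])
    logit(p[i]) = alpha_{measure[i]} + u_{hospital[i]} + gamma_{climate[i]}
                  + x_{hospital[i]} . beta

with hospital effects ``u_h ~ Normal(0, sigma_u)`` and partially pooled
climate effects ``gamma_c ~ Normal(0, sigma_gamma)``.  Modelling the
raw counts (not the published percentage) lets hospital size enter the
likelihood directly: a small hospital's rate is noisier and its effect
estimate shrinks harder toward the mean.  Weakly-informative priors:
Normal(0, 2.5) on ``alpha`` and ``beta``; half-Normal(1) on the scales.

Because the measure intercepts absorb any constant added to ``gamma``
(or ``u``), only contrasts between climates are likelihood-identified;
climate effects are therefore reported on the recentred (sum-to-zero)
scale ``gamma_c - mean(gamma)``.

A ``normal-on-logit-rate`` likelihood (Gaussian model for the logit of
the continuity-corrected observed rate) is exposed for sensitivity
analysis; it deliberately lacks the size-dependent sampling variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd

from ._sampler import SamplerSpec, run_chain
from .ingest import Cohort
from .linkage import CONFOUNDER_COLUMNS

__all__ = [
    "ConvergenceError",
    "ModelConfig",
    "ModelInputs",
    "PosteriorSummary",
    "ClimateSignificance",
    "standardize_covariates",
    "back_transform_covariates",
    "build_model_inputs",
    "log_likelihood",
    "fit",
    "climate_effect_table",
    "climate_significance",
]

RHAT_THRESHOLD = 1.05
ESS_THRESHOLD = 100.0


class ConvergenceError(RuntimeError):
    """Raised when an operation requires a converged fit and the fit is not."""


def standardize_covariates(
    table: pd.DataFrame, *, log_income: bool = True,
) -> tuple[np.ndarray, dict]:
    """Column-wise z-scores of the six confounders (sample sd, n−1).

    ``log_income`` (default on) log-transforms income first: county
    incomes are heavily right-skewed and the model is additive on the
    logit scale.  Returns the standardized matrix and a scaling record
    sufficient to map coefficients (or the matrix) back to natural
    units.  A zero-variance column is unusable and raises, naming the
    column.
    """
    missing = set(CONFOUNDER_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"confounder table missing column(s): {sorted(missing)}")
    raw = table[list(CONFOUNDER_COLUMNS)].astype(float).to_numpy().copy()
    if np.isnan(raw).any():
        raise ValueError("confounder table contains missing values")
    if log_income:
        raw[:, 0] = np.log(raw[:, 0])
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=1)
    for j, col in enumerate(CONFOUNDER_COLUMNS):
        if not sd[j] > 0:
            raise ValueError(f"covariate {col!r} has zero variance")
    z = (raw - mean) / sd
    scaler = {"columns": list(CONFOUNDER_COLUMNS), "mean": mean.tolist(),
              "sd": sd.tolist(), "log_income": log_income}
    return z, scaler


def back_transform_covariates(z: np.ndarray, scaler: dict) -> pd.DataFrame:
    """Invert :func:`standardize_covariates` exactly."""
    raw = np.asarray(z, dtype=float) * np.array(scaler["sd"]) + np.array(scaler["mean"])
    if scaler["log_income"]:
        raw = raw.copy()
        raw[:, 0] = np.exp(raw[:, 0])
    return pd.DataFrame(raw, columns=scaler["columns"])


@dataclass
class ModelInputs:
    """Long-format arrays over the available hospital × measure cells."""

    deaths: np.ndarray
    denominators: np.ndarray
    hospital_index: np.ndarray
    measure_index: np.ndarray
    climate_index: np.ndarray
    covariates: np.ndarray          # n_hospitals x 6, standardized
    provider_ids: list[str]
    measure_ids: list[str]
    climate_codes: list[str]
    scaler: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.deaths)
        for name in ("denominators", "hospital_index", "measure_index", "climate_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from deaths")
        if np.any(self.deaths < 0) or np.any(self.deaths > self.denominators):
            raise ValueError("deaths must satisfy 0 <= deaths <= denominator")
        if self.covariates.shape != (len(self.provider_ids), len(CONFOUNDER_COLUMNS)):
            raise ValueError("covariates must be n_hospitals x 6")
        for idx, labels in ((self.hospital_index, self.provider_ids),
                            (self.measure_index, self.measure_ids),
                            (self.climate_index, self.climate_codes)):
            if n and (idx.min() < 0 or idx.max() >= len(labels)):
                raise ValueError("index out of bounds")

    @property
    def n_cells(self) -> int:
        return len(self.deaths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "provider_id": [self.provider_ids[i] for i in self.hospital_index],
            "measure_id": [self.measure_ids[i] for i in self.measure_index],
            "climate": [self.climate_codes[i] for i in self.climate_index],
            "deaths": self.deaths,
            "denominator": self.denominators,
        })


def build_model_inputs(cohort: Cohort, *, log_income: bool = True) -> ModelInputs:
    """Assemble model arrays from a filtered, linked cohort.

    Rows are ordered by (provider_id, measure_id) so the layout is
    stable across runs.  Needs at least two climates, otherwise the
    climate effect is unidentifiable.
    """
    hospitals = sorted(cohort.hospitals, key=lambda h: h.provider_id)
    if not hospitals:
        raise ValueError("empty cohort")
    climates = sorted({h.climate for h in hospitals})
    if len(climates) < 2:
        raise ValueError(f"need >= 2 climates for a climate effect, got {len(climates)}")
    measures = sorted({o.measure_id for h in hospitals for o in h.observations if o.available})
    provider_ids = [h.provider_id for h in hospitals]
    c_of = {c: i for i, c in enumerate(climates)}
    m_of = {m: i for i, m in enumerate(measures)}

    conf = pd.DataFrame([dict(zip(CONFOUNDER_COLUMNS, h.confounders.as_tuple()))
                         for h in hospitals])
    z, scaler = standardize_covariates(conf, log_income=log_income)

    deaths, denoms, hidx, midx, cidx = [], [], [], [], []
    for i, h in enumerate(hospitals):
        for o in sorted(h.observations, key=lambda o: o.measure_id):
            if not o.available:
                continue
            deaths.append(o.deaths)
            denoms.append(o.denominator)
            hidx.append(i)
            midx.append(m_of[o.measure_id])
            cidx.append(c_of[h.climate])

    return ModelInputs(
        deaths=np.array(deaths, dtype=np.int64),
        denominators=np.array(denoms, dtype=np.int64),
        hospital_index=np.array(hidx, dtype=np.int64),
        measure_index=np.array(midx, dtype=np.int64),
        climate_index=np.array(cidx, dtype=np.int64),
        covariates=z,
        provider_ids=provider_ids,
        measure_ids=measures,
        climate_codes=climates,
        scaler=scaler,
    )


@dataclass(frozen=True)
class ModelConfig:
    """Sampler settings; defaults follow the engine convention of 2000
    iterations (half warm-up) on 4 chains."""

    chains: int = 4
    iterations: int = 2000
    warmup_frac: float = 0.5
    seed: int = 0
    prior_scale_fixed: float = 2.5
    prior_scale_sigma: float = 1.0
    likelihood: str = "binomial-logit"
    include_climate: bool = True
    pooled_climate: bool = True
    store_loglik: bool = False

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations < 2:
            raise ValueError("need >= 1 chain and >= 2 iterations")
        if not 0.0 < self.warmup_frac < 1.0:
            raise ValueError("warmup_frac must be in (0, 1)")


def _hospital_climates(inputs: ModelInputs) -> np.ndarray:
    hclim = np.zeros(len(inputs.provider_ids), dtype=np.int64)
    hclim[inputs.hospital_index] = inputs.climate_index
    return hclim


def _make_spec(inputs: ModelInputs, config: ModelConfig) -> SamplerSpec:
    return SamplerSpec(
        y=inputs.deaths.astype(float),
        n=inputs.denominators.astype(float),
        hidx=inputs.hospital_index,
        midx=inputs.measure_index,
        cidx=inputs.climate_index if config.include_climate else None,
        xcell=inputs.covariates.T[:, inputs.hospital_index],
        n_hospitals=len(inputs.provider_ids),
        n_measures=len(inputs.measure_ids),
        n_climates=len(inputs.climate_codes),
        xhosp=inputs.covariates,
        hclim=_hospital_climates(inputs) if config.include_climate else None,
        prior_scale_fixed=config.prior_scale_fixed,
        prior_scale_sigma=config.prior_scale_sigma,
        pooled_climate=config.pooled_climate,
        likelihood=config.likelihood,
    )


def log_likelihood(inputs: ModelInputs, alpha, beta, gamma, u) -> float:
    """Model log-likelihood at explicit parameter values (binomial-logit).

    Includes the binomial normalizing constant, so it matches a direct
    sum of binomial log-pmfs.
    """
    spec = _make_spec(inputs, ModelConfig())
    eta = (np.asarray(alpha)[inputs.measure_index]
           + np.asarray(u)[inputs.hospital_index]
           + np.asarray(gamma)[inputs.climate_index]
           + np.asarray(beta) @ spec.xcell)
    return float(np.sum(spec.loglik_cells(eta)))


@dataclass
class PosteriorSummary:
    """Posterior summaries, diagnostics and the underlying draws."""

    idata: az.InferenceData
    summary: pd.DataFrame
    converged: bool
    max_rhat: float
    min_ess: float
    measure_ids: list[str]
    climate_codes: list[str] | None
    config: ModelConfig

    def parameter(self, name: str) -> pd.Series:
        row = self.summary.loc[self.summary["parameter"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def _summarize(idata: az.InferenceData, var_labels: dict[str, list[str] | None]) -> pd.DataFrame:
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for var, labels in var_labels.items():
        draws = idata.posterior[var].values  # (chain, draw, ...) or (chain, draw)
        flat = draws.reshape(draws.shape[0] * draws.shape[1], -1)
        r = np.atleast_1d(rhat[var].values).ravel()
        e = np.atleast_1d(ess[var].values).ravel()
        for j in range(flat.shape[1]):
            name = var if labels is None else f"{var}[{labels[j]}]"
            x = flat[:, j]
            rows.append({
                "parameter": name, "mean": float(x.mean()), "sd": float(x.std(ddof=1)),
                "q2.5": float(np.quantile(x, 0.025)), "q97.5": float(np.quantile(x, 0.975)),
                "rhat": float(r[j]), "ess": float(e[j]),
            })
    return pd.DataFrame(rows)


def fit(inputs: ModelInputs, config: ModelConfig = ModelConfig()) -> PosteriorSummary:
    """Fit the hierarchical model by MCMC.

    Chains are seeded from ``config.seed``; rerunning with the same
    inputs, config and library versions reproduces the summary exactly.
    A fit failing the convergence thresholds (R-hat ≤ 1.05, ESS ≥ 100)
    is returned with ``converged=False``, never silently.
    """
    spec = _make_spec(inputs, config)
    warmup = int(round(config.iterations * config.warmup_frac))
    chains = []
    for c in range(config.chains):
        rng = np.random.default_rng([int(config.seed), c])
        chains.append(run_chain(spec, config.iterations, warmup, rng,
                                store_loglik=config.store_loglik))

    def stack(key):
        return np.stack([ch[key] for ch in chains])

    post = {"alpha": stack("alpha"), "beta": stack("beta"),
            "u": stack("u"), "sigma_u": stack("sigma_u")}
    dims = {"alpha": ["measure"], "beta": ["covariate"], "u": ["hospital"]}
    coords = {"measure": inputs.measure_ids, "covariate": list(CONFOUNDER_COLUMNS),
              "hospital": inputs.provider_ids}
    if config.include_climate:
        post["gamma"] = stack("gamma")
        dims["gamma"] = ["climate"]
        coords["climate"] = inputs.climate_codes
        if config.pooled_climate:
            post["sigma_gamma"] = stack("sigma_gamma")
    if config.likelihood == "normal-on-logit-rate":
        post["sigma_e"] = stack("sigma_e")

    kwargs = {}
    if config.store_loglik:
        kwargs["log_likelihood"] = {"deaths": stack("log_lik")}
        dims["deaths"] = ["cell"]
        coords["cell"] = np.arange(inputs.n_cells)
    idata = az.from_dict(posterior=post, dims=dims, coords=coords, **kwargs)

    var_labels: dict[str, list[str] | None] = {
        "alpha": inputs.measure_ids, "beta": list(CONFOUNDER_COLUMNS),
        "u": inputs.provider_ids, "sigma_u": None}
    if config.include_climate:
        var_labels["gamma"] = inputs.climate_codes
        if config.pooled_climate:
            var_labels["sigma_gamma"] = None
    if config.likelihood == "normal-on-logit-rate":
        var_labels["sigma_e"] = None
    summary = _summarize(idata, var_labels)

    max_rhat = float(summary["rhat"].max())
    min_ess = float(summary["ess"].min())
    return PosteriorSummary(
        idata=idata, summary=summary,
        converged=bool(max_rhat <= RHAT_THRESHOLD and min_ess >= ESS_THRESHOLD),
        max_rhat=max_rhat, min_ess=min_ess,
        measure_ids=inputs.measure_ids,
        climate_codes=inputs.climate_codes if config.include_climate else None,
        config=config)


def recentred_gamma_draws(posterior: PosteriorSummary) -> np.ndarray:
    """Sum-to-zero climate effects, (n_draws, n_climates)."""
    g = posterior.idata.posterior["gamma"].values
    flat = g.reshape(-1, g.shape[-1])
    return flat - flat.mean(axis=1, keepdims=True)


def climate_effect_table(posterior: PosteriorSummary, *, require_converged: bool = True) -> pd.DataFrame:
    """Per-climate effect table on the recentred logit scale.

    One row per climate: posterior mean of the sum-to-zero effect, 95%
    interval, and rank from lowest (best, rank 1) to highest (worst)
    mortality effect.  Refuses a non-converged fit.
    """
    if posterior.climate_codes is None:
        raise ValueError("fit has no climate block")
    if require_converged and not posterior.converged:
        raise ConvergenceError(
            f"fit not converged (max R-hat {posterior.max_rhat:.3f}, "
            f"min ESS {posterior.min_ess:.0f}); refusing to tabulate climate effects")
    gt = recentred_gamma_draws(posterior)
    table = pd.DataFrame({
        "climate": posterior.climate_codes,
        "mean": gt.mean(axis=0),
        "q2.5": np.quantile(gt, 0.025, axis=0),
        "q97.5": np.quantile(gt, 0.975, axis=0),
    })
    table["rank"] = table["mean"].rank(method="first").astype(int)
    return table.sort_values("rank").reset_index(drop=True)


@dataclass(frozen=True)
class ClimateSignificance:
    """Full vs no-climate model comparison (WAIC) plus the sigma_gamma rule."""

    elpd_full: float
    elpd_noclimate: float
    elpd_diff: float        # full - noclimate; positive favours climate
    se_diff: float
    sigma_gamma_q2_5: float
    climate_preferred: bool  # elpd_diff > 2 * se_diff
    climate_matters: bool    # climate_preferred OR sigma_gamma_q2_5 > 0.01


def climate_significance(inputs: ModelInputs, config: ModelConfig = ModelConfig()) -> ClimateSignificance:
    """Does climate carry predictive information beyond the confounders?

    Fits the model with and without the climate block and compares
    expected log predictive density (WAIC); the standard error of the
    difference comes from the pointwise contributions.  "Climate
    matters" when the no-climate model loses by more than two standard
    errors, or when the 95% interval of ``sigma_gamma`` excludes values
    below 0.01 on the logit scale.  Refuses non-converged fits.
    """
    full_cfg = replace(config, include_climate=True, store_loglik=True)
    null_cfg = replace(config, include_climate=False, store_loglik=True)
    post_full = fit(inputs, full_cfg)
    post_null = fit(inputs, null_cfg)
    for label, p in (("full", post_full), ("no-climate", post_null)):
        if not p.converged:
            raise ConvergenceError(
                f"{label} model not converged (max R-hat {p.max_rhat:.3f}, "
                f"min ESS {p.min_ess:.0f})")

    w_full = az.waic(post_full.idata, pointwise=True)
    w_null = az.waic(post_null.idata, pointwise=True)
    pw_diff = w_full.waic_i.values - w_null.waic_i.values
    n = pw_diff.size
    elpd_diff = float(pw_diff.sum())
    se_diff = float(np.sqrt(n * np.var(pw_diff, ddof=1))) if n > 1 else 0.0

    sg = post_full.parameter("sigma_gamma")
    preferred = elpd_diff > 2.0 * se_diff
    return ClimateSignificance(
        elpd_full=float(w_full.elpd_waic),
        elpd_noclimate=float(w_null.elpd_waic),
        elpd_diff=elpd_diff,
        se_diff=se_diff,
        sigma_gamma_q2_5=float(sg["q2.5"]),
        climate_preferred=preferred,
        climate_matters=bool(preferred or sg["q2.5"] > 0.01),
    )
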