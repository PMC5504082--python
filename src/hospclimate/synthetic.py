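"""Synthetic Hospital Compare-style cohorts with known ground truth.

The generator emulates the structures the pipeline consumes: counties
nested in Köppen-Geiger climates (some counties straddling a boundary
with mixed shares), hospitals nested in counties, county-level
socioeconomic confounders that shift with climate, per-cell binomial
death counts driven by measure intercepts, hospital effects, climate
effects and confounder coefficients on the logit scale, and CMS-style
'Not Available' suppression of small-denominator cells.  Every latent
quantity is recorded so parameter recovery and filter bookkeeping are
exactly checkable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ingest import DEFAULT_MORTALITY_MEASURES, FileDialect
from .linkage import CONFOUNDER_COLUMNS

__all__ = ["Scenario", "SyntheticData", "generate", "emit_hospital_compare_csv",
           "emit_all"]

# climates observed across US counties, most common first
US_CLIMATE_CODES = (
    "Cfa", "Dfa", "Dfb", "BSk", "Csb", "Cfb", "BWh", "Dfc",
    "Aw", "Csa", "BWk", "BSh", "Am", "Dsb", "ET",
)

# per-condition 30-day baseline mortality (AMI, CABG, COPD, HF, PN, STK)
_DEFAULT_BASELINES = (0.14, 0.033, 0.08, 0.12, 0.16, 0.15)

# natural-unit scales for the six confounders; percents affine in the
# latent z-score with gentle slopes so clipping is effectively never hit
_CONF_LOC = {"income": (np.log(55000.0), 0.35), "households": (np.log(20000.0), 0.8),
             "pct_renter": (30.0, 7.0), "pct_uninsured": (12.0, 4.0),
             "pct_english_very_well": (80.0, 6.0), "pct_white_alone": (70.0, 7.0)}


@dataclass(frozen=True)
class Scenario:
    """Ground-truth parameter set driving the generator.

    Defaults describe the study conditions used throughout the test
    harness: 600 hospitals over 150 counties in 8 climates (one climate
    a forced singleton, exercising the singleton filter), six mortality
    measures with per-condition baselines, hospital sd 0.15, climate
    effects drawn Normal(0, 0.3) then centred, one active confounder
    coefficient (income, +0.2 per sd), denominators log-normal with
    median 200, suppression below 25 cases.
    """

    n_climates: int = 8
    n_counties: int = 150
    n_hospitals: int = 600
    measures: tuple[str, ...] = DEFAULT_MORTALITY_MEASURES
    alpha: tuple[float, ...] | None = None       # logit scale; None -> baselines
    gamma: tuple[float, ...] | None = None       # logit scale; None -> drawn
    gamma_sd: float = 0.3
    beta: tuple[float, ...] = (0.2, 0.0, 0.0, 0.0, 0.0, 0.0)
    sigma_u: float = 0.15
    denominator_median: float = 200.0
    denominator_sigma: float = 0.7               # log-scale dispersion
    min_denominator: int = 25                    # suppression threshold
    confounder_climate_assoc: float = 0.5        # share of z-variance from climate
    mixed_climate_frac: float = 0.3              # counties with a secondary climate
    include_singleton: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_climates, self.n_counties, self.n_hospitals) < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.n_climates > len(US_CLIMATE_CODES):
            raise ValueError(f"at most {len(US_CLIMATE_CODES)} climates supported")
        if self.n_counties < self.n_climates:
            raise ValueError("need at least one county per climate")
        if self.n_hospitals < self.n_counties:
            raise ValueError("need at least one hospital per county")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be non-negative")
        if len(self.beta) != len(CONFOUNDER_COLUMNS):
            raise ValueError(f"beta must have length {len(CONFOUNDER_COLUMNS)}")
        if self.alpha is not None and len(self.alpha) != len(self.measures):
            raise ValueError("alpha length must match measures")
        if self.gamma is not None and len(self.gamma) != self.n_climates:
            raise ValueError("gamma length must match n_climates")
        if self.denominator_median < 1 or self.min_denominator < 0:
            raise ValueError("invalid denominator settings")
        if not 0.0 <= self.confounder_climate_assoc <= 1.0:
            raise ValueError("confounder_climate_assoc must be in [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "Scenario":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("measures", "alpha", "gamma", "beta"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("measures", "alpha", "gamma", "beta"):
            if d[key] is not None:
                d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class SyntheticData:
    """Generated cohort tables plus the full ground-truth record."""

    scenario: Scenario
    hospitals: pd.DataFrame      # provider_id, zip, fips, climate
    cells: pd.DataFrame          # provider_id, measure_id, denominator, deaths, available
    climate_table: pd.DataFrame  # fips, koppen_code, proportion
    acs: pd.DataFrame            # fips + six confounders
    crosswalk: pd.DataFrame      # zip, fips
    truth: dict = field(default_factory=dict)


def _allocate(n_items: int, n_bins: int) -> np.ndarray:
    """Round-robin assignment of items to bins (balanced, deterministic)."""
    return np.arange(n_items) % n_bins


def generate(scenario: Scenario) -> SyntheticData:
    """Draw a full synthetic cohort; byte-identical for a fixed scenario."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    M, C, K, H = len(sc.measures), sc.n_climates, sc.n_counties, sc.n_hospitals
    P = len(CONFOUNDER_COLUMNS)
    climate_codes = list(US_CLIMATE_CODES[:C])

    alpha = (np.array(sc.alpha, dtype=float) if sc.alpha is not None
             else np.log(np.array(_DEFAULT_BASELINES[:M]) / (1 - np.array(_DEFAULT_BASELINES[:M]))))
    if sc.gamma is not None:
        gamma = np.array(sc.gamma, dtype=float)
    else:
        gamma = rng.normal(0.0, sc.gamma_sd, size=C)
        gamma -= gamma.mean()

    # counties -> climates; climate 0 is the forced singleton (one
    # county, one hospital) when requested
    if sc.include_singleton and C >= 2:
        county_climate = np.concatenate([[0], 1 + _allocate(K - 1, C - 1)])
    else:
        county_climate = _allocate(K, C)

    # hospitals -> counties (hospital 0 alone in the singleton county)
    if sc.include_singleton and C >= 2:
        hosp_county = np.concatenate([[0], 1 + _allocate(H - 1, K - 1)])
    else:
        hosp_county = _allocate(H, K)

    fips = np.array([f"{i + 1:05d}" for i in range(K)])
    providers = np.array([f"P{i + 1:05d}" for i in range(H)])
    zips = np.array([f"{i + 1:05d}" for i in range(H)])

    # confounders: county z-scores with a climate-level component
    assoc = sc.confounder_climate_assoc
    climate_shift = rng.normal(0.0, 1.0, size=(C, P))
    county_z = (assoc * climate_shift[county_climate]
                + np.sqrt(1.0 - assoc**2) * rng.normal(0.0, 1.0, size=(K, P)))

    acs_cols = {}
    for j, col in enumerate(CONFOUNDER_COLUMNS):
        loc, slope = _CONF_LOC[col]
        if col in ("income", "households"):
            vals = np.exp(loc + slope * county_z[:, j])
            if col == "households":
                vals = np.round(vals)
        else:
            vals = np.clip(loc + slope * county_z[:, j], 0.5, 99.5)
        acs_cols[col] = np.round(vals, 1)
    acs = pd.DataFrame({"fips": fips, **acs_cols})

    # hospital-level linear predictor pieces (beta acts on the county z)
    u = rng.normal(0.0, sc.sigma_u, size=H) if sc.sigma_u > 0 else np.zeros(H)
    hosp_z = county_z[hosp_county]
    hosp_climate = county_climate[hosp_county]
    xb = hosp_z @ np.array(sc.beta, dtype=float)

    # denominators: per-hospital size times per-cell jitter, log-normal
    # around the stated median; top-coded at 999 so the one-decimal
    # printed score reconstructs counts exactly
    log_size = rng.normal(0.0, 0.6, size=H)
    cell_jitter = rng.normal(0.0, np.sqrt(max(sc.denominator_sigma**2 - 0.36, 1e-6)),
                             size=(H, M))
    denom = np.exp(np.log(sc.denominator_median) + log_size[:, None] + cell_jitter)
    denom = np.clip(np.round(denom), 1, 999).astype(np.int64)

    eta = alpha[None, :] + u[:, None] + gamma[hosp_climate][:, None] + xb[:, None]
    p = 1.0 / (1.0 + np.exp(-eta))
    deaths = rng.binomial(denom, p)
    available = denom >= sc.min_denominator

    cells = pd.DataFrame({
        "provider_id": np.repeat(providers, M),
        "measure_id": np.tile(np.array(sc.measures), H),
        "denominator": denom.ravel(),
        "deaths": deaths.ravel(),
        "available": available.ravel(),
    })

    hospitals = pd.DataFrame({
        "provider_id": providers, "zip": zips, "fips": fips[hosp_county],
        "climate": np.array(climate_codes)[hosp_climate],
    })

    # climate-share table; a fraction of counties get a secondary share
    rows = []
    mixed = rng.random(K) < sc.mixed_climate_frac
    for k in range(K):
        code = climate_codes[county_climate[k]]
        if mixed[k] and C >= 2:
            other = climate_codes[(county_climate[k] + 1 + int(rng.integers(C - 1))) % C]
            share = float(np.round(rng.uniform(0.10, 0.45), 4))
            rows.append({"fips": fips[k], "koppen_code": code, "proportion": 1.0 - share})
            rows.append({"fips": fips[k], "koppen_code": other, "proportion": share})
        else:
            rows.append({"fips": fips[k], "koppen_code": code, "proportion": 1.0})
    climate_table = pd.DataFrame(rows)

    crosswalk = pd.DataFrame({"zip": zips, "fips": fips[hosp_county]})

    # bookkeeping: expected cohort after the availability and singleton
    # filters (hospitals with every cell suppressed drop first, which
    # can itself empty or singleton a climate)
    hosp_any = available.any(axis=1)
    clim_counts = np.bincount(hosp_climate[hosp_any], minlength=C)
    singleton_climates = np.where(clim_counts == 1)[0]
    keep = hosp_any & ~np.isin(hosp_climate, singleton_climates)
    expected = {
        "n_hospitals": int(keep.sum()),
        "n_climates": int(len(np.unique(hosp_climate[keep]))),
        "n_counties": int(len(np.unique(hosp_county[keep]))),
        "removed_all_suppressed": int((~hosp_any).sum()),
        "removed_singletons": int((hosp_any & np.isin(hosp_climate, singleton_climates)).sum()),
    }

    # the estimand under the pipeline's re-standardization: the model
    # z-scores each covariate by its realized sample sd over hospitals,
    # so the coefficient it estimates is beta_j times that sd
    beta_effective = (np.array(sc.beta, dtype=float)
                      * hosp_z.std(axis=0, ddof=1)) if H >= 2 else np.array(sc.beta)

    truth = {
        "alpha": alpha.tolist(), "gamma": gamma.tolist(),
        "beta": list(sc.beta), "beta_effective": beta_effective.tolist(),
        "sigma_u": sc.sigma_u,
        "measures": list(sc.measures), "climate_codes": climate_codes,
        "u": u.tolist(), "hospital_climate": hosp_climate.tolist(),
        "hospital_county": hosp_county.tolist(), "hospital_z": hosp_z.tolist(),
        "expected_cohort": expected,
    }
    return SyntheticData(scenario=sc, hospitals=hospitals, cells=cells,
                         climate_table=climate_table, acs=acs,
                         crosswalk=crosswalk, truth=truth)


def emit_hospital_compare_csv(
    data: SyntheticData, path: str | Path, dialect: FileDialect = FileDialect(),
) -> None:
    """Write the cells in the Hospital Compare flat-file dialect.

    Scores print with one decimal, as in the real release; suppressed
    cells carry the 'Not Available' sentinel in both the denominator
    and score columns.  The emitted file parses through
    ``read_mortality_file`` with zero rejections and reproduces the
    available counts exactly.
    """
    cells = data.cells.merge(data.hospitals[["provider_id", "zip"]], on="provider_id")
    rate = 100.0 * cells["deaths"] / cells["denominator"]
    avail = cells["available"].to_numpy()
    df = pd.DataFrame({
        dialect.provider_col: cells["provider_id"],
        "Hospital Name": "Hospital " + cells["provider_id"].astype(str),
        dialect.zip_col: cells["zip"],
        dialect.measure_col: cells["measure_id"],
        dialect.denominator_col: np.where(avail, cells["denominator"].astype(str),
                                          dialect.not_available),
        dialect.score_col: np.where(avail, rate.map(lambda r: f"{r:.1f}"),
                                    dialect.not_available),
    })
    df.to_csv(path, index=False)


def emit_all(data: SyntheticData, out_dir: str | Path,
             dialect: FileDialect = FileDialect()) -> dict[str, Path]:
    """Write every table the pipeline ingests plus the ground truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mortality": out / "readmissions_and_deaths.csv",
        "climate": out / "county_climate.csv",
        "acs": out / "acs_confounders.csv",
        "crosswalk": out / "zip_fips_crosswalk.csv",
        "truth": out / "ground_truth.json",
        "scenario": out / "scenario.yaml",
    }
    emit_hospital_compare_csv(data, paths["mortality"], dialect)
    data.climate_table.to_csv(paths["climate"], index=False)
    data.acs.to_csv(paths["acs"], index=False)
    data.crosswalk.to_csv(paths["crosswalk"], index=False)
    paths["truth"].write_text(json.dumps(data.truth, indent=2) + "\n")
    data.scenario.to_file(paths["scenario"])
    return paths
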