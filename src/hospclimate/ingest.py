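"""Hospital Compare ingestion and cohort assembly.

Parses the CMS "Readmissions and Deaths" flat file (one row per
hospital × measure), keeps the six 30-day mortality measures,
reconstructs death counts from the reported percentage score and
denominator, applies the availability and singleton-climate filters,
and assembles the linked analysis cohort.  Every record removed by a
filter is counted in a provenance log so input = output + removals at
each stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .linkage import ConfounderVector, Crosswalk, join_confounders, zip_to_fips

logger = logging.getLogger(__name__)

__all__ = [
    "MeasureObservation",
    "HospitalRecord",
    "Cohort",
    "FileDialect",
    "DEFAULT_MORTALITY_MEASURES",
    "read_mortality_file",
    "filter_unavailable",
    "filter_singleton_climates",
    "cohort_summary",
    "build_cohort",
]

# The six 30-day mortality measures of the 2015 annual release.
DEFAULT_MORTALITY_MEASURES = (
    "MORT_30_AMI",
    "MORT_30_CABG",
    "MORT_30_COPD",
    "MORT_30_HF",
    "MORT_30_PN",
    "MORT_30_STK",
)

# Observed score is a rounded percentage, so the reconstructed rate can
# differ from the printed one by at most half of the printed precision.
RATE_ROUNDING_TOL = 0.05


@dataclass(frozen=True)
class FileDialect:
    """Column names and sentinels of a Hospital Compare flat file."""

    provider_col: str = "Provider ID"
    zip_col: str = "ZIP Code"
    measure_col: str = "Measure ID"
    denominator_col: str = "Denominator"
    score_col: str = "Score"
    not_available: str = "Not Available"
    measure_prefix: str = "MORT_30_"

    def required_columns(self) -> tuple[str, ...]:
        return (self.provider_col, self.zip_col, self.measure_col,
                self.denominator_col, self.score_col)


@dataclass(frozen=True)
class MeasureObservation:
    """One hospital × mortality-measure cell."""

    provider_id: str
    measure_id: str
    deaths: int | None
    denominator: int | None
    rate: float | None
    available: bool

    def __post_init__(self) -> None:
        if self.available:
            if self.deaths is None or self.denominator is None or self.rate is None:
                raise ValueError("available observation must carry deaths, denominator and rate")
            if not 0 <= self.deaths <= self.denominator:
                raise ValueError(
                    f"deaths {self.deaths} outside [0, denominator={self.denominator}]")
            implied = 100.0 * self.deaths / self.denominator
            # Printed scores carry one decimal (±0.05); for small
            # denominators the binding limit is half a death (±50/n).
            tol = max(RATE_ROUNDING_TOL, 50.0 / self.denominator)
            if abs(implied - self.rate) > tol + 1e-9:
                raise ValueError(
                    f"rate {self.rate} inconsistent with {self.deaths}/{self.denominator}")
        else:
            if not (self.deaths is None and self.denominator is None and self.rate is None):
                raise ValueError("unavailable observation must carry no counts")


@dataclass
class HospitalRecord:
    """A hospital with its geographic links and mortality observations."""

    provider_id: str
    zip: str
    fips: str | None = None
    climate: str | None = None
    confounders: ConfounderVector | None = None
    observations: list[MeasureObservation] = field(default_factory=list)

    @property
    def n_available(self) -> int:
        return sum(o.available for o in self.observations)


@dataclass
class Cohort:
    """Linked analysis cohort plus the provenance log of every removal."""

    hospitals: list[HospitalRecord]
    provenance: dict[str, int] = field(default_factory=dict)

    @property
    def n_hospitals(self) -> int:
        return len(self.hospitals)

    @property
    def n_climates(self) -> int:
        return len({h.climate for h in self.hospitals if h.climate is not None})

    @property
    def n_counties(self) -> int:
        return len({h.fips for h in self.hospitals if h.fips is not None})

    def log(self, stage: str, removed: int) -> None:
        self.provenance[stage] = self.provenance.get(stage, 0) + removed
        if removed:
            logger.info("filter %s removed %d record(s)", stage, removed)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per hospital × available measure."""
        rows = []
        for h in self.hospitals:
            conf = h.confounders.as_tuple() if h.confounders else (None,) * 6
            for o in h.observations:
                if not o.available:
                    continue
                rows.append({
                    "provider_id": h.provider_id, "zip": h.zip, "fips": h.fips,
                    "climate": h.climate, "measure_id": o.measure_id,
                    "deaths": o.deaths, "denominator": o.denominator, "rate": o.rate,
                    "income": conf[0], "households": conf[1], "pct_renter": conf[2],
                    "pct_uninsured": conf[3], "pct_english_very_well": conf[4],
                    "pct_white_alone": conf[5],
                })
        return pd.DataFrame(rows)

    def write(self, csv_path: str | Path, provenance_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if provenance_path is not None:
            Path(provenance_path).write_text(json.dumps(self.provenance, indent=2) + "\n")


def _reconstruct_deaths(rate: float, denominator: int) -> int:
    # Score is deaths/denominator in percent; invert with round-to-nearest.
    return int(round(rate * denominator / 100.0))


def read_mortality_file(
    path: str | Path,
    dialect: FileDialect = FileDialect(),
) -> tuple[list[MeasureObservation], pd.DataFrame, int]:
    """Parse a Hospital Compare flat file into mortality observations.

    Keeps only measure IDs starting with the dialect's mortality prefix
    (readmission and complication rows are discarded).  Death counts
    are reconstructed as ``round(score × denominator / 100)``.  Returns
    ``(observations, hospital_metadata, n_rejected_rows)`` where the
    metadata frame holds one ``provider_id``/``zip`` row per hospital
    and rejected rows are malformed-numeric rows, counted and logged.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        return [], pd.DataFrame(columns=["provider_id", "zip"]), 0
    missing = set(dialect.required_columns()) - set(df.columns)
    if missing:
        raise ValueError(f"mortality file missing column(s): {sorted(missing)}")
    if df.empty:
        return [], pd.DataFrame(columns=["provider_id", "zip"]), 0

    df = df[df[dialect.measure_col].str.startswith(dialect.measure_prefix, na=False)]
    observations: list[MeasureObservation] = []
    n_rejected = 0
    meta: dict[str, str] = {}
    cols = [dialect.provider_col, dialect.zip_col, dialect.measure_col,
            dialect.denominator_col, dialect.score_col]
    for provider, zip_code, measure, denom_raw, score_raw in df[cols].itertuples(index=False):
        provider = str(provider).strip()
        zip_code = str(zip_code).strip()
        measure = str(measure).strip()
        meta.setdefault(provider, zip_code)

        score_str = str(score_raw).strip()
        denom_str = str(denom_raw).strip()
        if score_str == dialect.not_available or denom_str == dialect.not_available:
            observations.append(MeasureObservation(
                provider_id=provider, measure_id=measure,
                deaths=None, denominator=None, rate=None, available=False))
            continue
        try:
            rate = float(score_str)
            denominator = int(float(denom_str))
            if denominator <= 0 or not 0.0 <= rate <= 100.0:
                raise ValueError
        except ValueError:
            n_rejected += 1
            logger.warning("rejected malformed row: provider=%s measure=%s score=%r denominator=%r",
                           provider, measure, score_raw, denom_raw)
            continue
        deaths = _reconstruct_deaths(rate, denominator)
        observations.append(MeasureObservation(
            provider_id=provider, measure_id=measure,
            deaths=deaths, denominator=denominator, rate=rate, available=True))

    meta_df = pd.DataFrame({"provider_id": list(meta), "zip": list(meta.values())})
    return observations, meta_df, n_rejected


def filter_unavailable(
    observations: list[MeasureObservation],
) -> tuple[list[MeasureObservation], int]:
    """Drop 'Not Available' cells; returns (kept, n_removed)."""
    kept = [o for o in observations if o.available]
    return kept, len(observations) - len(kept)


def filter_singleton_climates(cohort: Cohort) -> Cohort:
    """Remove hospitals that are alone in their climate.

    A climate represented by a single hospital carries no information
    about climate-level variation and would bias the pooled model, so
    such hospitals are excluded (with a per-climate log count).
    """
    counts: dict[str, int] = {}
    for h in cohort.hospitals:
        counts[h.climate] = counts.get(h.climate, 0) + 1
    singletons = {c for c, n in counts.items() if n == 1}
    kept = [h for h in cohort.hospitals if h.climate not in singletons]
    removed = len(cohort.hospitals) - len(kept)
    out = Cohort(hospitals=kept, provenance=dict(cohort.provenance))
    out.log("singleton_climate", removed)
    for code in sorted(singletons):
        logger.info("removed singleton-climate hospital in %s", code)
    return out


def cohort_summary(cohort: Cohort) -> tuple[int, int, int]:
    """(n_hospitals, n_climates, n_counties) — distinct provider/climate/FIPS counts."""
    return cohort.n_hospitals, cohort.n_climates, cohort.n_counties


def build_cohort(
    mortality_path: str | Path,
    crosswalk: Crosswalk,
    county_climates: dict[str, str],
    acs: pd.DataFrame,
    dialect: FileDialect = FileDialect(),
) -> Cohort:
    """Full assembly: parse → link ZIP→FIPS→climate→confounders → filter.

    Stages, each with a provenance count:

    1. parse the flat file (malformed rows rejected);
    2. drop 'Not Available' cells; hospitals left with zero available
       observations are dropped;
    3. drop hospitals with unmapped ZIPs, counties missing from the
       climate table, or counties missing from the ACS extract;
    4. drop singleton-climate hospitals.
    """
    observations, meta, n_rejected = read_mortality_file(mortality_path, dialect)
    cohort = Cohort(hospitals=[])
    cohort.log("malformed_rows", n_rejected)

    available, n_unavailable = filter_unavailable(observations)
    cohort.log("unavailable_observations", n_unavailable)

    by_provider: dict[str, list[MeasureObservation]] = {}
    for o in available:
        by_provider.setdefault(o.provider_id, []).append(o)

    n_no_obs = n_unmapped_zip = n_no_climate = n_no_acs = 0
    for row in meta.itertuples(index=False):
        provider, zip_code = row.provider_id, row.zip
        obs = sorted(by_provider.get(provider, []), key=lambda o: o.measure_id)
        if not obs:
            n_no_obs += 1
            continue
        fips = zip_to_fips(zip_code, crosswalk)
        if fips is None:
            n_unmapped_zip += 1
            continue
        climate = county_climates.get(fips)
        if climate is None:
            n_no_climate += 1
            continue
        conf = join_confounders(fips, acs)
        if conf is None:
            n_no_acs += 1
            continue
        cohort.hospitals.append(HospitalRecord(
            provider_id=provider, zip=zip_code, fips=fips,
            climate=climate, confounders=conf, observations=obs))

    cohort.log("no_available_observations", n_no_obs)
    cohort.log("unmapped_zip", n_unmapped_zip)
    cohort.log("county_missing_climate", n_no_climate)
    cohort.log("county_missing_acs", n_no_acs)
    cohort.hospitals.sort(key=lambda h: h.provider_id)
    return filter_singleton_climates(cohort)
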