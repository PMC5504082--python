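"""Geographic linkage: hospitals → counties → climates and confounders.

Hospitals carry a ZIP code; counties are identified by 5-digit FIPS
codes.  Linkage resolves ZIPs through a crosswalk table, attaches each
county's dominant Köppen-Geiger climate, and joins the six county-level
socioeconomic confounders (income, households, % renter, % uninsured,
% speaking English very well, % white alone) so that every hospital in
a county shares one confounder vector.  Records that cannot be resolved
are excluded, never imputed, and every exclusion is counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .koppen import dominant_climate

logger = logging.getLogger(__name__)

__all__ = [
    "ConfounderVector",
    "CONFOUNDER_COLUMNS",
    "Crosswalk",
    "load_crosswalk",
    "zip_to_fips",
    "load_climate_table",
    "county_dominant_climates",
    "load_acs",
    "join_confounders",
]

CONFOUNDER_COLUMNS = (
    "income",
    "households",
    "pct_renter",
    "pct_uninsured",
    "pct_english_very_well",
    "pct_white_alone",
)

_PERCENT_COLUMNS = CONFOUNDER_COLUMNS[2:]


@dataclass(frozen=True)
class ConfounderVector:
    """County socioeconomic covariates shared by all hospitals in the county."""

    income: float
    households: float
    pct_renter: float
    pct_uninsured: float
    pct_english_very_well: float
    pct_white_alone: float

    def __post_init__(self) -> None:
        if self.income <= 0:
            raise ValueError(f"income must be positive, got {self.income}")
        if self.households < 0:
            raise ValueError(f"households must be non-negative, got {self.households}")
        for name in _PERCENT_COLUMNS:
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, c) for c in CONFOUNDER_COLUMNS)


def _pad_zip(zip_code: str) -> str:
    z = str(zip_code).strip()
    if not z.isdigit() or len(z) > 5:
        raise ValueError(f"ZIP code must be 1-5 digits, got {zip_code!r}")
    return z.zfill(5)


def _pad_fips(fips: str) -> str:
    f = str(fips).strip()
    if not f.isdigit() or len(f) > 5:
        raise ValueError(f"FIPS code must be 1-5 digits, got {fips!r}")
    return f.zfill(5)


class Crosswalk:
    """ZIP → county FIPS lookup.

    A ZIP straddling county lines appears on several rows; the
    designated primary county is kept (largest ``weight`` when that
    column exists, otherwise the first row) and the ambiguity is
    counted in :attr:`n_ambiguous`.
    """

    def __init__(self, table: pd.DataFrame):
        if not {"zip", "fips"} <= set(table.columns):
            raise ValueError("crosswalk needs 'zip' and 'fips' columns")
        t = table.copy()
        t["zip"] = t["zip"].map(_pad_zip)
        t["fips"] = t["fips"].map(_pad_fips)
        dup = t["zip"].duplicated(keep=False)
        self.n_ambiguous = int(t.loc[dup, "zip"].nunique())
        if self.n_ambiguous:
            logger.info("crosswalk: %d ZIP(s) map to multiple counties; keeping primary", self.n_ambiguous)
        if "weight" in t.columns:
            t = t.sort_values("weight", ascending=False, kind="stable")
        self._map: dict[str, str] = dict(zip(t.drop_duplicates("zip", keep="first")["zip"], t.drop_duplicates("zip", keep="first")["fips"]))

    def __len__(self) -> int:
        return len(self._map)

    def get(self, zip_code: str) -> str | None:
        return self._map.get(_pad_zip(zip_code))


def load_crosswalk(path: str | Path) -> Crosswalk:
    """Read a ZIP→FIPS crosswalk CSV (columns ``zip``, ``fips``, optional ``weight``)."""
    return Crosswalk(pd.read_csv(path, dtype={"zip": str, "fips": str}))


def zip_to_fips(zip_code: str, crosswalk: Crosswalk) -> str | None:
    """Resolve a hospital ZIP to its county FIPS.

    ZIPs shorter than five characters are left-padded with zeros (CSV
    round-trips drop leading zeros).  Returns ``None`` for a ZIP absent
    from the crosswalk; the caller excludes and counts such records.
    """
    return crosswalk.get(zip_code)


def load_climate_table(path: str | Path) -> pd.DataFrame:
    """Read a county climate table CSV (columns ``fips``, ``koppen_code``, ``proportion``)."""
    t = pd.read_csv(path, dtype={"fips": str, "koppen_code": str})
    missing = {"fips", "koppen_code", "proportion"} - set(t.columns)
    if missing:
        raise ValueError(f"climate table missing column(s): {sorted(missing)}")
    t["fips"] = t["fips"].map(_pad_fips)
    return t


def county_dominant_climates(climate_table: pd.DataFrame) -> dict[str, str]:
    """Dominant climate per county from a (fips, koppen_code, proportion) table.

    Counties crossing climate boundaries carry several rows; the code
    with the highest proportion wins (lexicographic tie-break).
    """
    out: dict[str, str] = {}
    for fips, grp in climate_table.groupby("fips", sort=True):
        shares = dict(zip(grp["koppen_code"], grp["proportion"].astype(float)))
        out[str(fips)] = dominant_climate(shares)
    return out


def load_acs(path: str | Path) -> pd.DataFrame:
    """Read an ACS county extract CSV keyed by FIPS with the six confounders."""
    t = pd.read_csv(path, dtype={"fips": str})
    missing = ({"fips"} | set(CONFOUNDER_COLUMNS)) - set(t.columns)
    if missing:
        raise ValueError(f"ACS table missing column(s): {sorted(missing)}")
    t["fips"] = t["fips"].map(_pad_fips)
    if t["fips"].duplicated().any():
        raise ValueError("ACS table has duplicate FIPS rows")
    return t.set_index("fips")


def join_confounders(fips: str, acs: pd.DataFrame) -> ConfounderVector | None:
    """Look up a county's confounder vector; ``None`` when the county is absent.

    All hospitals sharing a county receive the identical vector; absent
    counties are excluded downstream with a logged count.
    """
    f = _pad_fips(fips)
    if f not in acs.index:
        return None
    row = acs.loc[f]
    return ConfounderVector(**{c: float(row[c]) for c in CONFOUNDER_COLUMNS})
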