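"""Köppen-Geiger climate classification.

The Köppen-Geiger system assigns a 2–3 letter code from monthly mean
temperature (°C) and monthly precipitation (mm): a main group (A
equatorial, B arid, C warm temperate, D snow, E polar), a precipitation
letter and, for most groups, a temperature letter.  This module parses
and describes codes, picks the dominant climate of a county that spans
a climate boundary, and classifies raw 12-month series through the
standard threshold cascade so synthetic counties carry internally
consistent climates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClimateClass",
    "CountyClimate",
    "MonthlyClimateSeries",
    "parse_climate_code",
    "dominant_climate",
    "classify_koppen",
    "describe_climate",
]

# Valid letter sets per main group: (precip letters, temp letters, temp required)
_GRAMMAR: dict[str, tuple[frozenset[str], frozenset[str], bool]] = {
    "A": (frozenset("fmsw"), frozenset(), False),
    "B": (frozenset("WS"), frozenset("hk"), True),
    "C": (frozenset("swf"), frozenset("abc"), True),
    "D": (frozenset("swf"), frozenset("abcd"), True),
    "E": (frozenset(), frozenset("TF"), True),
}

_MAIN_NAMES = {
    "A": "equatorial",
    "B": "arid",
    "C": "warm temperate",
    "D": "snow",
    "E": "polar",
}

_PRECIP_NAMES = {
    "f": "fully humid",
    "m": "monsoonal",
    "s": "summer dry",
    "w": "winter dry",
    "W": "desert",
    "S": "steppe",
}

_TEMP_NAMES = {
    "a": "hot summer",
    "b": "warm summer",
    "c": "cool summer",
    "d": "extremely continental",
    "h": "hot arid",
    "k": "cold arid",
    "T": "tundra",
    "F": "frost",
}


@dataclass(frozen=True)
class ClimateClass:
    """A decomposed Köppen-Geiger code, e.g. ``Cfa`` → (C, f, a)."""

    code: str
    main_group: str
    precip_letter: str | None = None
    temp_letter: str | None = None

    def __post_init__(self) -> None:
        recomposed = self.main_group + (self.precip_letter or "") + (self.temp_letter or "")
        if recomposed != self.code:
            raise ValueError(f"components {recomposed!r} do not recompose code {self.code!r}")

    def describe(self) -> str:
        parts = [_MAIN_NAMES[self.main_group]]
        if self.precip_letter:
            parts.append(_PRECIP_NAMES[self.precip_letter])
        if self.temp_letter:
            parts.append(_TEMP_NAMES[self.temp_letter])
        return ", ".join(parts)


def parse_climate_code(code: str) -> ClimateClass:
    """Decompose a Köppen-Geiger code, validating against the letter grammar.

    Raises ``ValueError`` naming the 1-based position of the offending
    character.
    """
    if not isinstance(code, str) or not 2 <= len(code) <= 3:
        raise ValueError(f"climate code must be a 2-3 character string, got {code!r}")
    main = code[0]
    if main not in _GRAMMAR:
        raise ValueError(f"invalid main group {main!r} at position 1 in {code!r}")
    precips, temps, temp_required = _GRAMMAR[main]

    if main == "E":
        if len(code) != 2 or code[1] not in temps:
            raise ValueError(f"invalid polar letter {code[1]!r} at position 2 in {code!r}")
        return ClimateClass(code=code, main_group=main, temp_letter=code[1])

    if code[1] not in precips:
        raise ValueError(f"invalid precipitation letter {code[1]!r} at position 2 in {code!r}")
    precip = code[1]

    if len(code) == 2:
        if temp_required:
            raise ValueError(f"main group {main!r} requires a temperature letter (code {code!r})")
        return ClimateClass(code=code, main_group=main, precip_letter=precip)

    if code[2] not in temps:
        raise ValueError(f"invalid temperature letter {code[2]!r} at position 3 in {code!r}")
    return ClimateClass(code=code, main_group=main, precip_letter=precip, temp_letter=code[2])


def describe_climate(code: str) -> str:
    """Human-readable reading of a code, e.g. Cfa → 'warm temperate, fully humid, hot summer'."""
    return parse_climate_code(code).describe()


def dominant_climate(shares: dict[str, float]) -> str:
    """Return the climate code with the largest within-county share.

    Counties crossing a climate boundary carry several codes with
    proportions; the analysis keeps the dominant one.  Ties are broken
    lexicographically by code so the choice is reproducible.
    """
    if not shares:
        raise ValueError("empty climate-share mapping")
    if any(p < 0 for p in shares.values()):
        raise ValueError("negative climate proportion")
    if all(p == 0 for p in shares.values()):
        raise ValueError("all climate proportions are zero")
    # max proportion; lexicographically smallest code among ties
    return min(shares, key=lambda c: (-shares[c], c))


@dataclass(frozen=True)
class CountyClimate:
    """A county's climate-share table and its dominant code."""

    fips: str
    climate_shares: dict[str, float]
    dominant: str = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.climate_shares.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"county {self.fips}: climate shares sum to {total}, not 1")
        object.__setattr__(self, "dominant", dominant_climate(self.climate_shares))


@dataclass(frozen=True)
class MonthlyClimateSeries:
    """Twelve monthly mean temperatures (°C) and precipitation totals (mm)."""

    temps: tuple[float, ...]
    precips: tuple[float, ...]
    hemisphere: str = "north"

    def __post_init__(self) -> None:
        if len(self.temps) != 12 or len(self.precips) != 12:
            raise ValueError("need exactly 12 monthly temperatures and precipitations")
        if any(p < 0 for p in self.precips):
            raise ValueError("precipitation cannot be negative")
        if self.hemisphere not in ("north", "south"):
            raise ValueError(f"hemisphere must be 'north' or 'south', got {self.hemisphere!r}")


def _season_masks(hemisphere: str) -> tuple[np.ndarray, np.ndarray]:
    # Summer = Apr-Sep in the northern hemisphere, Oct-Mar in the southern.
    months = np.arange(12)
    summer = (months >= 3) & (months <= 8)
    if hemisphere == "south":
        summer = ~summer
    return summer, ~summer


def classify_koppen(series: MonthlyClimateSeries, *, fold_as_into_aw: bool = True) -> ClimateClass:
    """Classify a 12-month series through the standard rule cascade.

    Cascade: polar E first (warmest month below 10 °C), then arid B via
    the dryness threshold, then A/C/D by the coldest month, with
    precipitation (s/w/f) and temperature (a/b/c/d) letters.  With
    ``fold_as_into_aw`` (default) the rare equatorial summer-dry class
    is reported as ``Aw``, the common convention for US county tables.
    """
    t = np.asarray(series.temps, dtype=float)
    p = np.asarray(series.precips, dtype=float)
    summer, winter = _season_masks(series.hemisphere)

    t_max, t_min, t_ann = t.max(), t.min(), t.mean()
    p_ann = p.sum()
    p_summer, p_winter = p[summer].sum(), p[winter].sum()

    # --- polar ---
    if t_max < 10.0:
        return parse_climate_code("ET" if t_max >= 0.0 else "EF")

    # --- arid ---
    # Dryness threshold: 2*Tann, +28 when >=2/3 of precipitation falls in
    # summer, +14 when neither season dominates.
    if p_ann > 0 and p_summer >= (2.0 / 3.0) * p_ann:
        p_th = 2.0 * t_ann + 28.0
    elif p_ann > 0 and p_winter >= (2.0 / 3.0) * p_ann:
        p_th = 2.0 * t_ann
    else:
        p_th = 2.0 * t_ann + 14.0
    if p_ann < 10.0 * p_th:
        second = "W" if p_ann < 5.0 * p_th else "S"
        third = "h" if t_ann >= 18.0 else "k"
        return parse_climate_code("B" + second + third)

    # --- equatorial ---
    if t_min >= 18.0:
        p_min = p.min()
        if p_min >= 60.0:
            return parse_climate_code("Af")
        if p_ann >= 25.0 * (100.0 - p_min):
            return parse_climate_code("Am")
        # dry season placement: winter-dry -> Aw, summer-dry -> As
        if p[winter].min() <= p[summer].min() or fold_as_into_aw:
            return parse_climate_code("Aw")
        return parse_climate_code("As")

    # --- temperate vs continental ---
    main = "C" if t_min > -3.0 else "D"

    ps_min, ps_max = p[summer].min(), p[summer].max()
    pw_min, pw_max = p[winter].min(), p[winter].max()
    if ps_min < pw_min and ps_min < 40.0 and ps_min < pw_max / 3.0:
        precip = "s"
    elif pw_min < ps_min and pw_min < ps_max / 10.0:
        precip = "w"
    else:
        precip = "f"

    if t_max >= 22.0:
        temp = "a"
    elif np.sum(t >= 10.0) >= 4:
        temp = "b"
    elif main == "D" and t_min <= -38.0:
        temp = "d"
    else:
        temp = "c"
    return parse_climate_code(main + precip + temp)
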