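"""Classify monthly climate series into Köppen-Geiger codes.

Builds a New-York-like monthly series, classifies it through the
standard threshold cascade, and shows how county-level climate shares
resolve to a dominant climate.
"""

from hospclimate import describe_climate, dominant_climate, parse_climate_code
from hospclimate.koppen import MonthlyClimateSeries, classify_koppen

nyc_like = MonthlyClimateSeries(
    temps=(0, 1, 5, 11, 17, 22, 25, 24, 20, 14, 8, 2),       # °C
    precips=(90, 80, 100, 100, 95, 95, 110, 100, 90, 85, 95, 90),  # mm
)
cls = classify_koppen(nyc_like)
print(f"NYC-like series classifies as {cls.code}: {describe_climate(cls.code)}")

# a county straddling a climate boundary keeps its dominant climate
shares = {"Cfa": 0.6, "Dfa": 0.4}
print(f"county shares {shares} -> dominant {dominant_climate(shares)}")

ice_cap = classify_koppen(MonthlyClimateSeries(temps=(-20,) * 12, precips=(20,) * 12))
print(f"all months at -20 °C -> {ice_cap.code} ({describe_climate(ice_cap.code)})")

c = parse_climate_code("BWk")
print(f"'BWk' decomposes into main={c.main_group} precip={c.precip_letter} "
      f"temp={c.temp_letter}: {c.describe()}")
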