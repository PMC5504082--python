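"""Within-climate performance benchmarking.

A hospital in a harsh climate can post a high 30-day mortality rate
without delivering worse care: part of the rate is the climate, not the
hospital.  The proposed adjustment scores each hospital against the
pooled rate of its climate peers rather than the national rate.  The
default expectation is the denominator-weighted pooled rate
(Σ deaths / Σ denominators), so the climate benchmark is the rate a
patient-weighted average hospital in that climate would post and the
weighted mean excess within every climate is zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import Cohort

__all__ = [
    "AdjustedScore",
    "within_climate_expected",
    "national_expected",
    "score_hospitals",
]

MIN_PEERS_DEFAULT = 5


@dataclass(frozen=True)
class AdjustedScore:
    provider_id: str
    measure_id: str
    climate: str
    observed: float            # percent
    expected_climate: float    # percent
    expected_national: float   # percent
    excess: float              # observed - expected_climate, percentage points
    excess_national: float
    percentile: float | None   # within-climate midrank percentile, [0, 100]
    peers: int


def _measure_frame(cohort: Cohort, measure: str) -> pd.DataFrame:
    df = cohort.to_frame()
    if df.empty:
        raise ValueError("empty cohort")
    df = df[df["measure_id"] == measure].copy()
    if df.empty:
        raise ValueError(f"no available observations for measure {measure!r}")
    # exact rate from counts; the printed score is rounded to 0.1 and
    # would break the zero-mean-excess identity
    df["rate"] = 100.0 * df["deaths"] / df["denominator"]
    return df


def within_climate_expected(cohort: Cohort, measure: str, *, weighted: bool = True) -> pd.Series:
    """Expected (benchmark) rate per climate for one measure, in percent.

    Default is the denominator-weighted pooled rate
    ``100 * sum(deaths) / sum(denominators)``; ``weighted=False`` gives
    the unweighted mean of hospital rates instead.  A climate with zero
    total denominator has no defined benchmark and is omitted.
    """
    df = _measure_frame(cohort, measure)
    if weighted:
        g = df.groupby("climate")
        denom = g["denominator"].sum()
        out = 100.0 * g["deaths"].sum() / denom
        out = out[denom > 0]
    else:
        out = df.groupby("climate")["rate"].mean()
    out.name = "expected_rate"
    return out


def national_expected(cohort: Cohort, measure: str, *, weighted: bool = True) -> float:
    """National benchmark rate for one measure, in percent."""
    df = _measure_frame(cohort, measure)
    if weighted:
        return float(100.0 * df["deaths"].sum() / df["denominator"].sum())
    return float(df["rate"].mean())


def _midrank_percentiles(rates: np.ndarray) -> np.ndarray:
    # midrank percentile: average rank among peers, mapped to [0, 100]
    order = pd.Series(rates).rank(method="average")
    return (100.0 * (order - 0.5) / len(rates)).to_numpy()


def score_hospitals(
    cohort: Cohort,
    measure: str,
    *,
    weighted: bool = True,
    min_peers: int = MIN_PEERS_DEFAULT,
) -> list[AdjustedScore]:
    """Score every hospital on one measure against its climate peers.

    ``excess`` is observed minus the within-climate expectation in
    percentage points; the national comparison is included for
    contrast.  Percentiles use the midrank convention (lower rate →
    lower percentile → better) and are suppressed when a climate has
    fewer than ``min_peers`` hospitals.
    """
    df = _measure_frame(cohort, measure).sort_values("provider_id")
    expected = within_climate_expected(cohort, measure, weighted=weighted)
    nat = national_expected(cohort, measure, weighted=weighted)

    scores: list[AdjustedScore] = []
    for climate, grp in df.groupby("climate", sort=True):
        exp_rate = float(expected[climate]) if climate in expected.index else float("nan")
        peers = len(grp)
        pcts = _midrank_percentiles(grp["rate"].to_numpy()) if peers >= min_peers else None
        for i, row in enumerate(grp.itertuples(index=False)):
            scores.append(AdjustedScore(
                provider_id=row.provider_id, measure_id=measure, climate=climate,
                observed=float(row.rate), expected_climate=exp_rate,
                expected_national=nat,
                excess=float(row.rate) - exp_rate,
                excess_national=float(row.rate) - nat,
                percentile=float(pcts[i]) if pcts is not None else None,
                peers=peers))
    scores.sort(key=lambda s: s.provider_id)
    return scores


def scores_frame(scores: list[AdjustedScore]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in scores])
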