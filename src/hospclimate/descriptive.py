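"""Per-climate summaries and one-way F-tests.

Before any modelling, the analysis asks whether each mortality measure
and each socioeconomic confounder varies across climates at all.  The
one-way F statistic compares between-climate to within-climate
variance; it is computed from explicit sums of squares so a brute-force
oracle can verify it digit-for-digit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupSummary", "FTestResult", "group_summaries", "summaries_frame",
           "oneway_f_test"]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float | None  # absent for singleton groups
    se: float | None

    def as_dict(self) -> dict:
        return {"group": self.group, "n": self.n, "mean": self.mean,
                "sd": self.sd, "se": self.se}


@dataclass(frozen=True)
class FTestResult:
    F: float
    df_between: int
    df_within: int
    p: float


def group_summaries(values, groups) -> list[GroupSummary]:
    """Mean/sd/se per group plus an ``__overall__`` row.

    Sample sd (n−1 denominator); se = sd/√n; both absent for groups of
    one.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.size == 0:
        raise ValueError("empty input")
    if v.shape != g.shape:
        raise ValueError("values and groups must have equal length")

    def summarize(label: str, x: np.ndarray) -> GroupSummary:
        if x.size >= 2:
            sd = float(np.std(x, ddof=1))
            return GroupSummary(label, int(x.size), float(x.mean()), sd, sd / np.sqrt(x.size))
        return GroupSummary(label, int(x.size), float(x.mean()), None, None)

    out = [summarize(str(label), v[g == label]) for label in sorted(np.unique(g).tolist())]
    out.append(summarize("__overall__", v))
    return out


def summaries_frame(values, groups) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in group_summaries(values, groups)])


def oneway_f_test(values, groups, *, weights=None) -> FTestResult:
    """One-way analysis-of-variance F-test of group-mean equality.

    F = (SSB/(k−1)) / (SSW/(N−k)) with k groups and N observations;
    the p-value comes from the F(k−1, N−k) distribution.  ``weights``
    (optional, e.g. measure denominators) computes the weighted
    analogue with the same degrees of freedom.  Zero within-group
    variance together with zero between-group variance is degenerate
    and raises.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values and groups must have equal length")
    labels = np.unique(g)
    k, n = len(labels), v.size
    if k < 2:
        raise ValueError(f"need at least 2 groups, got {k}")
    if n <= k:
        raise ValueError(f"need more observations ({n}) than groups ({k})")
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    grand = np.average(v, weights=w)
    ssb = ssw = 0.0
    for label in labels:
        mask = g == label
        gm = np.average(v[mask], weights=w[mask])
        ssb += w[mask].sum() * (gm - grand) ** 2
        ssw += float(np.sum(w[mask] * (v[mask] - gm) ** 2))
    if weights is not None:
        # keep the F statistic scale-free in the weights
        scale = n / w.sum()
        ssb, ssw = ssb * scale, ssw * scale

    df_b, df_w = k - 1, n - k
    if ssw == 0.0 and ssb == 0.0:
        raise ValueError("all values identical: F statistic undefined")
    if ssw == 0.0:
        return FTestResult(F=float("inf"), df_between=df_b, df_within=df_w, p=0.0)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return FTestResult(F=float(f), df_between=df_b, df_within=df_w, p=p)
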