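"""Quartile-stratified survival analysis of marker expression.

Patients are scored by the average expression of the three basal marker
genes (probe-level values averaged per gene first), trichotomized into
lower-quartile ('low') and upper-quartile ('high') strata with the middle
half excluded, and compared by Kaplan-Meier estimation, the two-group
log-rank test, and the log-rank O/E hazard-ratio estimator
HR = (O1/E1)/(O2/E2) with CI exp(log HR +/- 1.96*sqrt(1/E1 + 1/E2)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "average_gene_expression",
    "trichotomize",
    "StrataAssignment",
    "km_estimate",
    "KMCurve",
    "logrank",
    "hazard_ratio",
    "HazardRatioResult",
]


# ---------------------------------------------------------------------------
# expression scoring and stratification
# ---------------------------------------------------------------------------

def average_gene_expression(
    table: pd.DataFrame,
    genes: Sequence[str],
    probe_map: Optional[Dict[str, Sequence[str]]] = None,
) -> pd.Series:
    """Per-patient mean marker expression: probes averaged within each gene
    first, then an unweighted mean across genes."""
    gene_values = []
    for g in genes:
        cols = list(probe_map.get(g, [g])) if probe_map else [g]
        missing = [c for c in cols if c not in table.columns]
        if missing or not cols:
            raise ValueError(f"gene {g!r} has no expression columns in the table")
        gene_values.append(table[cols].mean(axis=1))
    out = pd.concat(gene_values, axis=1).mean(axis=1)
    out.name = "mean_expression"
    return out


@dataclass
class StrataAssignment:
    strata: pd.Series  # 'low' | 'high' | 'excluded'
    rule: str  # 'quartile_trichotomy' | 'mean_split'
    thresholds: Tuple[float, ...]

    def counts(self) -> Dict[str, int]:
        return self.strata.value_counts().to_dict()


def trichotomize(values: pd.Series, rule: str = "quartile_trichotomy") -> StrataAssignment:
    """Stratify patients by expression.

    ``quartile_trichotomy`` (default): low = values <= Q1, high = values >=
    Q3 (linear-interpolation quartiles), the intermediate half excluded.
    ``mean_split``: low/high around the mean, nobody excluded.
    """
    x = values.astype(float)
    if rule == "mean_split":
        m = float(x.mean())
        strata = pd.Series(
            np.where(x > m, "high", "low"), index=values.index, name="stratum"
        )
        return StrataAssignment(strata, rule, (m,))
    if rule != "quartile_trichotomy":
        raise ValueError(f"unknown stratification rule {rule!r}")
    if len(x) < 8:
        raise ValueError("need at least 8 patients for a quartile split")
    q1, q3 = np.quantile(x, [0.25, 0.75])  # linear interpolation
    if q1 == q3:
        raise ValueError("Q1 equals Q3; no expression contrast to stratify on")
    strata = pd.Series("excluded", index=values.index, name="stratum", dtype=object)
    strata[x <= q1] = "low"
    strata[x >= q3] = "high"
    return StrataAssignment(strata, rule, (float(q1), float(q3)))


# ---------------------------------------------------------------------------
# Kaplan-Meier estimation
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def km_estimate(time: pd.Series, event: pd.Series) -> KMCurve:
    """Product-limit survival curve with at-risk counts at each event time."""
    if len(time) == 0:
        raise ValueError("empty stratum")
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int))
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
    )
    return KMCurve(times=times, survival=surv, at_risk=at_risk)


# ---------------------------------------------------------------------------
# log-rank test and hazard ratio
# ---------------------------------------------------------------------------

def _logrank_table(
    time: np.ndarray, event: np.ndarray, in_group1: np.ndarray
) -> Tuple[float, float, float, float, float]:
    """Event-by-event log-rank tally.

    Returns (O1, E1, O2, E2, V): observed and hypergeometric-expected events
    in each group and the variance of O1 - E1.
    """
    order = np.argsort(time, kind="stable")
    time, event, in_group1 = time[order], event[order], in_group1[order]
    o1 = e1 = o2 = e2 = v = 0.0
    event_times = np.unique(time[event == 1])
    for t in event_times:
        at_risk = time >= t
        n = float(at_risk.sum())
        n1 = float((at_risk & in_group1).sum())
        dead = (time == t) & (event == 1)
        d = float(dead.sum())
        d1 = float((dead & in_group1).sum())
        o1 += d1
        o2 += d - d1
        e1 += d * n1 / n
        e2 += d * (n - n1) / n
        if n > 1:
            v += d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1.0)
    return o1, e1, o2, e2, v


def _extract(table: pd.DataFrame, strata: StrataAssignment | pd.Series):
    s = strata.strata if isinstance(strata, StrataAssignment) else strata
    s = s.reindex(table.index)
    keep = s.isin(["low", "high"])
    t = table.loc[keep, "time_months"].to_numpy(dtype=float)
    e = table.loc[keep, "event"].to_numpy(dtype=int)
    g1 = (s[keep] == "high").to_numpy()  # group 1 = high stratum
    if g1.all() or not g1.any():
        raise ValueError("both strata need at least one subject")
    return t, e, g1


def logrank(table: pd.DataFrame, strata: StrataAssignment | pd.Series) -> Tuple[float, float]:
    """Two-group log-rank test: chi-square = (O1 - E1)^2 / V, p from a
    1-df chi-square distribution.  No events (zero variance) gives p = 1."""
    t, e, g1 = _extract(table, strata)
    o1, e1, _, _, v = _logrank_table(t, e, g1)
    if v == 0.0:
        return 0.0, 1.0
    chi2 = (o1 - e1) ** 2 / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    o1: float
    e1: float
    o2: float
    e2: float


def hazard_ratio(
    table: pd.DataFrame, strata: StrataAssignment | pd.Series
) -> HazardRatioResult:
    """Log-rank O/E hazard-ratio estimator for high vs low expression.

    HR = (O1/E1)/(O2/E2) with group 1 the high stratum; the 95% CI is
    exp(log HR +/- 1.96*sqrt(1/E1 + 1/E2)).  A group with zero observed or
    expected events yields an infinite/undefined estimate (returned as inf
    or nan rather than raising).
    """
    t, e, g1 = _extract(table, strata)
    o1, e1, o2, e2, _ = _logrank_table(t, e, g1)
    if e1 == 0.0 or e2 == 0.0:
        return HazardRatioResult(float("nan"), float("nan"), float("nan"), o1, e1, o2, e2)
    if o2 == 0.0:
        return HazardRatioResult(float("inf"), float("nan"), float("inf"), o1, e1, o2, e2)
    hr = (o1 / e1) / (o2 / e2)
    se = np.sqrt(1.0 / e1 + 1.0 / e2)
    if hr == 0.0:
        return HazardRatioResult(0.0, 0.0, float("nan"), o1, e1, o2, e2)
    return HazardRatioResult(
        hr=float(hr),
        ci_low=float(hr * np.exp(-1.96 * se)),
        ci_high=float(hr * np.exp(1.96 * se)),
        o1=o1, e1=e1, o2=o2, e2=e2,
    )
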