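"""Drug-screen analysis and dose-response fitting.

Covers the screening arm of the pipeline: plate-level viability
normalisation, per-compound group means over tB/nB cell lines, the
selective-hit rule (mean tB viability < 20% while mean nB viability > 20%),
the composite tB marker score used to stratify cell lines, marker-versus-
sensitivity Pearson correlation, and four-parameter logistic (4PL) IC50
fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy

from .config import TB_MARKER_GENES

__all__ = [
    "normalize_viability",
    "group_mean_viability",
    "call_selective_hits",
    "composite_tb_score",
    "stratify_cell_lines",
    "correlate_marker_sensitivity",
    "CorrelationResult",
    "DoseResponseFit",
    "fit_four_pl",
    "HIT_VIABILITY_THRESHOLD",
]

#: Decision boundary of the selective-hit rule, in percent viability.
HIT_VIABILITY_THRESHOLD = 20.0


# ---------------------------------------------------------------------------
# normalisation and hit calling
# ---------------------------------------------------------------------------

def normalize_viability(
    wells: np.ndarray | pd.Series, control_wells: Sequence[float], blank: float = 0.0
) -> np.ndarray:
    """Percent viability from raw absorbance:
    ``100 * (well - blank) / (mean(controls) - blank)``, clipped at 0
    (not capped above 100)."""
    controls = np.asarray(control_wells, dtype=float)
    if controls.size == 0:
        raise ValueError("need at least one vehicle-control well")
    denom = controls.mean() - blank
    if denom <= 0:
        raise ValueError("control mean does not exceed blank; plate unusable")
    v = 100.0 * (np.asarray(wells, dtype=float) - blank) / denom
    return np.clip(v, 0.0, None)


def group_mean_viability(
    screen: pd.DataFrame, line_groups: pd.Series
) -> pd.DataFrame:
    """Per-compound arithmetic mean viability within each cell-line group.

    Compounds with any missing viability value are flagged (``complete`` is
    False) and are excluded from hit calling downstream.
    """
    groups = line_groups.reindex(screen.columns)
    if groups.isna().any():
        raise ValueError("every cell line needs a group label")
    out = pd.DataFrame(index=screen.index)
    for g in ("tB", "nB"):
        cols = screen.columns[groups == g]
        if len(cols) == 0:
            raise ValueError(f"group {g!r} has no cell lines")
        out[f"mean_{g}_viability"] = screen[cols].mean(axis=1)
    out["complete"] = screen.notna().all(axis=1)
    return out


def call_selective_hits(means: pd.DataFrame) -> pd.DataFrame:
    """Selective-cytotoxicity hit calls from group-mean viabilities.

    A compound is a hit when it suppresses the tB group below 20% mean
    viability (an over-80% reduction) while the nB group stays strictly
    above 20%.  Both inequalities are strict; incomplete compounds are
    never hits.
    """
    out = means.copy()
    complete = means["complete"] if "complete" in means else pd.Series(True, index=means.index)
    out["is_hit"] = (
        (means["mean_tB_viability"] < HIT_VIABILITY_THRESHOLD)
        & (means["mean_nB_viability"] > HIT_VIABILITY_THRESHOLD)
        & complete
    )
    return out


# ---------------------------------------------------------------------------
# cell-line stratification
# ---------------------------------------------------------------------------

def _zscore_panel(panel: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    missing = [g for g in genes if g not in panel.columns]
    if missing:
        raise ValueError(f"marker gene(s) missing from panel: {', '.join(missing)}")
    z = pd.DataFrame(index=panel.index)
    for g in genes:
        x = panel[g].to_numpy(dtype=float)
        sd = x.std(ddof=0)  # population sd; zero-variance genes score 0
        z[g] = (x - x.mean()) / sd if sd > 0 else 0.0
    return z


def composite_tb_score(
    panel: pd.DataFrame, genes: Sequence[str] = TB_MARKER_GENES
) -> pd.Series:
    """Composite tB marker score: the mean of the per-gene z-scores (across
    cell lines, population sd) of the three marker genes."""
    if len(panel) < 2:
        raise ValueError("need at least 2 cell lines")
    z = _zscore_panel(panel, genes)
    score = z.mean(axis=1)
    score.name = "composite_tb_score"
    return score


def stratify_cell_lines(
    panel: pd.DataFrame,
    genes: Sequence[str] = TB_MARKER_GENES,
    scores: Optional[pd.Series] = None,
) -> pd.Series:
    """tB/nB cell-line labels from complete-linkage Euclidean clustering of
    the z-scored marker matrix (2-cut); the cluster with the higher mean
    composite score is labeled tB."""
    if len(panel) < 2:
        raise ValueError("need at least 2 cell lines")
    z = _zscore_panel(panel, genes)
    if scores is None:
        scores = z.mean(axis=1)
    values = z.to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        out = pd.Series("nB", index=panel.index, name="group")
        out.attrs["degenerate"] = True
        return out
    Z = hierarchy.linkage(values, method="complete", metric="euclidean")
    cut = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    means = {c: scores.to_numpy()[cut == c].mean() for c in np.unique(cut)}
    tb_cluster = max(means, key=means.get)
    out = pd.Series(
        np.where(cut == tb_cluster, "tB", "nB"), index=panel.index, name="group"
    )
    out.attrs["degenerate"] = False
    return out


# ---------------------------------------------------------------------------
# marker-sensitivity correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    x_grid: np.ndarray
    fit: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


def correlate_marker_sensitivity(
    expression: np.ndarray | pd.Series,
    sensitivity: np.ndarray | pd.Series,
    n_grid: int = 100,
) -> CorrelationResult:
    """Pearson correlation of marker expression against drug sensitivity,
    with the least-squares fit line and a pointwise 95% confidence band.

    The p-value comes from the t transform of r with n-2 degrees of freedom.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(sensitivity, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    s2 = (resid**2).sum() / (n - 2)
    sxx = ((x - x.mean()) ** 2).sum()
    grid = np.linspace(x.min(), x.max(), n_grid)
    fit = slope * grid + intercept
    half = stats.t.ppf(0.975, n - 2) * np.sqrt(s2 * (1.0 / n + (grid - x.mean()) ** 2 / sxx))
    return CorrelationResult(float(r), float(p), float(slope), float(intercept),
                             grid, fit, fit - half, fit + half)


# ---------------------------------------------------------------------------
# 4PL dose-response fitting
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool
    no_fit: bool = False

    def predict(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (dose / self.ic50) ** self.hill
        )


def fit_four_pl(
    doses: np.ndarray | pd.Series, viability: np.ndarray | pd.Series
) -> DoseResponseFit:
    """Bounded least-squares fit of the four-parameter logistic
    ``v(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill)``.

    The IC50 is fitted on the log10-dose scale to keep it identifiable;
    bounds keep 0 <= bottom, top <= 120 and the IC50 within one decade of
    the tested dose range.  Initialisation: top = max(v), bottom = min(v),
    IC50 at the dose closest to the half-maximal response, hill = 1.
    Near-flat data (response range below 10 percentage points) returns a
    ``no_fit`` flag rather than a spurious IC50.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viability, dtype=float)
    ok = ~(np.isnan(d) | np.isnan(v))
    d, v = d[ok], v[ok]
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    if len(np.unique(d)) < 5:
        raise ValueError("need at least 5 distinct doses")
    if np.ptp(v) < 10.0:
        return DoseResponseFit(
            float(v.max()), float(v.min()), float("nan"), float("nan"),
            float("nan"), converged=False, no_fit=True,
        )

    logd = np.log10(d)
    top0, bot0 = float(v.max()), float(v.min())
    half = (top0 + bot0) / 2.0
    lic0 = float(logd[np.argmin(np.abs(v - half))])

    def model(params, logd):
        top, bottom, lic50, hill = params
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logd - lic50)))

    def resid(params):
        return model(params, logd) - v

    lo = [0.0, 0.0, logd.min() - 1.0, 0.05]
    hi = [120.0, 120.0, logd.max() + 1.0, 10.0]
    x0 = np.clip([top0, bot0, lic0, 1.0], lo, hi)
    sol = optimize.least_squares(
        resid, x0, bounds=(lo, hi), ftol=1e-8, xtol=1e-10, gtol=1e-10
    )
    top, bottom, lic50, hill = sol.x
    if bottom > top:  # degenerate orientation: swap and flip the slope
        top, bottom, hill = bottom, top, -hill
    return DoseResponseFit(
        top=float(top),
        bottom=float(bottom),
        ic50=float(10.0**lic50),
        hill=float(hill),
        rss=float(2.0 * sol.cost),
        converged=bool(sol.success),
    )
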