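"""Tumor cohort stratification from IHC marker %-positive tables.

A cohort is a samples x markers table of percent-positive tumor cells
(0-100).  Two independent routes classify each tumor as tB (true-basal) or
nB (non-basal):

* unsupervised hierarchical clustering of the raw percentages (Euclidean
  distance, complete linkage, 2-cut);
* per-marker positivity cutoffs placed at the valley of each marker's
  bimodal distribution, combined by a k-of-n rule (default: at least 2 of
  the 3 markers above their cutoffs).

Concordance, per-marker ROC/AUC and subtype prevalence quantify the
agreement and discriminatory power of the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "CutoffEntry",
    "CutoffSet",
    "cluster_cohort",
    "derive_cutoff",
    "derive_cutoffs",
    "classify_samples",
    "concordance",
    "marker_auc",
    "prevalence",
    "mean_center_cluster",
]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_cohort(cohort: pd.DataFrame, n_clusters: int = 2) -> pd.Series:
    """Agglomerative clustering of samples on raw marker percentages
    (Euclidean distance, complete linkage, tree cut at ``n_clusters``).

    With the default 2-cut, the cluster with the higher mean marker
    percentage is labeled ``tB`` and the other ``nB``; otherwise numeric
    cluster labels are returned.  All-identical samples are flagged
    degenerate via the series ``attrs``.
    """
    if n_clusters > len(cohort):
        raise ValueError("more clusters requested than samples")
    if cohort.isna().any().any():
        raise ValueError("cohort contains missing values")
    values = cohort.to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        out = pd.Series("nB", index=cohort.index, name="cluster")
        out.attrs["degenerate"] = True
        return out
    Z = hierarchy.linkage(values, method="complete", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    out = pd.Series(labels, index=cohort.index, name="cluster")
    out.attrs["degenerate"] = False
    if n_clusters == 2:
        means = {c: values[labels == c].mean() for c in np.unique(labels)}
        tb_cluster = max(means, key=means.get)
        out = out.map(lambda c: "tB" if c == tb_cluster else "nB")
        out.name = "cluster"
    return out


# ---------------------------------------------------------------------------
# valley cutoffs
# ---------------------------------------------------------------------------

@dataclass
class CutoffEntry:
    """Positivity threshold for one marker with its derivation provenance."""

    cutoff: Optional[float]
    valley_density: Optional[float]
    peaks: List[float]
    bandwidth: float
    flag: str  # 'bimodal' | 'unimodal' | 'degenerate'


@dataclass
class CutoffSet:
    entries: Dict[str, CutoffEntry] = field(default_factory=dict)

    def __getitem__(self, marker: str) -> CutoffEntry:
        return self.entries[marker]

    def cutoffs(self) -> Dict[str, Optional[float]]:
        return {m: e.cutoff for m, e in self.entries.items()}

    def to_dict(self) -> dict:
        return {
            m: {
                "cutoff": e.cutoff,
                "valley_density": e.valley_density,
                "peaks": e.peaks,
                "bandwidth": e.bandwidth,
                "flag": e.flag,
            }
            for m, e in self.entries.items()
        }

    @classmethod
    def fixed(cls, cutoffs: Dict[str, float]) -> "CutoffSet":
        """Cutoff set from externally supplied thresholds (no KDE provenance)."""
        return cls(
            {
                m: CutoffEntry(float(c), None, [], float("nan"), "fixed")
                for m, c in cutoffs.items()
            }
        )


def _silverman_bw(x: np.ndarray) -> float:
    """Silverman's factor on the sample standard deviation (scipy's rule)."""
    return float(x.std(ddof=1) * (3.0 * len(x) / 4.0) ** (-0.2))


def _nrd0_bw(x: np.ndarray) -> float:
    """Silverman's robust rule of thumb 0.9*min(sd, IQR/1.34)*n^(-1/5)."""
    s = x.std(ddof=1)
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    sig = min(s, iqr / 1.34) if iqr > 0 else s
    return float(0.9 * (sig if sig > 0 else s) * len(x) ** (-0.2))


def _reflected_kde(values: np.ndarray, grid: np.ndarray, bw) -> np.ndarray:
    """Gaussian KDE on [0, 100] with boundary reflection at 0 and 100.

    ``bw`` is either a scalar bandwidth (data units) or a per-observation
    bandwidth array (variable-bandwidth estimate).
    """
    h = np.broadcast_to(np.asarray(bw, dtype=float), values.shape)[None, :]
    x = values[None, :]
    g = grid[:, None]
    dens = (
        np.exp(-0.5 * ((g - x) / h) ** 2)
        + np.exp(-0.5 * ((-g - x) / h) ** 2)
        + np.exp(-0.5 * ((200.0 - g - x) / h) ** 2)
    )
    return (dens / (h * np.sqrt(2.0 * np.pi))).mean(axis=1)


def _best_valley(
    dens: np.ndarray, values: np.ndarray, grid: np.ndarray, min_side_frac: float
) -> Optional[int]:
    """Grid index of the most pronounced density valley.

    Candidate minima lie strictly between the outermost local maxima and
    must leave at least ``min_side_frac`` of the observations on each side
    (a subtype-defining split separates two substantial groups, which also
    rejects dips next to outlier micro-peaks or a clipped boundary mass).
    Among candidates the winner maximises the relative depth
    ``1 - density / min(highest peak left, highest peak right)``; exact
    density ties resolve to the midpoint of the tied plateau.
    """
    padded = np.concatenate([[-np.inf], dens, [-np.inf]])
    rising = padded[1:-1] > padded[:-2]
    falling = padded[1:-1] > padded[2:]
    maxima = np.flatnonzero(rising & falling)
    if len(maxima) < 2:
        return None
    lmax = np.maximum.accumulate(dens)
    rmax = np.maximum.accumulate(dens[::-1])[::-1]
    lo_frac_at = np.searchsorted(np.sort(values), grid, side="right") / len(values)
    best_score, best = -np.inf, None
    for m in range(maxima[0] + 1, maxima[-1]):
        if padded[m + 1] > padded[m] or padded[m + 1] > padded[m + 2]:
            continue  # not a local minimum
        if not min_side_frac <= lo_frac_at[m] <= 1.0 - min_side_frac:
            continue
        ref = min(lmax[m], rmax[m])
        if ref <= 0:
            continue
        score = 1.0 - dens[m] / ref
        if score > best_score + 1e-12:
            best_score, best = score, m
    if best is None:
        return None
    lo = hi = best
    while lo - 1 > 0 and dens[lo - 1] == dens[best]:
        lo -= 1
    while hi + 1 < len(dens) and dens[hi + 1] == dens[best]:
        hi += 1
    return (lo + hi) // 2


def derive_cutoff(
    values: np.ndarray | pd.Series,
    grid_step: float = 0.5,
    min_values: int = 20,
    min_side_frac: float = 0.10,
) -> CutoffEntry:
    """Valley positivity cutoff for one marker's %-positive distribution.

    Two-pass kernel density estimate on [0, 100] (boundary reflection,
    density evaluated on a grid of step ``grid_step``):

    1. pilot pass with a single Silverman bandwidth to locate a first
       valley; a density with fewer than two local maxima is flagged
       ``unimodal`` and carries no cutoff;
    2. refinement pass with a variable bandwidth — observations on each
       side of the pilot valley get that side's robust Silverman (nrd0)
       bandwidth — so a narrow negative mode is not over-smoothed against
       a broad positive mode, which would bias the valley toward the
       wider mode.

    The cutoff is the grid point of the most pronounced valley (see
    :func:`_best_valley`); reported peaks are the density maxima on each
    side of it, so the cutoff lies strictly between them.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < min_values:
        raise ValueError(f"need at least {min_values} values to derive a cutoff")
    if np.ptp(values) == 0:
        return CutoffEntry(None, None, [float(values[0])], float("nan"), "degenerate")
    grid = np.arange(0.0, 100.0 + grid_step / 2, grid_step)

    bw0 = _silverman_bw(values)
    dens = _reflected_kde(values, grid, bw0)
    idx = _best_valley(dens, values, grid, min_side_frac)
    if idx is None:
        peaks = [float(grid[int(np.argmax(dens))])]
        return CutoffEntry(None, None, peaks, bw0, "unimodal")
    bw_used = bw0

    low = values[values <= grid[idx]]
    high = values[values > grid[idx]]
    if min(len(low), len(high)) >= 5:
        bw_lo, bw_hi = _nrd0_bw(low), _nrd0_bw(high)
        if min(bw_lo, bw_hi) > grid_step / 2:  # skip degenerate point masses
            h = np.where(values <= grid[idx], bw_lo, bw_hi)
            dens2 = _reflected_kde(values, grid, h)
            idx2 = _best_valley(dens2, values, grid, min_side_frac)
            if idx2 is not None:
                dens, idx = dens2, idx2
                bw_used = 0.5 * (bw_lo + bw_hi)

    left_peak = int(np.argmax(dens[:idx]))
    right_peak = idx + 1 + int(np.argmax(dens[idx + 1 :]))
    return CutoffEntry(
        cutoff=float(grid[idx]),
        valley_density=float(dens[idx]),
        peaks=[float(grid[left_peak]), float(grid[right_peak])],
        bandwidth=float(bw_used),
        flag="bimodal",
    )


def derive_cutoffs(
    cohort: pd.DataFrame, markers: Optional[List[str]] = None, **kwargs
) -> CutoffSet:
    """Valley cutoff per marker column of the cohort table."""
    markers = list(cohort.columns) if markers is None else markers
    return CutoffSet({m: derive_cutoff(cohort[m], **kwargs) for m in markers})


# ---------------------------------------------------------------------------
# classification and agreement
# ---------------------------------------------------------------------------

def classify_samples(
    cohort: pd.DataFrame, cutoffs: CutoffSet, k: int = 2
) -> pd.DataFrame:
    """k-of-n positivity calls: a marker is positive when its value is
    strictly greater than its cutoff; a sample is ``tB`` when at least
    ``k`` markers are positive.

    Returns per-marker positivity booleans, ``n_markers_positive`` and the
    ``label`` column.
    """
    markers = [m for m in cohort.columns if m in cutoffs.entries]
    if not 1 <= k <= len(markers):
        raise ValueError("k must lie between 1 and the number of markers")
    calls = pd.DataFrame(index=cohort.index)
    for m in markers:
        entry = cutoffs[m]
        if entry.cutoff is None:
            raise ValueError(f"no cutoff available for marker {m!r}")
        calls[f"{m}_positive"] = cohort[m] > entry.cutoff
    calls["n_markers_positive"] = calls.sum(axis=1).astype(int)
    calls["label"] = np.where(calls["n_markers_positive"] >= k, "tB", "nB")
    return calls


def concordance(calls_a: pd.Series, calls_b: pd.Series) -> float:
    """Fraction of samples with identical tB/nB label in both call sets."""
    if set(calls_a.index) != set(calls_b.index):
        raise ValueError("call sets cover different samples")
    b = calls_b.reindex(calls_a.index)
    return float((calls_a == b).mean())


def marker_auc(
    values: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Tie-corrected ROC AUC of one marker for the tB-vs-nB contrast, with a
    bootstrap standard error.

    AUC is the Mann-Whitney statistic U/(n1*n0) computed from midranks
    (ties contribute 1/2), equal to exhaustive pair enumeration.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == "tB"]
    neg = values[labels == "nB"]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")

    def _auc(p: np.ndarray, n: np.ndarray) -> float:
        ranks = stats.rankdata(np.concatenate([p, n]))
        u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2.0
        return u / (len(p) * len(n))

    auc = _auc(pos, neg)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(len(values), size=len(values))
        bl, bv = labels[idx], values[idx]
        bp, bn = bv[bl == "tB"], bv[bl == "nB"]
        if len(bp) and len(bn):
            boots.append(_auc(bp, bn))
    se = float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan")
    return float(auc), se


def prevalence(calls: pd.DataFrame | pd.Series) -> Tuple[int, int, float]:
    """Subtype prevalence: (tB count, total, percentage to one decimal)."""
    labels = calls["label"] if isinstance(calls, pd.DataFrame) else calls
    if len(labels) == 0:
        raise ValueError("empty call set")
    count = int((labels == "tB").sum())
    total = int(len(labels))
    return count, total, round(100.0 * count / total, 1)


# ---------------------------------------------------------------------------
# expression heatmap ordering
# ---------------------------------------------------------------------------

def mean_center_cluster(expression: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Series]:
    """Per-gene mean centering followed by hierarchical clustering of samples
    (Euclidean, complete linkage).

    Returns the centered matrix in dendrogram leaf order plus the 2-cut
    cluster labels (the cluster with the higher centered mean is labeled
    ``tB``).
    """
    if len(expression) < 2:
        raise ValueError("need at least 2 samples")
    centered = expression - expression.mean(axis=0)
    values = centered.to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        labels = pd.Series("nB", index=expression.index, name="cluster")
        labels.attrs["degenerate"] = True
        return centered, labels
    Z = hierarchy.linkage(values, method="complete", metric="euclidean")
    order = hierarchy.leaves_list(Z)
    cut = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    means = {c: values[cut == c].mean() for c in np.unique(cut)}
    tb_cluster = max(means, key=means.get)
    labels = pd.Series(
        np.where(cut == tb_cluster, "tB", "nB"), index=expression.index, name="cluster"
    )
    labels.attrs["degenerate"] = False
    return centered.iloc[order], labels
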