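"""Basal-marker discovery from compartment-annotated single-cell counts.

The stages mirror a standard scRNA-seq marker workflow: QC filtering
(mitochondrial share and detected-gene count), library-size log
normalisation, PCA on scaled highly-variable genes, PC1-loading ranking of
genes (PC1 separates the basal from the luminal compartments), Wilcoxon
rank-sum differential expression with Benjamini-Hochberg correction,
candidate selection with expression-fraction filters, rank-based (UCell
style) signature scoring, and a cross-species consistency filter.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "qc_filter",
    "log_normalize",
    "compute_pca",
    "PCAResult",
    "rank_by_pc1",
    "rank_sum_de",
    "select_candidates",
    "score_signature",
    "cross_species_consistency",
    "build_marker_table",
]

LUMINAL_COMPARTMENTS = ("luminal_ER_pos", "luminal_ER_neg")


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


# ---------------------------------------------------------------------------
# QC and normalisation
# ---------------------------------------------------------------------------

def qc_filter(
    adata: ad.AnnData, min_genes: int = 500, max_mito_pct: float = 25.0
) -> ad.AnnData:
    """Drop low-quality cells: fewer than ``min_genes`` detected genes or a
    mitochondrial count share above ``max_mito_pct`` percent.

    The gene set is unchanged; per-cell QC metrics (``n_genes_detected``,
    ``pct_mito``) are attached to ``obs``.  Idempotent.
    """
    if not 0.0 <= max_mito_pct <= 100.0:
        raise ValueError("max_mito_pct must lie in [0, 100]")
    if min_genes < 0:
        raise ValueError("min_genes must be non-negative")
    X = _dense(adata.X)
    n_detected = (X > 0).sum(axis=1)
    total = X.sum(axis=1)
    mito = np.asarray(adata.var["mito"], dtype=bool) if "mito" in adata.var else np.zeros(
        adata.n_vars, dtype=bool
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(total > 0, 100.0 * X[:, mito].sum(axis=1) / total, 0.0)
    keep = (n_detected >= min_genes) & (pct_mito <= max_mito_pct)
    if not keep.any():
        raise ValueError(
            f"all cells removed by QC (min_genes={min_genes}, "
            f"max_mito_pct={max_mito_pct})"
        )
    out = adata[keep].copy()
    out.obs["n_genes_detected"] = n_detected[keep]
    out.obs["pct_mito"] = pct_mito[keep]
    return out


def log_normalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Library-size log normalisation: ln(1 + count / cell_total * scale).

    Zeros map to zero; per cell, sum(exp(x) - 1) equals ``scale_factor``.
    """
    X = _dense(adata.X).astype(float)
    total = X.sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("cells with zero total counts present; run qc_filter first")
    out = adata.copy()
    out.X = np.log1p(X / total[:, None] * scale_factor)
    return out


# ---------------------------------------------------------------------------
# PCA on highly-variable genes
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    loadings: pd.DataFrame  # genes (HVG) x PCs, orthonormal columns
    scores: pd.DataFrame  # cells x PCs
    explained_variance: np.ndarray
    hvg: List[str]


def _hvg_by_dispersion(X: np.ndarray, gene_ids: pd.Index, n_hvg: int, n_bins: int = 20):
    """Top genes by mean-binned standardized dispersion (variance/mean),
    a variance-stabilizing-style selection."""
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(mean, kind="stable")
    bins = np.empty(len(mean), dtype=int)
    bins[order] = np.arange(len(mean)) * n_bins // len(mean)
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = disp[sel].mean(), disp[sel].std(ddof=0)
        z[sel] = (disp[sel] - mu) / sd if sd > 0 else 0.0
    top = np.argsort(-z, kind="stable")[:n_hvg]
    return gene_ids[np.sort(top)]


def compute_pca(
    adata_norm: ad.AnnData, n_hvg: int = 500, n_pcs: int = 20, scale_cap: float = 10.0
) -> PCAResult:
    """PCA of the centered, unit-scaled (capped at ``scale_cap``) expression
    of the top ``n_hvg`` genes by standardized dispersion.

    Loadings are orthonormal; scores are the projection of the scaled data,
    so the sample variance of PC k equals the k-th eigenvalue.
    """
    X = _dense(adata_norm.X).astype(float)
    if n_pcs > min(n_hvg, adata_norm.n_obs - 1):
        raise ValueError("n_pcs exceeds min(n_hvg, n_cells - 1)")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("constant expression matrix; PCA undefined")
    hvg = _hvg_by_dispersion(X, adata_norm.var_names, n_hvg)
    Xh = X[:, adata_norm.var_names.get_indexer(hvg)]
    sd = Xh.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = np.minimum((Xh - Xh.mean(axis=0)) / sd, scale_cap)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(Z)
    pcs = [f"PC{i + 1}" for i in range(n_pcs)]
    return PCAResult(
        loadings=pd.DataFrame(pca.components_.T, index=hvg, columns=pcs),
        scores=pd.DataFrame(scores, index=adata_norm.obs_names, columns=pcs),
        explained_variance=pca.explained_variance_,
        hvg=list(hvg),
    )


def rank_by_pc1(pca: PCAResult, cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by signed PC1 loading, PC1 oriented so that basal cells
    score higher than luminal cells on average.

    Returns a frame indexed by gene with ``pc1_loading`` and ``rank``
    (1 = strongest basal candidate).  A ``separation_warning`` attr is set
    when basal and luminal PC1 scores overlap (|standardized diff| < 1).
    """
    comp = cell_meta["compartment"].reindex(pca.scores.index)
    if comp.nunique() < 2:
        raise ValueError("need at least two compartments to orient PC1")
    pc1 = pca.scores["PC1"]
    basal = pc1[comp == "basal"]
    luminal = pc1[comp.isin(LUMINAL_COMPARTMENTS)]
    sign = 1.0 if basal.mean() >= luminal.mean() else -1.0
    loading = sign * pca.loadings["PC1"]
    pooled_sd = np.sqrt((basal.var(ddof=1) + luminal.var(ddof=1)) / 2.0)
    std_diff = abs(basal.mean() - luminal.mean()) / pooled_sd if pooled_sd > 0 else np.inf
    out = pd.DataFrame({"pc1_loading": loading})
    out = out.sort_values("pc1_loading", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["separation_warning"] = bool(std_diff < 1.0)
    if out.attrs["separation_warning"]:
        warnings.warn("basal and luminal compartments are not separated on PC1")
    return out


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all labelings (handles ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    na = len(x)
    w_obs = ranks[:na].sum()
    mu = na * (len(pooled) + 1) / 2.0
    dev = abs(w_obs - mu)
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= dev - 1e-12:
            count += 1
    return count / total


def rank_sum_de(
    adata_norm: ad.AnnData,
    cell_meta: pd.DataFrame,
    group_a: str = "basal",
    group_b: Optional[Sequence[str]] = None,
    exact_max_n: int = 8,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum test of ``group_a`` cells against the
    pooled ``group_b`` compartments, with BH adjustment across genes.

    Uses the normal approximation with tie correction, or exact enumeration
    of all labelings when both groups have at most ``exact_max_n`` cells.
    ``log_fc`` is the natural-log fold change of group means with
    pseudo-count ``eps``.  Expression fractions and per-compartment means
    are included for downstream filters.
    """
    if group_b is None:
        group_b = list(LUMINAL_COMPARTMENTS)
    comp = cell_meta["compartment"].reindex(adata_norm.obs_names)
    in_a = (comp == group_a).to_numpy()
    in_b = comp.isin(group_b).to_numpy()
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("each group needs at least 2 cells")
    X = _dense(adata_norm.X).astype(float)
    Xa, Xb = X[in_a], X[in_b]

    exact = in_a.sum() <= exact_max_n and in_b.sum() <= exact_max_n
    pvals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        if exact:
            pvals[j] = _exact_ranksum_p(Xa[:, j], Xb[:, j])
        else:
            if np.ptp(np.concatenate([Xa[:, j], Xb[:, j]])) == 0:
                pvals[j] = 1.0
            else:
                pvals[j] = stats.mannwhitneyu(
                    Xa[:, j], Xb[:, j], alternative="two-sided", method="asymptotic"
                ).pvalue
    padj = multipletests(pvals, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "log_fc": np.log(Xa.mean(axis=0) + eps) - np.log(Xb.mean(axis=0) + eps),
            "p_value": pvals,
            "p_adj": padj,
            "frac_basal": (Xa > 0).mean(axis=0),
            "frac_luminal": (Xb > 0).mean(axis=0),
            "mean_basal": Xa.mean(axis=0),
        },
        index=adata_norm.var_names,
    )
    for c in group_b:
        sel = (comp == c).to_numpy()
        if sel.any():
            table[f"mean_{c}"] = X[sel].mean(axis=0)
    return table


def select_candidates(
    table: pd.DataFrame,
    k: int = 20,
    min_frac_basal: float = 0.75,
    max_frac_luminal: float = 1.0,
    alpha: float = 0.05,
) -> List[str]:
    """First ``k`` genes (by ``rank``) passing adjusted p < alpha and the
    expression-fraction filters (strictly more than ``min_frac_basal`` of
    basal cells expressing, at most ``max_frac_luminal`` of luminal cells).

    Returns fewer than ``k`` genes, with a warning, when the filters
    exhaust the ranked list.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not (0 <= min_frac_basal <= 1 and 0 <= max_frac_luminal <= 1):
        raise ValueError("fraction thresholds must lie in [0, 1]")
    passing = table[
        (table["p_adj"] < alpha)
        & (table["frac_basal"] > min_frac_basal)
        & (table["frac_luminal"] <= max_frac_luminal)
    ].sort_values("rank", kind="stable")
    if len(passing) < k:
        warnings.warn(
            f"only {len(passing)} of the requested {k} candidates pass the filters"
        )
    return list(passing.index[:k])


# ---------------------------------------------------------------------------
# signature scoring
# ---------------------------------------------------------------------------

def score_signature(
    adata_norm: ad.AnnData, gene_set: Iterable[str], r_max: int = 1500
) -> pd.Series:
    """Rank-based (UCell-style) per-cell signature score in [0, 1].

    Genes are ranked per cell by descending expression (ties get the average
    rank); ranks above ``r_max`` are set to ``r_max + 1``.  The score is
    ``1 - U / (|set| * r_max)`` with ``U = sum(ranks of set) - s(s+1)/2``,
    clipped to [0, 1].
    """
    gene_set = list(dict.fromkeys(gene_set))
    present = [g for g in gene_set if g in adata_norm.var_names]
    if not present:
        raise ValueError("no gene of the signature is present in the matrix")
    s = len(present)
    if r_max < s:
        raise ValueError("r_max must be at least the signature size")
    X = _dense(adata_norm.X).astype(float)
    # ranks of descending expression, average ties, capped at r_max + 1
    ranks = stats.rankdata(-X, axis=1)
    ranks = np.minimum(ranks, r_max + 1)
    cols = adata_norm.var_names.get_indexer(present)
    U = ranks[:, cols].sum(axis=1) - s * (s + 1) / 2.0
    score = np.clip(1.0 - U / (s * r_max), 0.0, 1.0)
    return pd.Series(score, index=adata_norm.obs_names, name="signature_score")


# ---------------------------------------------------------------------------
# cross-species consistency
# ---------------------------------------------------------------------------

def cross_species_consistency(
    mouse_table: pd.DataFrame,
    human_table: pd.DataFrame,
    candidates: Sequence[str],
    top_n: int = 10,
    min_frac_basal: float = 0.75,
) -> List[str]:
    """Retain mouse candidates that are consistently basal in the human data.

    Gene symbols are matched case-insensitively.  A candidate survives when
    its human basal expression fraction exceeds ``min_frac_basal`` and its
    human basal mean exceeds every human luminal compartment mean.  The
    first ``top_n`` survivors are returned in mouse rank order.
    """
    human_lut = {g.upper(): g for g in human_table.index}
    if not any(g.upper() in human_lut for g in mouse_table.index):
        raise ValueError("no gene symbols shared between the two species tables")
    lum_cols = [c for c in human_table.columns if c.startswith("mean_luminal")]
    ranked = mouse_table.loc[
        [g for g in candidates if g in mouse_table.index]
    ].sort_values("rank", kind="stable")
    kept: List[str] = []
    for g in ranked.index:
        h = human_lut.get(g.upper())
        if h is None:
            continue
        row = human_table.loc[h]
        if row["frac_basal"] <= min_frac_basal:
            continue
        if any(row["mean_basal"] <= row[c] for c in lum_cols):
            continue
        kept.append(g)
        if len(kept) == top_n:
            break
    return kept


# ---------------------------------------------------------------------------
# convenience: full marker table
# ---------------------------------------------------------------------------

def build_marker_table(
    adata_norm: ad.AnnData, n_hvg: int = 500, n_pcs: int = 20
) -> pd.DataFrame:
    """DE statistics merged with PC1-loading ranks for all tested genes.

    Genes outside the highly-variable set carry no PC1 loading and are
    ranked after every HVG (original order preserved among them).
    """
    de = rank_sum_de(adata_norm, adata_norm.obs)
    pca = compute_pca(adata_norm, n_hvg=n_hvg, n_pcs=n_pcs)
    order = rank_by_pc1(pca, adata_norm.obs)
    de["pc1_loading"] = order["pc1_loading"].reindex(de.index)
    de["rank"] = order["rank"].reindex(de.index)
    missing = de["rank"].isna()
    de.loc[missing, "rank"] = len(order) + 1 + np.arange(missing.sum())
    de["rank"] = de["rank"].astype(int)
    de.attrs["separation_warning"] = order.attrs.get("separation_warning", False)
    return de
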