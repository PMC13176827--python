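"""Readers and writers for the pipeline's plain-text interchange formats.

Counts travel as matrix-market triplets with gene/cell TSV sidecars (or a
dense TSV); cohort, screen, dose-response and survival tables as CSV with
header rows; ground truth and cutoffs as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


# ---------------------------------------------------------------------------
# annotated counts
# ---------------------------------------------------------------------------

def write_counts_mtx(adata: ad.AnnData, prefix: str | Path) -> None:
    """Write counts as ``<prefix>.mtx`` (genes x cells, matrix-market
    triplet) with ``<prefix>.genes.tsv`` and ``<prefix>.cells.tsv`` sidecars."""
    prefix = Path(prefix)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(np.asarray(X))
    spio.mmwrite(str(prefix.with_suffix(".mtx")), X.T.astype(int))
    genes = adata.var.reset_index()
    genes.to_csv(prefix.parent / f"{prefix.name}.genes.tsv", sep="\t", index=False)
    cells = adata.obs.reset_index()
    cells.to_csv(prefix.parent / f"{prefix.name}.cells.tsv", sep="\t", index=False)


def read_counts_mtx(prefix: str | Path) -> ad.AnnData:
    """Read an annotated count matrix written by :func:`write_counts_mtx`."""
    prefix = Path(prefix)
    X = spio.mmread(str(prefix.with_suffix(".mtx"))).tocsr().T
    genes = pd.read_csv(prefix.parent / f"{prefix.name}.genes.tsv", sep="\t")
    cells = pd.read_csv(prefix.parent / f"{prefix.name}.cells.tsv", sep="\t")
    var = genes.set_index(genes.columns[0])
    obs = cells.set_index(cells.columns[0])
    return ad.AnnData(X=X.astype(np.int32), obs=obs, var=var)


def write_counts_tsv(adata: ad.AnnData, path: str | Path) -> None:
    """Dense gene x cell TSV (genes as rows)."""
    X = adata.X
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    df = pd.DataFrame(np.asarray(X).T, index=adata.var_names, columns=adata.obs_names)
    df.to_csv(path, sep="\t")


def read_annotation_csv(path: str | Path) -> pd.DataFrame:
    """Per-cell annotation CSV: cell_id, sample, species, compartment."""
    df = pd.read_csv(path)
    return df.set_index(df.columns[0])


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, index=index)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """IHC cohort CSV: sample_id, then one %-positive column per marker
    (extra clinical columns are carried through untouched)."""
    df = pd.read_csv(path)
    return df.set_index(df.columns[0])


def read_screen_csv(path: str | Path, lines_path: str | Path) -> Tuple[pd.DataFrame, pd.Series]:
    """Viability screen CSV (rows = compounds, columns = cell lines) plus a
    line-metadata CSV with columns (cell_line, group)."""
    screen = pd.read_csv(path).set_index("compound")
    lines = pd.read_csv(lines_path).set_index("cell_line")["group"]
    return screen, lines


def read_dose_response_csv(path: str | Path) -> pd.DataFrame:
    """Dose-response CSV with columns dose_uM, replicate, viability_pct."""
    return pd.read_csv(path)


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    """Survival CSV: patient_id, time_months, event, then expression columns."""
    df = pd.read_csv(path)
    return df.set_index(df.columns[0])


# ---------------------------------------------------------------------------
# JSON artifacts
# ---------------------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
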