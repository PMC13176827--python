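"""Synthetic data generators with recorded ground truth.

Each generator emulates one input of the stratification pipeline:

* :func:`gen_sc_dataset` — a three-population (basal / luminal ER+ / luminal
  ER-) negative-binomial count matrix with planted compartment markers and
  injected QC artifacts (high-mitochondrial and low-depth cells);
* :func:`gen_ihc_cohort` — per-sample %-positive values for the SMA/TAGL/TPM2
  panel drawn from bimodal mixtures with known subtype labels and known
  density valleys;
* :func:`gen_viability_screen` — a compound x cell-line percent-viability
  matrix with planted selective hits, pan-toxic and inert controls;
* :func:`gen_dose_response` — four-parameter-logistic viability series with a
  known IC50;
* :func:`gen_survival_cohort` — exponential event times with a known hazard
  ratio between the expression-defined strata;
* :func:`gen_cellline_expression` — a lines x marker-genes log2(TPM+1)-like
  panel with known tB/nB group labels and correlated drug-sensitivity AUCs.

All generators are pure functions of :class:`~tbstrat.config.SimConfig`;
every one draws from its own seed sub-stream so the outputs are mutually
independent and individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import anndata as ad
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import TB_MARKER_GENES, SimConfig

__all__ = [
    "GroundTruth",
    "gen_sc_dataset",
    "gen_ihc_cohort",
    "gen_viability_screen",
    "gen_dose_response",
    "gen_survival_cohort",
    "gen_cellline_expression",
    "fourpl_curve",
]

# Fixed sub-stream ids: one PRNG stream per generator.
_STREAMS = {"sc": 1, "ihc": 2, "screen": 3, "dose": 4, "survival": 5, "panel": 6}


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


@dataclass
class GroundTruth:
    """Planted truth sufficient to score every downstream stage."""

    cell_compartments: Optional[pd.Series] = None
    planted_markers: Dict[str, List[str]] = field(default_factory=dict)
    artifact_cells: List[str] = field(default_factory=list)
    sample_subtypes: Optional[pd.Series] = None
    true_cutoffs: Dict[str, Optional[float]] = field(default_factory=dict)
    hit_compounds: List[str] = field(default_factory=list)
    pan_toxic_compounds: List[str] = field(default_factory=list)
    inert_compounds: List[str] = field(default_factory=list)
    true_ic50: Optional[float] = None
    true_fourpl: Optional[tuple] = None
    true_hr: Optional[float] = None
    patient_strata: Optional[pd.Series] = None
    line_groups: Optional[pd.Series] = None

    def to_json(self) -> str:
        d = {}
        for k, v in asdict(self).items():
            if isinstance(v, pd.Series):
                v = v.to_dict()
            d[k] = v
        for k in ("cell_compartments", "sample_subtypes", "patient_strata", "line_groups"):
            v = getattr(self, k)
            d[k] = None if v is None else v.to_dict()
        return json.dumps(d, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------

_COMPARTMENTS = ("basal", "luminal_ER_pos", "luminal_ER_neg")
_N_MITO = 10
_MARKER_FOLD = 10.0  # boost of a planted marker in its own compartment
_MARKER_OFF = 0.1  # residual level elsewhere


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw parameterised by mean and dispersion (var = mu + a*mu^2)."""
    n = 1.0 / dispersion
    p = n / (n + np.maximum(mu, 1e-12))
    return rng.negative_binomial(n, p)


def gen_sc_dataset(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Three-population NB count matrix with planted compartment markers.

    Returns an :class:`anndata.AnnData` (cells x genes; ``obs`` carries
    sample, species and compartment, ``var`` a mitochondrial flag) plus the
    ground truth (compartment per cell, planted marker lists, artifact cells).

    A ``mito_artifact_fraction`` of cells carries an injected QC artifact:
    alternately a high mitochondrial share or a depth low enough to detect
    fewer than ~500 genes.
    """
    rng = _rng(config, "sc")
    n_pop = config.n_cells_per_population
    n_cells = 3 * n_pop
    n_genes = config.n_genes
    mouse = config.species == "mouse"

    def sym(s: str) -> str:
        return s.capitalize() if mouse else s.upper()

    # gene names: mito genes first, then planted markers, then background
    mito_names = [sym(f"mt-nd{i + 1}") for i in range(_N_MITO)]
    marker_names: Dict[str, List[str]] = {}
    stems = {"basal": "basm", "luminal_ER_pos": "lpom", "luminal_ER_neg": "lnem"}
    for comp in _COMPARTMENTS:
        marker_names[comp] = [
            sym(f"{stems[comp]}{i + 1:03d}") for i in range(config.n_marker_genes)
        ]
    n_special = _N_MITO + 3 * config.n_marker_genes
    if n_special > n_genes:
        raise ValueError("n_genes too small for mito + planted marker genes")
    bg_names = [sym(f"gene{i + 1:04d}") for i in range(n_genes - n_special)]
    gene_names = (
        mito_names
        + marker_names["basal"]
        + marker_names["luminal_ER_pos"]
        + marker_names["luminal_ER_neg"]
        + bg_names
    )

    # baseline relative rates; markers get a solid base so they are detected
    # in most cells of their own compartment
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base[:_N_MITO] = 0.0
    marker_sl = slice(_N_MITO, _N_MITO + 3 * config.n_marker_genes)
    base[marker_sl] = 1.0
    base = base / base.sum() * 0.96  # non-mito genes carry 96% of depth
    base[:_N_MITO] = 0.04 / _N_MITO  # ~4% mitochondrial share

    # per-compartment rate multipliers for planted markers; luminal marker
    # programs are partially shared between the two luminal compartments, so
    # the dominant expression axis is basal vs luminal as in real tissue
    mult = np.ones((3, n_genes))
    for ci, comp in enumerate(_COMPARTMENTS):
        lo = _N_MITO + ci * config.n_marker_genes
        hi = lo + config.n_marker_genes
        mult[:, lo:hi] = _MARKER_OFF
        mult[ci, lo:hi] = _MARKER_FOLD
        if comp != "basal":
            sibling = 3 - ci  # the other luminal compartment (indices 1, 2)
            mult[sibling, lo:hi] = _MARKER_FOLD / 4.0

    comp_idx = np.repeat(np.arange(3), n_pop)
    lib = rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)

    # inject artifacts: alternate high-mito / low-depth
    n_art = int(round(config.mito_artifact_fraction * n_cells))
    art_idx = rng.choice(n_cells, size=n_art, replace=False) if n_art else np.array([], int)
    mito_boost = np.ones(n_cells)
    depth_fac = np.ones(n_cells)
    for j, i in enumerate(np.sort(art_idx)):
        if j % 2 == 0:
            mito_boost[i] = 60.0  # mito share ~ 70%, as in dying cells
        else:
            depth_fac[i] = 0.08  # ~240 counts => <500 detected genes

    mu = (
        config.mean_depth
        * (lib * depth_fac)[:, None]
        * base[None, :]
        * mult[comp_idx, :]
    )
    mu[:, :_N_MITO] *= mito_boost[:, None]
    counts = _nb_sample(rng, mu, config.nb_dispersion).astype(np.int32)

    cell_ids = [f"cell{i + 1:05d}" for i in range(n_cells)]
    obs = pd.DataFrame(
        {
            "sample": [f"{config.species}_s{(i % 3) + 1}" for i in range(n_cells)],
            "species": config.species,
            "compartment": [_COMPARTMENTS[c] for c in comp_idx],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    var = pd.DataFrame(
        {"mito": [i < _N_MITO for i in range(n_genes)]},
        index=pd.Index(gene_names, name="gene_id"),
    )
    adata = ad.AnnData(X=counts, obs=obs, var=var)

    truth = GroundTruth(
        cell_compartments=obs["compartment"].copy(),
        planted_markers={c: list(marker_names[c]) for c in _COMPARTMENTS},
        artifact_cells=[cell_ids[i] for i in np.sort(art_idx)],
    )
    return adata, truth


# ---------------------------------------------------------------------------
# IHC cohort
# ---------------------------------------------------------------------------

def _mixture_valley(mix, weight_high: float) -> Optional[float]:
    """Density minimum of the two-component Gaussian mixture, located between
    the two mode means on a fine grid (0.01 percentage points)."""
    if weight_high <= 0.0 or weight_high >= 1.0:
        return None
    grid = np.arange(0.0, 100.0001, 0.01)
    dens = (1.0 - weight_high) * stats.norm.pdf(grid, mix.low_mean, mix.low_sd) + (
        weight_high
    ) * stats.norm.pdf(grid, mix.high_mean, mix.high_sd)
    lo = np.searchsorted(grid, max(mix.low_mean, 0.0))
    hi = np.searchsorted(grid, min(mix.high_mean, 100.0))
    if hi <= lo:
        return None
    return float(grid[lo + int(np.argmin(dens[lo:hi]))])


def gen_ihc_cohort(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Bimodal %-positive marker table with known subtype labels and valleys.

    tB samples draw at least two of the three markers from the high mode
    (all three with probability 1/2); nB samples draw every marker from the
    low mode.  Values are clipped to [0, 100].  The true valley per marker is
    the density minimum of the realised mixture; it is ``None`` (flagged
    unimodal) when a mode is absent.
    """
    rng = _rng(config, "ihc")
    markers = list(config.ihc_mixture_params)
    for name, mix in config.ihc_mixture_params.items():
        mix.check_separated(name)

    n = config.cohort_size
    n_tb = int(round(config.tb_prevalence * n))
    labels = np.array(["nB"] * n, dtype=object)
    tb_idx = rng.choice(n, size=n_tb, replace=False) if n_tb else np.array([], int)
    labels[tb_idx] = "tB"

    # which markers are drawn from the high mode, per sample
    high = np.zeros((n, len(markers)), dtype=bool)
    for i in tb_idx:
        if rng.random() < 0.5:
            high[i, :] = True
        else:
            off = rng.integers(len(markers))  # one marker stays low
            high[i, :] = True
            high[i, off] = False

    values = np.empty((n, len(markers)))
    for j, m in enumerate(markers):
        mix = config.ihc_mixture_params[m]
        lo = rng.normal(mix.low_mean, mix.low_sd, size=n)
        hi = rng.normal(mix.high_mean, mix.high_sd, size=n)
        values[:, j] = np.where(high[:, j], hi, lo)
    values = np.clip(values, 0.0, 100.0)

    sample_ids = pd.Index([f"T{i + 1:04d}" for i in range(n)], name="sample_id")
    cohort = pd.DataFrame(values, index=sample_ids, columns=markers)

    weights = high.mean(axis=0)
    cutoffs = {
        m: _mixture_valley(config.ihc_mixture_params[m], w)
        for m, w in zip(markers, weights)
    }
    truth = GroundTruth(
        sample_subtypes=pd.Series(labels, index=sample_ids, name="subtype"),
        true_cutoffs=cutoffs,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# viability screen
# ---------------------------------------------------------------------------

_HIT_TB_MEAN = 5.0
_HIT_NB_MEAN = 70.0
_BG_LOW = 35.0


def gen_viability_screen(config: SimConfig) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Compound x cell-line viability screen with planted selective hits.

    Returns ``(viability, line_groups, truth)``: a compounds x lines percent
    viability table, a per-line tB/nB group label series, and the ground
    truth listing planted hits and controls.  Planted hits sit at a tB group
    mean of ~5% and nB mean of ~70%, clear of the 20% decision boundary by
    more than three noise standard deviations.
    """
    sd = config.viability_noise_sd
    if _HIT_TB_MEAN >= 20.0 - 3.0 * sd or _HIT_NB_MEAN <= 20.0 + 3.0 * sd:
        raise ValueError(
            f"viability_noise_sd={sd} leaves no margin around the 20% "
            "hit-calling boundary"
        )
    rng = _rng(config, "screen")
    n = config.n_compounds
    n_special = config.n_planted_hits + config.n_pan_toxic + config.n_inert
    if n_special > n:
        raise ValueError("planted hits + controls exceed n_compounds")

    compounds = pd.Index([f"cmpd{i + 1:05d}" for i in range(n)], name="compound")
    lines = pd.Index(["TB-1", "TB-2", "NB-1", "NB-2"], name="cell_line")
    groups = pd.Series(["tB", "tB", "nB", "nB"], index=lines, name="group")

    special = rng.choice(n, size=n_special, replace=False)
    hits = np.sort(special[: config.n_planted_hits])
    pan = np.sort(special[config.n_planted_hits : config.n_planted_hits + config.n_pan_toxic])
    inert = np.sort(special[config.n_planted_hits + config.n_pan_toxic :])

    tb_base = rng.uniform(_BG_LOW, 100.0, size=n)
    nb_base = tb_base.copy()  # background compounds affect both groups alike
    tb_base[hits] = _HIT_TB_MEAN
    nb_base[hits] = _HIT_NB_MEAN
    tb_base[pan] = 5.0
    nb_base[pan] = 5.0
    tb_base[inert] = 100.0
    nb_base[inert] = 100.0

    base = np.column_stack([tb_base, tb_base, nb_base, nb_base])
    viability = np.clip(base + rng.normal(0.0, sd, size=base.shape), 0.0, None)
    screen = pd.DataFrame(viability, index=compounds, columns=lines)

    truth = GroundTruth(
        hit_compounds=[compounds[i] for i in hits],
        pan_toxic_compounds=[compounds[i] for i in pan],
        inert_compounds=[compounds[i] for i in inert],
        line_groups=groups.copy(),
    )
    return screen, groups, truth


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

def fourpl_curve(dose, top: float, bottom: float, ic50: float, hill: float):
    """Four-parameter logistic: v(d) = bottom + (top-bottom)/(1+(d/ic50)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def gen_dose_response(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Serial half-log dilution series following a 4PL curve plus noise.

    The dose grid mimics a serial-dilution scheme starting at
    ``top_dose_uM`` and descending in half-log steps; it must cover at least
    three orders of magnitude around the true IC50.
    """
    top, bottom, ic50, hill = config.fourpl_params
    if config.n_doses < 6:
        raise ValueError("need at least 6 doses")
    doses = config.top_dose_uM * 10.0 ** (-0.5 * np.arange(config.n_doses))
    span = np.log10(doses.max() / doses.min())
    if span < 3.0 or not doses.min() / 10.0 <= ic50 <= doses.max() * 10.0:
        raise ValueError("dose grid must span >=3 log10 units around the IC50")

    rng = _rng(config, "dose")
    rows = []
    for rep in range(1, config.n_replicates + 1):
        v = fourpl_curve(doses, top, bottom, ic50, hill)
        v = v + rng.normal(0.0, config.dose_noise_sd, size=v.shape)
        for d, vi in zip(doses, v):
            rows.append((d, rep, vi))
    df = pd.DataFrame(rows, columns=["dose_uM", "replicate", "viability_pct"])
    truth = GroundTruth(true_ic50=float(ic50), true_fourpl=(top, bottom, ic50, hill))
    return df, truth


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

def _uniform_censor_bound(rate: float, censor_rate: float) -> float:
    """Upper bound b of the Uniform(0, b) censoring law giving the requested
    expected censoring fraction against Exponential(rate) event times."""
    # P(censored) = P(C < T) = (1 - exp(-rate*b)) / (rate*b), decreasing in b
    def f(b):
        return (1.0 - np.exp(-rate * b)) / (rate * b) - censor_rate

    return float(optimize.brentq(f, 1e-9 / rate, 1e6 / rate))


def gen_survival_cohort(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Exponential survival with a planted hazard ratio between strata.

    Patients split into quarters: the lowest quarter of the three-gene mean
    expression ('low'), the top quarter ('high', hazard = baseline * HR) and
    an intermediate half (hazard = baseline * sqrt(HR)).  The three marker
    gene columns are constructed so their per-patient mean reproduces the
    planted stratum assignment under an upper/lower-quartile split.
    """
    rng = _rng(config, "survival")
    n = config.n_patients
    if n < 8:
        raise ValueError("need at least 8 patients")
    n_q = n // 4
    strata = np.array(
        ["low"] * n_q + ["mid"] * (n - 2 * n_q) + ["high"] * n_q, dtype=object
    )
    rng.shuffle(strata)

    # three-gene mean scores; inter-stratum gaps are ~10 sds wide so the
    # quartile split reproduces the planted strata exactly
    centers = {"low": 2.0, "mid": 5.0, "high": 8.0}
    score = np.array([centers[s] for s in strata]) + rng.normal(0.0, 0.3, size=n)
    deltas = rng.normal(0.0, 0.5, size=(n, 3))
    deltas -= deltas.mean(axis=1, keepdims=True)  # per-patient gene mean == score
    genes = score[:, None] + deltas

    lam0 = config.baseline_hazard
    hr = config.survival_hr
    lam = np.where(
        strata == "high", lam0 * hr, np.where(strata == "mid", lam0 * np.sqrt(hr), lam0)
    )
    t_event = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        b = _uniform_censor_bound(float(np.mean(lam)), config.censor_rate)
        t_cens = rng.uniform(0.0, b, size=n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(n, dtype=int)
        time = t_event

    pid = pd.Index([f"P{i + 1:05d}" for i in range(n)], name="patient_id")
    df = pd.DataFrame(
        {
            "time_months": time,
            "event": event,
            "ACTA2": genes[:, 0],
            "TAGLN": genes[:, 1],
            "TPM2": genes[:, 2],
        },
        index=pid,
    )
    truth = GroundTruth(
        true_hr=float(hr),
        patient_strata=pd.Series(strata, index=pid, name="stratum"),
    )
    return df, truth


# ---------------------------------------------------------------------------
# cell-line marker panel
# ---------------------------------------------------------------------------

def gen_cellline_expression(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Lines x marker-genes panel on a log2(TPM+1)-like scale, plus a
    correlated drug-sensitivity AUC column (lower AUC = more sensitive).

    tB lines express all three markers highly; nB lines are low for all
    three.  Ground truth records the group label per line.
    """
    if config.n_cell_lines < 2:
        raise ValueError("need at least 2 cell lines")
    rng = _rng(config, "panel")
    n = config.n_cell_lines
    n_tb = config.n_tb_lines
    groups = np.array(["tB"] * n_tb + ["nB"] * (n - n_tb), dtype=object)
    lines = pd.Index(
        [f"{g}-line{i + 1:02d}" for i, g in enumerate(groups)], name="cell_line"
    )
    expr = np.where(
        (groups == "tB")[:, None],
        rng.normal(7.0, 0.8, size=(n, 3)),
        rng.normal(1.2, 0.5, size=(n, 3)),
    )
    expr = np.clip(expr, 0.0, None)
    panel = pd.DataFrame(expr, index=lines, columns=list(TB_MARKER_GENES))
    # sensitivity AUC decreases with marker expression (more sensitive lines)
    panel["dasatinib_auc"] = np.clip(
        0.85 - 0.06 * expr.mean(axis=1) + rng.normal(0.0, 0.02, size=n), 0.0, 1.0
    )
    truth = GroundTruth(line_groups=pd.Series(groups, index=lines, name="group"))
    return panel, truth
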