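"""Simulation configuration for every synthetic input the pipeline consumes.

A single :class:`SimConfig` (one seed) drives all generators.  Each generator
draws from its own deterministic sub-stream of the seed, so adding or
re-running one generator never perturbs the output of another.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, Tuple

__all__ = ["MarkerMixture", "SimConfig", "DEFAULT_IHC_MIXTURES", "TB_MARKER_GENES"]

#: The three-gene basal marker panel used for tumor and cell-line stratification.
TB_MARKER_GENES: Tuple[str, str, str] = ("ACTA2", "TAGLN", "TPM2")


@dataclass(frozen=True)
class MarkerMixture:
    """Two-component Gaussian mixture (on the 0-100 %-positive scale) for one
    IHC marker: a low (negative) mode and a high (positive) mode."""

    low_mean: float
    low_sd: float
    high_mean: float
    high_sd: float

    def check_separated(self, name: str = "marker") -> None:
        """Reject overlapping modes: the high-low mean gap must exceed twice
        the summed standard deviations, otherwise no valley exists."""
        gap = self.high_mean - self.low_mean
        if gap <= 2.0 * (self.low_sd + self.high_sd):
            raise ValueError(
                f"IHC mixture modes for {name!r} overlap: mean gap {gap:.1f} "
                f"must exceed 2*(low_sd+high_sd)="
                f"{2.0 * (self.low_sd + self.high_sd):.1f}"
            )


# Defaults place the true mixture valleys near the positivity cutoffs the
# marker panel uses in practice (~5 for SMA, ~30 for TAGL, ~40 for TPM2),
# so cutoff-recovery checks are meaningful.
DEFAULT_IHC_MIXTURES: Dict[str, MarkerMixture] = {
    "SMA": MarkerMixture(1.0, 1.0, 32.0, 11.0),
    "TAGL": MarkerMixture(10.0, 7.5, 53.0, 11.0),
    "TPM2": MarkerMixture(17.0, 8.0, 62.0, 11.0),
}


@dataclass(frozen=True)
class SimConfig:
    """All tunable knobs of the synthetic-data generators.

    Every generator is a pure function of this object: identical configs
    (seed included) give byte-identical outputs.
    """

    seed: int = 0

    # --- single-cell count matrix ---
    n_cells_per_population: int = 300
    n_genes: int = 1000
    n_marker_genes: int = 20  # planted markers per epithelial compartment
    nb_dispersion: float = 0.5  # NB: var = mu + dispersion * mu^2
    mito_artifact_fraction: float = 0.05
    mean_depth: float = 3000.0  # expected counts per clean cell
    species: str = "mouse"

    # --- IHC cohort ---
    cohort_size: int = 243
    tb_prevalence: float = 55.0 / 243.0
    ihc_mixture_params: Dict[str, MarkerMixture] = field(
        default_factory=lambda: dict(DEFAULT_IHC_MIXTURES)
    )

    # --- viability screen ---
    n_compounds: int = 3200
    n_planted_hits: int = 10
    n_pan_toxic: int = 5
    n_inert: int = 5
    viability_noise_sd: float = 3.0  # percent viability units

    # --- dose-response ---
    fourpl_params: Tuple[float, float, float, float] = (100.0, 0.0, 1.0, 1.0)
    # (top %, bottom %, ic50 uM, hill)
    n_doses: int = 10
    top_dose_uM: float = 1000.0  # serial half-log dilutions downward
    n_replicates: int = 3
    dose_noise_sd: float = 2.0

    # --- survival cohort ---
    n_patients: int = 2000
    survival_hr: float = 2.59
    baseline_hazard: float = 0.02  # events per month in the low stratum
    censor_rate: float = 0.2

    # --- cell-line expression panel ---
    n_cell_lines: int = 4
    n_tb_lines: int = 2

    def __post_init__(self) -> None:
        if self.n_cells_per_population <= 0 or self.n_genes <= 0:
            raise ValueError("cell/gene dimensions must be positive")
        if self.n_marker_genes * 3 > self.n_genes:
            raise ValueError("3 * n_marker_genes must not exceed n_genes")
        if not 0.0 <= self.mito_artifact_fraction <= 1.0:
            raise ValueError("mito_artifact_fraction must lie in [0, 1]")
        if not 0.0 <= self.tb_prevalence <= 1.0:
            raise ValueError("tb_prevalence must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_planted_hits > self.n_compounds:
            raise ValueError("n_planted_hits cannot exceed n_compounds")
        if self.survival_hr <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if not 0 < self.n_tb_lines < self.n_cell_lines:
            raise ValueError("need at least one tB and one nB cell line")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["ihc_mixture_params"] = {
            k: asdict(v) for k, v in self.ihc_mixture_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "ihc_mixture_params" in d:
            d["ihc_mixture_params"] = {
                k: MarkerMixture(**v) if isinstance(v, dict) else v
                for k, v in d["ihc_mixture_params"].items()
            }
        if "fourpl_params" in d:
            d["fourpl_params"] = tuple(d["fourpl_params"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SimConfig":
        return cls.from_dict(json.loads(s))

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
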