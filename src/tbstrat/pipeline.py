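"""End-to-end orchestration of the synthetic demo pipeline.

:func:`run_pipeline` executes the selected stages — simulate, marker
discovery, cohort stratification, screen analysis, dose-response fitting,
survival analysis — from a single :class:`RunConfig`, writes every artifact
under the output directory together with a resolved-config copy, and
returns a manifest listing each file with its content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import cohort as co
from . import io as tio
from . import markers as mk
from . import screen as sc
from . import survival as sv
from .config import SimConfig
from .synthetic import (
    gen_cellline_expression,
    gen_dose_response,
    gen_ihc_cohort,
    gen_sc_dataset,
    gen_survival_cohort,
    gen_viability_screen,
)

log = logging.getLogger("tbstrat")

ALL_STAGES = ("simulate", "discover-markers", "stratify", "screen", "dose-response", "survival")

_KNOWN_KEYS = {
    "stages",
    "seed",
    "out_dir",
    "log_level",
    "sim",
    "markers",
    "stratify",
    "screen",
    "survival",
}


@dataclass
class RunConfig:
    stages: List[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    out_dir: str = "tbstrat_out"
    log_level: str = "INFO"
    sim: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)  # min_genes, max_mito, top_k, min_frac_basal
    stratify: dict = field(default_factory=dict)  # k, fixed_cutoffs
    screen: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)  # genes, split rule

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        bad = [s for s in cfg.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        return cfg

    def sim_config(self) -> SimConfig:
        return SimConfig.from_dict({"seed": self.seed, **self.sim})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Dict[str, str]:
    """Run the selected stages and return ``{relative path: sha256}``.

    Stage failures abort with a :class:`StageError` naming the stage;
    artifacts written by earlier stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=config.log_level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    simc = config.sim_config()
    (out / "resolved_config.json").write_text(
        json.dumps(
            {
                "stages": config.stages,
                "seed": config.seed,
                "sim": simc.to_dict(),
                "markers": config.markers,
                "stratify": config.stratify,
                "screen": config.screen,
                "survival": config.survival,
            },
            indent=2,
            sort_keys=True,
        )
    )

    stage = "simulate"
    try:
        if "simulate" in config.stages:
            log.info("simulate: generating all synthetic inputs")
            adata, sc_truth = gen_sc_dataset(simc)
            tio.write_counts_mtx(adata, out / "counts")
            (out / "sc_truth.json").write_text(sc_truth.to_json())
            ihc, ihc_truth = gen_ihc_cohort(simc)
            tio.write_table(ihc, out / "cohort.csv")
            (out / "ihc_truth.json").write_text(ihc_truth.to_json())
            screen_df, groups, screen_truth = gen_viability_screen(simc)
            tio.write_table(screen_df, out / "screen.csv")
            tio.write_table(groups.to_frame(), out / "lines.csv")
            (out / "screen_truth.json").write_text(screen_truth.to_json())
            dr, dr_truth = gen_dose_response(simc)
            tio.write_table(dr, out / "dose_response.csv", index=False)
            (out / "dose_truth.json").write_text(dr_truth.to_json())
            surv, surv_truth = gen_survival_cohort(simc)
            tio.write_table(surv, out / "survival.csv")
            (out / "survival_truth.json").write_text(surv_truth.to_json())
            panel, panel_truth = gen_cellline_expression(simc)
            tio.write_table(panel, out / "cellline_panel.csv")
            (out / "panel_truth.json").write_text(panel_truth.to_json())

        stage = "discover-markers"
        if "discover-markers" in config.stages:
            log.info("discover-markers: QC, normalisation, PCA ranking, DE")
            p = config.markers
            _require(out / "counts.mtx", stage)
            adata = tio.read_counts_mtx(out / "counts")
            filtered = mk.qc_filter(
                adata, p.get("min_genes", 500), p.get("max_mito", 25.0)
            )
            norm = mk.log_normalize(filtered)
            table = mk.build_marker_table(
                norm,
                n_hvg=p.get("n_hvg", min(500, norm.n_vars)),
                n_pcs=p.get("n_pcs", 20),
            )
            top = mk.select_candidates(
                table,
                k=p.get("top_k", 20),
                min_frac_basal=p.get("min_frac_basal", 0.75),
            )
            table.loc[top].to_csv(out / "markers.csv")
            table.to_csv(out / "marker_table.csv")

        stage = "stratify"
        if "stratify" in config.stages:
            log.info("stratify: valley cutoffs and k-of-n subtype calls")
            p = config.stratify
            path = out / "cohort.csv"
            _require(path, stage)
            ihc = tio.read_cohort_csv(path)
            if "fixed_cutoffs" in p:
                cutoffs = co.CutoffSet.fixed(p["fixed_cutoffs"])
            else:
                cutoffs = co.derive_cutoffs(ihc)
            calls = co.classify_samples(ihc, cutoffs, k=p.get("k", 2))
            clusters = co.cluster_cohort(ihc)
            calls["cluster"] = clusters
            tio.write_json(cutoffs.to_dict(), out / "cutoffs.json")
            tio.write_table(calls, out / "calls.csv")
            count, total, pct = co.prevalence(calls)
            tio.write_json(
                {
                    "tB": count,
                    "total": total,
                    "prevalence_pct": pct,
                    "concordance": co.concordance(calls["label"], clusters),
                },
                out / "prevalence.json",
            )

        stage = "screen"
        if "screen" in config.stages:
            log.info("screen: group means and selective hit calling")
            path = out / "screen.csv"
            _require(path, stage)
            screen_df = pd.read_csv(path).set_index("compound")
            groups = pd.read_csv(out / "lines.csv").set_index("cell_line")["group"]
            hits = sc.call_selective_hits(sc.group_mean_viability(screen_df, groups))
            tio.write_table(hits, out / "hits.csv")

        stage = "dose-response"
        if "dose-response" in config.stages:
            log.info("dose-response: 4PL IC50 fit")
            path = out / "dose_response.csv"
            _require(path, stage)
            dr = tio.read_dose_response_csv(path)
            fit = sc.fit_four_pl(dr["dose_uM"], dr["viability_pct"])
            tio.write_json(
                {
                    "top": fit.top,
                    "bottom": fit.bottom,
                    "ic50_uM": fit.ic50,
                    "hill": fit.hill,
                    "rss": fit.rss,
                    "converged": fit.converged,
                    "no_fit": fit.no_fit,
                },
                out / "dose_fit.json",
            )

        stage = "survival"
        if "survival" in config.stages:
            log.info("survival: quartile strata, KM, log-rank, HR")
            p = config.survival
            path = out / "survival.csv"
            _require(path, stage)
            surv = tio.read_survival_csv(path)
            genes = p.get("genes", ["ACTA2", "TAGLN", "TPM2"])
            score = sv.average_gene_expression(surv, genes)
            strata = sv.trichotomize(score, rule=p.get("split", "quartile_trichotomy"))
            chi2, pval = sv.logrank(surv, strata)
            hr = sv.hazard_ratio(surv, strata)
            tio.write_json(
                {
                    "n_low": int((strata.strata == "low").sum()),
                    "n_high": int((strata.strata == "high").sum()),
                    "logrank_chi2": chi2,
                    "logrank_p": pval,
                    "hr": hr.hr,
                    "hr_ci": [hr.ci_low, hr.ci_high],
                },
                out / "km.json",
            )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with the stage name
        raise StageError(stage, exc) from exc

    manifest = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _require(path: Path, stage: str) -> None:
    if not path.exists():
        raise StageError(stage, FileNotFoundError(f"missing input file: {path}"))
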