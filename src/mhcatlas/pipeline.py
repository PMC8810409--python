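"""End-to-end orchestration of the atlas analysis.

A single :class:`RunConfig` (YAML-loadable) drives either simulation or
loading of inputs, then the stages in dependency order: binder filtering,
landscape summaries, allele enrichment, expression linkage, universal
selection with conservation scoring, and the proteome screen. Each run
emits a machine-readable JSON report with per-stage row counts, fractions,
flags and the seed; identical configs reproduce identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conservation as cons
from . import enrichment as enr
from . import io as mio
from . import landscape as land
from . import linkage as link
from . import screen as scr
from .simulate import CohortConfig, generate_cohort, write_cohort
from .types import ConfigurationError

logger = logging.getLogger("mhcatlas")

try:
    __version__ = version("mhcatlas")
except PackageNotFoundError:  # pragma: no cover - source tree without install
    __version__ = "unknown"


@dataclass
class RunConfig:
    outdir: str = "mhcatlas_run"
    species_mode: str = "human"
    seed: int = 0
    simulate: bool = True
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    # alternatively, explicit input paths
    peptides: str | None = None
    expression: str | None = None
    proteins: str | None = None
    genes: str | None = None
    conservation: str | None = None
    # stage parameters
    rank_max: float = 2.0
    min_len: int = 8
    max_len: int = 12
    enrichment_mode: str = "exclusive"
    enrichment_threshold: float = 1.5
    min_tissues_per_donor: int = 14
    top_k: int = 100
    window: int = 12
    r2_min: float = 0.4
    p_max: float = 0.01
    min_pairs: int = 10
    min_subjects: int = 2
    n_permutations: int = 0  # 0 skips permutation calibration

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown run-config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("peptides",):
                p = getattr(self, name)
                if not p or not Path(p).exists():
                    raise ConfigurationError(f"input path {name!r} missing: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written to disk).

    A failing stage is recorded as failed and its dependents are skipped;
    the report's ``status`` is then "failed".
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "species_mode": config.species_mode,
        "stages": {},
    }
    state: dict = {}

    def stage(name, func, requires=()):
        missing = [r for r in requires if r not in state]
        if missing:
            report["stages"][name] = {
                "status": "skipped",
                "reason": f"missing inputs: {missing}",
            }
            return
        try:
            entry = func()
        except Exception as exc:  # deliberate broad catch: report and continue
            logger.exception("stage %s failed", name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            return
        entry["status"] = "ok"
        report["stages"][name] = entry

    # ---- inputs ----------------------------------------------------------
    def _load():
        if config.simulate:
            overrides = dict(config.cohort)
            overrides.setdefault("seed", config.seed)
            overrides.setdefault("species_mode", config.species_mode)
            if config.species_mode == "mouse":
                cc = CohortConfig.mouse(**{k: v for k, v in overrides.items() if k != "species_mode"})
            else:
                cc = CohortConfig(**overrides)
            catalog, expression, proteins, models, track, truth = generate_cohort(cc)
            write_cohort(outdir / "cohort", catalog, expression, proteins, models, track, truth, cc)
            state.update(
                catalog=catalog, expression=expression, proteins=proteins,
                models=models, track=track, truth=truth,
            )
            return {"n_observations": len(catalog), "simulated": True}
        state["catalog"] = mio.read_peptide_table(config.peptides, config.species_mode)
        if config.expression:
            state["expression"] = mio.read_matrix(config.expression, "expression")
        if config.proteins:
            state["proteins"] = mio.read_matrix(config.proteins, "protein")
        if config.genes:
            state["models"] = mio.read_gene_models(config.genes)
        if config.conservation:
            state["track"] = mio.read_conservation(config.conservation)
        return {"n_observations": len(state["catalog"]), "simulated": False}

    stage("load", _load)

    def _filter():
        filtered = land.filter_binders(
            state["catalog"], config.min_len, config.max_len, config.rank_max
        )
        state["filtered"] = filtered
        return {"n_observations": len(filtered), "n_peptides": len(filtered.peptides)}

    stage("filter", _filter, requires=("catalog",))

    def _landscape():
        f = state["filtered"]
        counts = land.count_per_tissue(f)
        conn = land.connectivity(f)
        conn.to_csv(outdir / "connectivity.tsv", sep="\t")
        part = land.partition_specificity(f)
        entry = {
            "counts_per_tissue": counts.to_dict(),
            "tissue_specific_percent": part.tissue_specific_percent,
            "shared_all_percent": part.shared_core_percent,
        }
        if len(f.tissues) >= 3 and len(f.peptides) >= 2:
            coords, shares = land.pca_tissues(f)
            coords.to_csv(outdir / "pca_tissues.tsv", sep="\t")
            entry["pca_explained"] = [float(s) for s in shares[:2]]
            entry["pca_scaled"] = True
        b = land.breadth_vs_property(f)
        b["table"].to_csv(outdir / "breadth.tsv", sep="\t", index=False)
        entry["rho_breadth_intensity"] = b["rho_intensity"]
        entry["rho_breadth_rank"] = b["rho_rank"]
        state["counts"] = counts
        return entry

    stage("landscape", _landscape, requires=("filtered",))

    def _enrichment():
        f = state["filtered"]
        tables = [
            enr.enrichment(enr.allele_shares(f, s), mode=config.enrichment_mode)
            for s in f.subjects
        ]
        agg = enr.average_and_flag(tables, threshold=config.enrichment_threshold)
        agg.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        entry = enr.summarize_flags(agg)
        entry["mode"] = config.enrichment_mode
        state["enrichment"] = agg
        return entry

    stage("enrichment", _enrichment, requires=("filtered",))

    def _linkage():
        res = link.classify_genes(state["filtered"], state["expression"])
        res["table"].to_csv(outdir / "gene_classes.tsv", sep="\t")
        z, flags = link.zscore_matrix(state["filtered"], state["expression"])
        z.to_csv(outdir / "zscore_matrix.tsv", sep="\t")
        return {
            "class_counts": res["table"]["primary_label"].value_counts().to_dict(),
            "unmapped_fraction": res["unmapped_fraction"],
            "zero_sd_rows": flags,
        }

    stage("linkage", _linkage, requires=("filtered", "expression"))

    def _universal():
        f = state["filtered"]
        sel = cons.select_universal(
            f,
            config.species_mode,
            min_tissues_per_donor=config.min_tissues_per_donor,
            top_k=config.top_k,
        )
        sel.criteria.to_csv(outdir / "universal_peptides.tsv", sep="\t")
        state["universal"] = sel
        return {
            "n_universal": len(sel.peptides),
            "universal_percent": sel.percent,
            "n_source_genes": len(sel.source_genes),
        }

    stage("universal", _universal, requires=("filtered",))

    def _conservation():
        f = state["filtered"]
        sel = state["universal"]
        models = {m.gene_id: m for m in state["models"]}
        part = land.partition_specificity(f)
        ts_genes = cons._source_genes_of(f, part.tissue_specific) - sel.source_genes
        uni_models = [models[g] for g in sorted(sel.source_genes) if g in models]
        ts_models = [models[g] for g in sorted(ts_genes) if g in models]
        su = cons.score_genes(state["track"], uni_models, window=config.window)
        st = cons.score_genes(state["track"], ts_models, window=config.window)
        frames = [
            f
            for f in (su.assign(group="universal"), st.assign(group="tissue_specific"))
            if len(f)
        ]
        pd.concat(frames).to_csv(outdir / "conservation_scores.tsv", sep="\t", index=False)
        res = cons.compare_conservation(su, st)
        return {
            feat: {
                "p_value": r["p_value"],
                "median_difference": r["median_difference"],
                "n_universal": r["n_universal"],
                "n_tissue_specific": r["n_tissue_specific"],
            }
            for feat, r in res.items()
        }

    stage("conservation", _conservation, requires=("filtered", "universal", "models", "track"))

    def _screen():
        f = state["filtered"]
        sc = scr.ScreenConfig(
            r2_min=config.r2_min,
            p_max=config.p_max,
            min_pairs=config.min_pairs,
            min_subjects=config.min_subjects,
        )
        if config.species_mode == "mouse":
            counts = {"mouse": land.count_per_tissue(f).astype(float)}
            mode = "mouse"
        else:
            counts = {
                s: land.count_per_tissue(f, subject=s).astype(float) for s in f.subjects
            }
            mode = "human"
        res = scr.run_screen(state["proteins"], counts, sc, mode=mode)
        res["fits"].to_csv(outdir / "screen_fits.tsv", sep="\t", index=False)
        entry = {
            "n_hits": res["n_hits"],
            "n_positive": res["n_positive"],
            "n_negative": res["n_negative"],
            "positive_fraction": res["positive_fraction"],
        }
        if config.n_permutations:
            cal = scr.calibrate_fp(
                state["proteins"],
                next(iter(counts.values())),
                n_permutations=config.n_permutations,
                seed=config.seed,
                config=sc,
            )
            entry["calibration"] = cal
        state["screen"] = res
        return entry

    stage("screen", _screen, requires=("filtered", "proteins"))

    failed = any(s.get("status") == "failed" for s in report["stages"].values())
    report["status"] = "failed" if failed else "ok"
    (outdir / "run_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonable) + "\n"
    )
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, tuple)):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
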