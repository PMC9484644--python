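"""One-command orchestration: QC -> ROH -> Froh -> summaries -> associations.

The pipeline is configured by a plain mapping (usually loaded from
YAML).  Exactly one of an ``input`` block (ped/map/phenotypes/ptas
paths) or a ``simulate`` block (synthetic-cohort parameters) must be
present.  All outputs are TSV/JSON under the output directory, every
random draw is routed through the configured seed, and the run log
carries no timestamps, so re-running an identical config reproduces
byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .assoc import AssocConfig, build_grm, fit_trait_class_models, pta_regression
from .detect import ROHParams, call_roh
from .io import read_plink, write_plink, write_roh_table
from .qc import QCThresholds, apply_qc
from .simulate import (
    ChromSpec,
    EffectTemplate,
    SegmentLengthDist,
    SimConfig,
    TraitEffects,
    simulate_genotypes,
    simulate_marker_map,
    simulate_phenotypes,
)
from .summaries import (
    SCHEMES,
    bin_by_length,
    compute_froh,
    distinct_to_frame,
    group_identical_roh,
    per_animal_summary,
    per_chromosome_summary,
)

logger = logging.getLogger(__name__)

OUTPUT_FILES = [
    "qc_report.tsv",
    "roh.tsv",
    "froh.tsv",
    "length_classes.tsv",
    "chromosome_summary.tsv",
    "distinct_roh.tsv",
    "assoc_pta.tsv",
    "assoc_mme.tsv",
    "run_log.txt",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    outdir: Path
    seed: int
    input_paths: dict[str, str] | None = None
    sim: SimConfig | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    roh: ROHParams = field(default_factory=ROHParams)
    schemes: tuple[str, ...] = ("table2", "model")
    assoc: AssocConfig = field(default_factory=AssocConfig)
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        if ("input" in d) == ("simulate" in d):
            raise ValueError("config must contain exactly one of 'input' or 'simulate'")
        seed = int(d.get("seed", 0))
        sim = None
        input_paths = None
        if "simulate" in d:
            sim = _sim_from_dict(dict(d["simulate"]), default_seed=seed)
        else:
            input_paths = dict(d["input"])
            for key in ("ped", "map", "phenotypes", "ptas"):
                if key not in input_paths:
                    raise ValueError(f"input block missing {key!r}")
        qc = QCThresholds(**d.get("qc", {}))
        roh = ROHParams(**d.get("roh", {}))
        assoc_d = dict(d.get("assoc", {}))
        if "traits" in assoc_d:
            assoc_d["traits"] = tuple(assoc_d["traits"])
        if "lambda" in assoc_d:
            assoc_d["lambda_"] = assoc_d.pop("lambda")
        assoc = AssocConfig(**assoc_d)
        schemes = tuple(d.get("schemes", ("table2", "model")))
        for s in schemes:
            if s not in SCHEMES:
                raise ValueError(f"unknown length-class scheme {s!r}")
        return cls(
            outdir=Path(d.get("outdir", "rohpipe_out")),
            seed=seed,
            input_paths=input_paths,
            sim=sim,
            qc=qc,
            roh=roh,
            schemes=schemes,
            assoc=assoc,
            log_level=str(d.get("log_level", "INFO")),
            raw=d,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sim_from_dict(d: dict, default_seed: int) -> SimConfig:
    d.setdefault("seed", default_seed)
    if "chromosomes" in d:
        d["chromosomes"] = tuple(
            ChromSpec(int(c["chrom"]), int(c["length_bp"]), int(c["n_markers"]))
            for c in d["chromosomes"]
        )
    if "segment_length" in d:
        d["segment_length"] = SegmentLengthDist(**d["segment_length"])
    if "trait_effects" in d:
        d["trait_effects"] = {k: TraitEffects(**v) for k, v in d["trait_effects"].items()}
    if "planted_roh_effects" in d:
        d["planted_roh_effects"] = tuple(
            EffectTemplate(**t) for t in d["planted_roh_effects"]
        )
    for key in ("allele_freq_range", "age_range_months"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)


def _setup_run_log(outdir: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("rohpipe")
    root.setLevel(level.upper())
    root.addHandler(handler)
    return handler


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the full analysis and write all outputs under ``cfg.outdir``."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_log(out, cfg.log_level)
    stage = "setup"
    try:
        stage = "load"
        truth = None
        if cfg.sim is not None:
            marker_map = simulate_marker_map(cfg.sim)
            ds, truth = simulate_genotypes(marker_map, cfg.sim)
        else:
            ds = read_plink(cfg.input_paths["ped"], cfg.input_paths["map"])
        logger.info("loaded %d animals x %d markers", ds.n_animals, ds.n_markers)

        stage = "qc"
        ds_qc, report = apply_qc(ds, cfg.qc)
        report.to_tsv(out / "qc_report.tsv")
        (out / "qc_summary.json").write_text(json.dumps(report.summary(), indent=2) + "\n")

        stage = "call"
        rohset = call_roh(ds_qc, cfg.roh)
        write_roh_table(rohset, out / "roh.tsv")

        stage = "froh"
        froh = compute_froh(rohset, ds_qc.markers)
        froh.table.to_csv(out / "froh.tsv", sep="\t", index=False)

        stage = "summarize"
        frames = []
        for name in cfg.schemes:
            f = bin_by_length(rohset, SCHEMES[name])
            f.insert(0, "scheme", name)
            frames.append(f)
        pd.concat(frames, ignore_index=True).to_csv(
            out / "length_classes.tsv", sep="\t", index=False
        )
        per_chromosome_summary(rohset, ds_qc.markers).to_csv(
            out / "chromosome_summary.tsv", sep="\t", index=False
        )
        per_animal, pop = per_animal_summary(rohset)
        per_animal.to_csv(out / "animal_summary.tsv", sep="\t", index=False)
        distinct, group_counts = group_identical_roh(rohset)
        distinct_to_frame(distinct).to_csv(out / "distinct_roh.tsv", sep="\t", index=False)

        stage = "phenotypes"
        if cfg.sim is not None:
            ph, pta, truth = simulate_phenotypes(ds_qc, truth, froh, cfg.sim)
        else:
            ph = pd.read_csv(cfg.input_paths["phenotypes"], sep="\t", dtype={"cow_id": str})
            pta = pd.read_csv(cfg.input_paths["ptas"], sep="\t", dtype={"animal_id": str})

        stage = "assoc"
        pta_res = pta_regression(pta, distinct, min_carriers=cfg.assoc.min_carriers)
        pta_res.to_csv(out / "assoc_pta.tsv", sep="\t", index=False)
        G = build_grm(ds_qc)
        mme_res = fit_trait_class_models(
            ph, froh, distinct, config=cfg.assoc, G=G, grm_animal_ids=list(ds_qc.animal_ids)
        )
        mme_res.to_csv(out / "assoc_mme.tsv", sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "rohpipe_version": __version__,
            "seed": cfg.seed,
            "config": _jsonable(cfg.raw),
            "n_animals_post_qc": ds_qc.n_animals,
            "n_markers_post_qc": ds_qc.n_markers,
            "n_roh": len(rohset),
            "n_distinct_roh": len(distinct),
            "group_counts": group_counts,
            "population_summary": pop,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as err:  # noqa: BLE001 - rewrap with the stage name
        raise PipelineError(stage, err) from err
    finally:
        handler.close()
        logging.getLogger("rohpipe").removeHandler(handler)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_simulated_inputs(cfg: SimConfig, outdir: str | Path) -> Path:
    """Materialise a synthetic cohort as PED/MAP + phenotype/PTA TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    marker_map = simulate_marker_map(cfg)
    ds, truth = simulate_genotypes(marker_map, cfg)
    write_plink(ds, out / "genotypes.ped", out / "genotypes.map")
    ph, pta, truth = simulate_phenotypes(ds, truth, truth.to_froh_table(), cfg)
    ph.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    pta.to_csv(out / "ptas.tsv", sep="\t", index=False)
    rows = [
        {"animal_id": a, "chrom": c, "start_bp": s, "end_bp": e}
        for a in truth.animal_ids
        for c, s, e in truth.segments[a]
    ]
    pd.DataFrame(rows, columns=["animal_id", "chrom", "start_bp", "end_bp"]).to_csv(
        out / "truth_segments.tsv", sep="\t", index=False
    )
    return out
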