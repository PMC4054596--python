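"""End-to-end orchestration: calibrate, test, bootstrap, map, render.

The stages mirror the method's flow: (1) calibrate each tetramer's h_min
on the pooled flanking sequence of all monitored exons; (2) score every
(event, region, tetramer) for cluster instances; (3) one-tailed Fisher
tests vs controls with BH correction and a bootstrap achieved
significance level; (4) retain tetramers passing both thresholds in some
region; (5) compute the positional ES matrix over the four junction
windows for the retained tetramers, group/sort them and render the RNA
splicing map.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster_calling import calibrate_h_min
from .genome_io import load_exon_events, load_genome
from .motif_space import enumerate_tetramers
from .positional_map import (
    ESMatrix,
    TetramerGroup,
    build_junction_pool,
    compute_es_matrix,
    group_tetramers,
    groups_to_frame,
)
from .region_enrichment import (
    BootstrapConfig,
    enrichment_analysis,
    region_occurrence_matrices,
    retained_tetramer_names,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome: str = ""
    events: str = ""
    outdir: str = "rnamotifs_out"
    window: int = 31
    min_h: int = 4
    max_h: int = 31
    coverage_target: float = 0.5
    fdr_threshold: float = 0.1
    empirical_threshold: float = 0.0005
    n_bootstrap: int = 10000
    seed: int = 0
    bootstrap_scheme: str = "pooled"
    map_intronic: int = 200
    map_exonic: int = 50
    top_k_render: int = 10
    render: bool = True

    def __post_init__(self):
        for name in ("fdr_threshold", "empirical_threshold", "coverage_target"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


def load_config(path) -> dict:
    """Parse a flat key = value config file (``#`` comments allowed)."""
    out = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = val
    return out


def config_from_file(path, **overrides) -> RunConfig:
    raw = load_config(path)
    kwargs = {}
    for f_ in RunConfig.__dataclass_fields__.values():
        if f_.name in raw:
            v = raw[f_.name]
            if f_.type in ("int", int):
                v = int(v)
            elif f_.type in ("float", float):
                v = float(v)
            elif f_.type in ("bool", bool):
                v = v.lower() in ("1", "true", "yes")
            kwargs[f_.name] = v
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**kwargs)


@dataclass
class RunResult:
    config: RunConfig
    hmin_table: pd.DataFrame
    enrichment: pd.DataFrame
    retained: list[str]
    es_matrix: ESMatrix
    groups: list[TetramerGroup]
    outputs: dict = field(default_factory=dict)


def run_pipeline(cfg: RunConfig) -> RunResult:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings = {}

    def _stage(name):
        timings[name] = round(time.time() - t0, 2)
        logger.info("stage done: %s (%.1fs)", name, timings[name])

    try:
        genome = load_genome(cfg.genome)
        events = load_exon_events(cfg.events)
    except Exception as exc:
        raise RuntimeError(f"input stage failed: {exc}") from exc
    n_by_class = {c: sum(e.reg_class == c for e in events) for c in ("enhanced", "silenced", "control")}
    for c, n in n_by_class.items():
        if n == 0:
            raise ValueError(f"no {c} events")

    tetramers = enumerate_tetramers()
    try:
        hmin = calibrate_h_min(events, genome, tetramers, target=cfg.coverage_target, window=cfg.window)
    except Exception as exc:
        raise RuntimeError(f"calibration stage failed: {exc}") from exc
    _stage("calibration")

    try:
        occ = region_occurrence_matrices(events, genome, hmin, window=cfg.window)
        bcfg = BootstrapConfig(n_samples=cfg.n_bootstrap, seed=cfg.seed, scheme=cfg.bootstrap_scheme)
        enr = enrichment_analysis(
            occ, bcfg, fdr_threshold=cfg.fdr_threshold,
            empirical_threshold=cfg.empirical_threshold,
        )
    except Exception as exc:
        raise RuntimeError(f"enrichment stage failed: {exc}") from exc
    retained = retained_tetramer_names(enr)
    _stage("enrichment")

    try:
        pool = build_junction_pool(
            events, genome, intronic=cfg.map_intronic, exonic=cfg.map_exonic, window=cfg.window
        )
        es = compute_es_matrix(pool, hmin, retained)
        groups = group_tetramers(es)
    except Exception as exc:
        raise RuntimeError(f"map stage failed: {exc}") from exc
    _stage("map")

    outputs = {}
    hmin_df = hmin.to_frame()
    outputs["hmin"] = outdir / "hmin.tsv"
    hmin_df.to_csv(outputs["hmin"], sep="\t", index=False)
    outputs["enrichment"] = outdir / "enrichment.tsv"
    enr.to_csv(outputs["enrichment"], sep="\t", index=False)
    outputs["retained"] = outdir / "retained.tsv"
    enr.loc[enr["retained"]].to_csv(outputs["retained"], sep="\t", index=False)
    outputs["es_matrix"] = outdir / "es_matrix.tsv"
    es.to_frame(cfg.map_intronic, cfg.map_exonic).to_csv(outputs["es_matrix"], sep="\t", index=False)
    outputs["groups"] = outdir / "groups.tsv"
    groups_to_frame(groups).to_csv(outputs["groups"], sep="\t", index=False)

    if cfg.render:
        try:
            from .render import render_map

            outputs["map_svg"] = outdir / "splicing_map.svg"
            outputs["map_png"] = outdir / "splicing_map.png"
            render_map(es, groups, enr, cfg, outputs["map_svg"])
            render_map(es, groups, enr, cfg, outputs["map_png"])
        except Exception as exc:
            raise RuntimeError(f"render stage failed: {exc}") from exc
    _stage("outputs")

    import scipy

    log = {
        "config": asdict(cfg),
        "versions": {"rnamotifs": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
        "n_events": n_by_class,
        "n_retained": len(retained),
        "retained": retained,
        "timings_s": timings,
    }
    outputs["run_log"] = outdir / "run_log.json"
    Path(outputs["run_log"]).write_text(json.dumps(log, indent=2))

    return RunResult(
        config=cfg, hmin_table=hmin_df, enrichment=enr, retained=retained,
        es_matrix=es, groups=groups, outputs={k: str(v) for k, v in outputs.items()},
    )
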