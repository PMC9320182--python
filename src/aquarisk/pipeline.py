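"""Pipeline orchestration: campaign -> indices -> risk -> MC -> stats -> maps.

Each stage reads only its inputs (no stage mutates the campaign), writes its
CSV/JSON artifacts into the output directory and registers them in a manifest
carrying the package version, a config hash, the seed and a SHA-256 checksum
per file.  Stage failures are recorded in the manifest and independent stages
continue.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .campaign import (
    CampaignConfig,
    WaterSample,
    generate_campaign,
    read_campaign,
    samples_to_frame,
    write_campaign,
)
from .indices import group_indices, index_table
from .mapping import GridSpec, build_surface
from .montecarlo import fit_input_distributions, run_mc
from .reference import CARCINOGENS, DEFAULT_AUTHORITY, METALS
from .risk import risk_table
from .stats import cluster_metals, correlation_long, correlation_matrix, describe_table

log = logging.getLogger("aquarisk")

ALL_STAGES = ("simulate", "indices", "risk", "mc", "stats", "map")


@dataclass
class RunConfig:
    """What to run, on what input, with which knobs."""

    output_dir: str | Path = "aquarisk_out"
    input_csv: str | Path | None = None  # None -> synthetic campaign
    stages: Sequence[str] = ALL_STAGES
    authority: str = DEFAULT_AUTHORITY
    cohorts: Sequence[str] = ("adult", "child")
    seed: int = 0
    campaign: CampaignConfig | None = None
    mc_n_iter: int = 10_000
    mc_metals: Sequence[str] = CARCINOGENS
    map_index: str = "mpi"
    map_grid_n: int = 40
    map_n_hidden: int = 5
    map_n_particles: int = 20
    map_n_iterations: int = 150

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if not self.stages:
            raise ValueError("at least one stage must be enabled")

    def config_hash(self) -> str:
        # output location does not alter the analysis
        fields = {
            k: str(v)
            for k, v in dataclasses.asdict(self).items()
            if k != "output_dir"
        }
        blob = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "package": "aquarisk",
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stages": {},
            "files": [],
        }

    def register(self, path: Path) -> None:
        self.manifest["files"].append(
            {"path": str(path.relative_to(self.outdir)), "sha256": _sha256(path)}
        )

    def write_frame(self, df: pd.DataFrame, name: str) -> Path:
        path = self.outdir / name
        df.to_csv(path, index=False)
        self.register(path)
        return path

    def write_json(self, obj, name: str) -> Path:
        path = self.outdir / name
        path.write_text(json.dumps(obj, indent=1, default=float), encoding="utf-8")
        self.register(path)
        return path


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages; return the artifact manifest (also written to
    ``manifest.json``).  Deterministic given the seed."""
    run = PipelineRun(config)
    stages = list(config.stages)

    # --- input ---------------------------------------------------------
    samples: list[WaterSample]
    if config.input_csv is not None:
        samples = read_campaign(config.input_csv)
        run.manifest["input"] = str(config.input_csv)
    else:
        camp = config.campaign or CampaignConfig(seed=config.seed)
        if config.campaign is None:
            camp.seed = config.seed
        samples = generate_campaign(camp)
        if "simulate" in stages:
            path = run.outdir / "campaign.csv"
            write_campaign(samples, path, seed=camp.seed)
            run.register(path)
            run.register(path.with_suffix(".csv.meta.json"))
            run.manifest["stages"]["simulate"] = "ok"
    df = samples_to_frame(samples)

    def stage(name, fn):
        if name not in stages:
            return
        try:
            fn()
            run.manifest["stages"][name] = "ok"
        except Exception as exc:  # independent stages continue
            log.error("stage %s failed: %s", name, exc)
            run.manifest["stages"][name] = f"failed: {exc}"

    # --- indices -------------------------------------------------------
    idx_df: pd.DataFrame | None = None

    def _indices():
        nonlocal idx_df
        idx_df = index_table(samples, config.authority)
        run.write_frame(idx_df, "indices.csv")
        run.write_frame(group_indices(samples, config.authority), "indices_groups.csv")

    stage("indices", _indices)

    # --- risk ----------------------------------------------------------
    def _risk():
        run.write_frame(risk_table(samples, config.cohorts, mode="group"),
                        "risk_groups.csv")
        run.write_frame(risk_table(samples, config.cohorts, mode="sample"),
                        "risk_samples.csv")

    stage("risk", _risk)

    # --- Monte Carlo ---------------------------------------------------
    def _mc():
        reports = []
        for cohort in config.cohorts:
            for metal in config.mc_metals:
                conc = [s.conc[metal] for s in samples]
                specs = fit_input_distributions(conc, cohort, metal=metal)
                summ = run_mc(specs, metal, cohort,
                              n_iter=config.mc_n_iter, seed=config.seed)
                reports.append(summ.to_dict())
        run.write_json(reports, "mc_report.json")

    stage("mc", _mc)

    # --- stats ---------------------------------------------------------
    def _stats():
        variables = ["temperature_C", "pH", "EC_uScm", "TDS_ppm"] + [
            f"{m}_mgL" for m in METALS
        ]
        run.write_frame(describe_table(df, variables, group_col="source_type"),
                        "descriptives.csv")
        metal_cols = [f"{m}_mgL" for m in METALS]
        for src, gdf in df.groupby("source_type", sort=False):
            r, p = correlation_matrix(gdf, variables)
            run.write_frame(r.reset_index(names="variable"), f"correlation_{src}.csv")
            run.write_frame(correlation_long(r, p), f"correlation_{src}_long.csv")
            try:
                tree = cluster_metals(gdf, metal_cols)
                run.write_frame(tree.to_frame().assign(
                    labels=",".join(tree.labels)), f"linkage_{src}.csv")
            except ValueError as exc:
                log.warning("clustering skipped for %s: %s", src, exc)

    stage("stats", _stats)

    # --- mapping -------------------------------------------------------
    def _map():
        nonlocal idx_df
        if idx_df is None:
            idx_df = index_table(samples, config.authority)
        xy = df[["x", "y"]].to_numpy()
        vals = idx_df[config.map_index].to_numpy(dtype=float)
        x0, y0 = xy[:, 0].min(), xy[:, 1].min()
        span = max(xy[:, 0].max() - x0, xy[:, 1].max() - y0)
        cell = span / config.map_grid_n
        spec = GridSpec(x0, y0, cell, config.map_grid_n, config.map_grid_n)
        surf = build_surface(
            xy, vals, spec,
            n_hidden=config.map_n_hidden,
            n_particles=config.map_n_particles,
            n_iterations=config.map_n_iterations,
            seed=config.seed,
        )
        run.write_frame(surf.to_frame(), f"surface_{config.map_index}.csv")
        run.write_json(surf.to_geojson(), f"surface_{config.map_index}.geojson.json")

    stage("map", _map)

    run.write_json(run.manifest, "manifest.json")
    return run.manifest
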