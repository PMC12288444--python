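"""End-to-end orchestration: simulate | cluster | preprocess | fit | summarise.

Each stage reads/writes flat files in an artifact directory and records a
manifest entry (config hash + completion marker), so re-running with the
same configuration skips completed stages. Identical config and seeds give
byte-identical summary values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as uio
from .clustering import Cluster, build_clusters, membership_map
from .design import build_design
from .dhglm import PosteriorDraws, check_convergence, sample_posterior
from .env import ToyRaster, attach_env
from .preprocess import (
    apply_conversions,
    dedupe_individuals,
    filter_outliers,
    select_first_clutches,
)
from .simulate import SimScenario, simulate_observations
from .summaries import habitat_variance_contrast, summarize_model
from .types import Habitat, RunConfig, Trait

logger = logging.getLogger("urbanvar")

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_done(out: Path, stage: str, chash: str) -> bool:
    marker = out / f".done_{stage}"
    return marker.exists() and marker.read_text().strip() == chash


def _mark_done(out: Path, stage: str, chash: str) -> None:
    (out / f".done_{stage}").write_text(chash + "\n")


def _clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "system_id": c.system_id,
                "habitat": c.habitat.value,
                "n_boxes": c.size,
                "area_km2": c.area_km2,
                "mean_lat": c.mean_lat,
                "years_studied": c.years_studied,
                "isa_100": c.env.isa_100,
                "isa_1000": c.env.isa_1000,
                "shannon_h": c.env.shannon_h,
                "mixed_fraction": c.mixed_fraction,
            }
            for c in clusters
        ]
    )


def _clusters_from_frames(attrs: pd.DataFrame, members: pd.DataFrame) -> list[Cluster]:
    by_cluster = members.groupby("cluster_id")["box_id"].apply(list)
    out = []
    for r in attrs.itertuples(index=False):
        c = Cluster(
            cluster_id=r.cluster_id,
            system_id=r.system_id,
            member_boxes=sorted(by_cluster[r.cluster_id]),
            habitat=Habitat(r.habitat),
            area_km2=r.area_km2,
            mean_lat=r.mean_lat,
            years_studied=int(r.years_studied),
        )
        c.env.isa_100, c.env.isa_1000, c.env.shannon_h = r.isa_100, r.isa_1000, r.shannon_h
        out.append(c)
    return out


def stage_simulate(config: RunConfig, out: Path, scenario: SimScenario | None = None) -> None:
    scenario = scenario or SimScenario(
        species=config.species, trait=config.trait, seed=config.sim_seed
    )
    sim = simulate_observations(scenario, seed=config.sim_seed)
    uio.write_boxes(sim.landscape.boxes, out / "boxes.csv")
    uio.write_observations(sim.observations, out / "observations.csv")
    for system_id, (isa_r, lc_r) in sim.landscape.rasters.items():
        isa_r.write_text(out / f"isa_{system_id}.txt")
        lc_r.write_text(out / f"landcover_{system_id}.txt")


def stage_cluster(config: RunConfig, out: Path) -> list[Cluster]:
    boxes = uio.read_boxes(out / "boxes.csv")
    by_system: dict[str, list] = {}
    for b in boxes:
        by_system.setdefault(b.system_id, []).append(b)
    clusters: list[Cluster] = []
    membership_rows = []
    for system_id in sorted(by_system):
        cl, unassigned = build_clusters(
            by_system[system_id],
            max_link_m=config.max_link_m,
            min_size=config.min_cluster_size,
            buffer_m=config.hull_buffer_m,
        )
        isa_path = out / f"isa_{system_id}.txt"
        lc_path = out / f"landcover_{system_id}.txt"
        if isa_path.exists() and lc_path.exists():
            attach_env(cl, by_system[system_id], ToyRaster.read_text(isa_path), ToyRaster.read_text(lc_path))
        clusters.extend(cl)
        for b in unassigned:
            logger.info("box %s unassigned (component below min size)", b.box_id)
    for c in clusters:
        for b in c.member_boxes:
            membership_rows.append({"box_id": b, "cluster_id": c.cluster_id})
    pd.DataFrame(membership_rows).to_csv(out / "cluster_membership.csv", index=False)
    _clusters_to_frame(clusters).to_csv(out / "cluster_attributes.csv", index=False, float_format="%.17g")
    return clusters


def stage_preprocess(config: RunConfig, out: Path) -> None:
    obs = uio.read_observations(out / "observations.csv", trait=config.trait)
    obs = [o for o in obs if o.species == config.species and o.trait == config.trait]
    members = pd.read_csv(out / "cluster_membership.csv", dtype=str)
    cluster_of_box = dict(zip(members.box_id, members.cluster_id))

    reports = []
    obs, rep = apply_conversions(obs)
    reports.append(rep)
    obs, rep = filter_outliers(obs, config.species, config.trait)
    reports.append(rep)
    if config.trait is Trait.LAY_DATE:
        obs, rep = select_first_clutches(obs, cluster_of_box)
        reports.append(rep)
    obs, rep = dedupe_individuals(obs, config.trait, seed=config.nestling_seed)
    reports.append(rep)
    uio.write_observations(obs, out / "model_ready.csv")
    uio.write_json([dataclasses.asdict(r) for r in reports], out / "filter_report.json")


def stage_fit(config: RunConfig, out: Path) -> PosteriorDraws:
    obs = uio.read_observations(out / "model_ready.csv", trait=config.trait)
    attrs = pd.read_csv(out / "cluster_attributes.csv")
    members = pd.read_csv(out / "cluster_membership.csv", dtype=str)
    clusters = _clusters_from_frames(attrs, members)
    data = build_design(
        obs,
        clusters,
        config.trait,
        config.urbanisation_mode,
        standardise_response=config.standardise_response,
    )
    draws = sample_posterior(data, config.mcmc, seed=config.seed)
    draws.save_csv(out / "draws.csv")
    report = check_convergence(draws)
    uio.write_json(report, out / "diagnostics.json")
    return draws


def stage_summarise(config: RunConfig, out: Path) -> None:
    draws = PosteriorDraws.load_csv(out / "draws.csv")
    # meta is not persisted in the CSV; reconstruct the term lists
    mean_names = [n[len("b_mean["):-1] for n in draws.names if n.startswith("b_mean[")]
    disp_names = [n[len("b_disp["):-1] for n in draws.names if n.startswith("b_disp[")]
    draws.meta.update({"mean_names": mean_names, "disp_names": disp_names})
    rows = summarize_model(draws)
    uio.write_summary_table(rows, out / "summary.csv")
    if config.urbanisation_mode == "categorical":
        contrast_rows = []
        for level in ("cluster_mean", "cluster_dispersion"):
            c = habitat_variance_contrast(draws, level)
            contrast_rows.append(
                {
                    "level": level,
                    "var_urban_mean": float(np.mean(c.var_urban)),
                    "var_forest_mean": float(np.mean(c.var_forest)),
                    "diff_mean": float(np.mean(c.diff)),
                    "ratio_of_means": float(np.mean(c.var_urban) / np.mean(c.var_forest)),
                    "pd": c.pd,
                    "hpdi95_lo": c.hpdi95_diff[0],
                    "hpdi95_hi": c.hpdi95_diff[1],
                    "evidence": c.evidence,
                }
            )
        pd.DataFrame(contrast_rows).to_csv(out / "variance_contrasts.csv", index=False, float_format="%.17g")


_STAGES = ("simulate", "cluster", "preprocess", "fit", "summarise")


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path | None = None,
    stages: tuple = _STAGES,
    scenario: SimScenario | None = None,
) -> Path:
    """Run the requested stages, resuming past completed ones.

    Returns the artifact directory. Any stage failure raises PipelineError
    naming the stage.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    chash = _config_hash(config)
    uio.write_json(
        {"config": dataclasses.asdict(config), "config_hash": chash},
        out / "manifest.json",
    )
    for stage in stages:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if _stage_done(out, stage, chash):
            logger.info("stage %s already complete; skipping", stage)
            continue
        logger.info("running stage %s", stage)
        try:
            if stage == "simulate":
                stage_simulate(config, out, scenario)
            elif stage == "cluster":
                stage_cluster(config, out)
            elif stage == "preprocess":
                stage_preprocess(config, out)
            elif stage == "fit":
                stage_fit(config, out)
            elif stage == "summarise":
                stage_summarise(config, out)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            logger.removeHandler(log_handler)
            raise PipelineError(stage, exc) from exc
        _mark_done(out, stage, chash)
    logger.removeHandler(log_handler)
    return out
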