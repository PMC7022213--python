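"""End-to-end orchestration: generate/load scenes, detect, quantify, test.

A run is described by a single configuration document (dict or YAML) whose
keys name every tunable of the underlying stages with its conventional
default: detection windows 200/15 px, cell-body k 0.75 within [0.5, 1],
spot k 2.5, area gates >500 and 7-200 px, eccentricity bounds 0.9/0.97,
assignment rule, CD31 co-labeling threshold, and the group-test plan at
alpha 0.05.  Identical config + seed reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detect import (CELL_K_DEFAULT, CELL_WINDOW, SPOT_K, SPOT_WINDOW,
                     detect_cells, detect_spots)
from .quantify import (AssignmentRule, CellRecord, assign_region,
                       build_cell_records, classify_endothelial,
                       records_to_frame, summarize_groups)
from .stats import group_compare
from .synth import SceneConfig, generate_scene, quantize_u16, write_scene


@dataclass
class RunConfig:
    """Configuration of a full synthetic-scene pipeline run."""

    seed: int = 0
    # group label -> SceneConfig field overrides (puncta means etc.)
    groups: dict[str, dict] = field(default_factory=lambda: {
        "CTRL": {"puncta_mean_per_cell": {"CD31": 5.0, "TARGET1": 4.0}},
        "SS": {"puncta_mean_per_cell": {"CD31": 5.0, "TARGET1": 4.0}},
        "RES": {"puncta_mean_per_cell": {"CD31": 5.0, "TARGET1": 2.4}},
    })
    scenes_per_group: int = 4
    scene: dict = field(default_factory=dict)  # shared SceneConfig overrides
    cells: dict = field(default_factory=lambda: {
        "window": CELL_WINDOW, "k": CELL_K_DEFAULT, "tiling_mode": "block"})
    # keep_at_most is the compact-object reading of the spot eccentricity
    # rule; required for Gaussian puncta (see docs/methods.md)
    spots: dict = field(default_factory=lambda: {
        "window": SPOT_WINDOW, "k": SPOT_K, "area": (7, 200),
        "ecc_bound": 0.97, "ecc_direction": "keep_at_most",
        "tiling_mode": "block"})
    assignment_method: str = "majority_overlap"
    min_cd31: int = 1
    stats_channel: str = "TARGET1"
    control_group: str = "CTRL"
    alpha: float = 0.05
    use_region_mask: bool = True
    max_bin: int = 8
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    counts: dict[str, int]
    warnings: list[str]
    timing_s: float


@dataclass
class PipelineResult:
    manifest: RunManifest
    cell_table: pd.DataFrame
    group_summaries: dict
    stats_report: dict | None
    unassigned: dict[str, int]
    detected: dict[str, int]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _scene_seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def _scene_config(run: RunConfig, group: str, seed: int) -> SceneConfig:
    overrides = dict(run.scene)
    overrides.update(run.groups[group])
    overrides["group_label"] = group
    overrides["seed"] = seed
    if "nucleus_axis_range" in overrides:
        overrides["nucleus_axis_range"] = tuple(
            overrides["nucleus_axis_range"])
    return SceneConfig(**overrides)


def process_scene(images: dict, region_mask, run: RunConfig,
                  ) -> tuple[list[CellRecord], dict[str, int], dict[str, int]]:
    """Detect + quantify one scene (already-quantized images)."""
    cells = detect_cells(images["DAPI"], **run.cells)
    clusters_by_channel = {}
    detected = {}
    for channel, img in images.items():
        if channel == "DAPI":
            continue
        spots = detect_spots(img, **{**run.spots,
                                     "area": tuple(run.spots["area"])})
        clusters_by_channel[channel] = spots
        detected[channel] = len(spots)
    records, unassigned = build_cell_records(
        cells, clusters_by_channel, AssignmentRule(run.assignment_method))
    classify_endothelial(records, min_cd31=run.min_cd31)
    assign_region(records, region_mask if run.use_region_mask else None)
    return records, unassigned, detected


CELL_TABLE_SCHEMA = ["scene_id", "cell_id", "group", "region",
                     "is_endothelial", "nucleus_area", "nucleus_ecc",
                     "nucleus_cy", "nucleus_cx"]


def _validate_cell_table(df: pd.DataFrame) -> None:
    missing = [c for c in CELL_TABLE_SCHEMA if c not in df.columns]
    if missing:
        raise PipelineError(f"stage quantify: cell table missing columns "
                            f"{missing}")
    extra = [c for c in df.columns if c not in CELL_TABLE_SCHEMA
             and not c.split("_", 1)[0] in ("count", "area", "intensity")]
    if extra:
        raise PipelineError(f"stage quantify: undocumented columns {extra}")


def run_pipeline(run: RunConfig) -> PipelineResult:
    """Execute generate -> detect -> quantify -> stats for every group."""
    t0 = time.perf_counter()
    caught: list[str] = []
    seeds = _scene_seeds(run.seed, len(run.groups) * run.scenes_per_group)
    frames = []
    unassigned_total: dict[str, int] = {}
    detected_total: dict[str, int] = {}
    records_by_group: dict[str, list[CellRecord]] = {g: []
                                                     for g in run.groups}
    out_dir = Path(run.out_dir) if run.out_dir else None
    i = 0
    for group in run.groups:
        for rep in range(run.scenes_per_group):
            scene_seed = seeds[i]
            i += 1
            cfg = _scene_config(run, group, scene_seed)
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                try:
                    truth, images, mask = generate_scene(cfg)
                except Exception as exc:  # noqa: BLE001
                    raise PipelineError(f"stage synth ({group}/{rep}): {exc}"
                                        ) from exc
                # detection consumes the 16-bit rasters, as on disk
                qimages = {ch: quantize_u16(im) for ch, im in images.items()}
                if out_dir is not None:
                    write_scene(truth, qimages, mask,
                                out_dir / f"scene_{group}_{rep}", cfg)
                try:
                    records, unassigned, detected = process_scene(
                        qimages, mask, run)
                except Exception as exc:  # noqa: BLE001
                    raise PipelineError(
                        f"stage detect/quantify ({group}/{rep}): {exc}"
                        ) from exc
            caught.extend(str(w.message) for w in wlist)
            for ch, n in unassigned.items():
                unassigned_total[ch] = unassigned_total.get(ch, 0) + n
            for ch, n in detected.items():
                detected_total[ch] = detected_total.get(ch, 0) + n
            records_by_group[group].extend(records)
            frames.append(records_to_frame(records, group=group,
                                           scene_id=f"{group}_{rep}"))
    cell_table = pd.concat(frames, ignore_index=True)
    _validate_cell_table(cell_table)

    summaries = summarize_groups(records_by_group, run.stats_channel,
                                 max_bin=run.max_bin)

    stats_report = None
    count_col = f"count_{run.stats_channel}"
    endo = cell_table[cell_table["is_endothelial"]]
    values = {g: endo.loc[endo["group"] == g, count_col].to_numpy(float)
              for g in run.groups}
    if all(len(v) >= 2 for v in values.values()) and len(values) >= 2:
        try:
            stats_report = group_compare(values, alpha=run.alpha)
        except ValueError as exc:
            caught.append(f"stats stage skipped: {exc}")
    else:
        caught.append("stats stage skipped: too few endothelial cells")

    manifest = RunManifest(
        config=run.to_dict(), version=__version__, seed=run.seed,
        counts={
            "scenes": len(run.groups) * run.scenes_per_group,
            "cells": int(len(cell_table)),
            **{f"clusters_{ch}": n for ch, n in detected_total.items()},
            **{f"unassigned_{ch}": n for ch, n in unassigned_total.items()},
        },
        warnings=caught, timing_s=time.perf_counter() - t0)

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        cell_table.to_csv(out_dir / "cells_quant.csv", index=False)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(dataclasses.asdict(manifest), fh, indent=2,
                      default=str)
        if stats_report is not None:
            with open(out_dir / "stats_report.json", "w") as fh:
                json.dump(stats_report, fh, indent=2, default=str)

    return PipelineResult(manifest=manifest, cell_table=cell_table,
                          group_summaries=summaries,
                          stats_report=stats_report,
                          unassigned=unassigned_total,
                          detected=detected_total)


FIXTURE_PROFILES = ("tiny", "default", "stress")


def make_fixtures(out_dir: str | Path, profile: str = "tiny",
                  seed: int = 1234) -> dict:
    """Write deterministic miniature scenes and tables for testing.

    tiny: a 64x64 scene with a handful of nuclei, done in seconds.
    default: one full-size scene per group.
    stress: writes (and returns) a deliberately overcrowded scene config
    that makes rejection sampling fail, for exercising the error path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if profile not in FIXTURE_PROFILES:
        raise ValueError(f"profile must be one of {FIXTURE_PROFILES}")
    info: dict = {"profile": profile, "seed": seed}
    if profile == "stress":
        crowded = SceneConfig(image_height=96, image_width=96, n_nuclei=40,
                              nucleus_axis_range=(12.0, 16.0),
                              max_place_attempts=50, seed=seed)
        path = out / "crowded_scene_config.json"
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(crowded), fh, indent=2)
        info["config_path"] = str(path)
        info["expect"] = "SceneCrowdingError"
        return info
    if profile == "tiny":
        cfg = SceneConfig(image_height=64, image_width=64, n_nuclei=4,
                          nucleus_axis_range=(5.0, 7.0),
                          puncta_mean_per_cell={"CD31": 2.0, "TARGET1": 2.0},
                          punctum_min_separation=6.0, seed=seed)
        truth, images, mask = generate_scene(cfg)
        write_scene(truth, images, mask, out / "scene_tiny", cfg)
        info["scenes"] = ["scene_tiny"]
        info["n_nuclei"] = len(truth.nuclei)
    else:
        run = RunConfig(seed=seed, scenes_per_group=1,
                        out_dir=str(out / "run_default"))
        result = run_pipeline(run)
        info["scenes"] = sorted(p.name for p in
                                (out / "run_default").glob("scene_*"))
        info["cells"] = int(result.manifest.counts["cells"])
    _write_toy_tables(out)
    info["tables"] = ["behavior.csv", "qpcr.csv", "genes.csv"]
    with open(out / "fixtures.json", "w") as fh:
        json.dump(info, fh, indent=2)
    return info


def toy_behavior_table() -> pd.DataFrame:
    """Behavior table with known SI phenotypes: SS, RES, an exact-boundary
    unclassified animal, and an unstressed CTRL."""
    return pd.DataFrame({
        "mouse_id": ["m1", "m2", "m3", "m4"],
        "time_present": [24.0, 96.0, 60.0, 80.0],
        "time_absent": [60.0, 60.0, 60.0, 50.0],
        "stressed": [True, True, True, False],
        "expected_phenotype": ["SS", "RES", "unclassified", "CTRL"],
    })


def toy_qpcr_table() -> pd.DataFrame:
    """qPCR table with a planted one-cycle shift: the SS group's dCt is one
    cycle below control, so its fold change is exactly 2."""
    rows = []
    for sid in ("c1", "c2", "c3"):
        rows.append({"sample_id": sid, "group": "CTRL", "gene": "cldn5",
                     "ct_gene": 24.0, "ct_housekeeping": 18.0})
    for sid in ("s1", "s2", "s3"):
        rows.append({"sample_id": sid, "group": "SS", "gene": "cldn5",
                     "ct_gene": 23.0, "ct_housekeeping": 18.0})
    return pd.DataFrame(rows)


def planted_gene_table(n_up: int = 30, n_down: int = 20, n_null: int = 950,
                       seed: int = 0) -> pd.DataFrame:
    """Gene table with planted up/down regulation: n_up genes at FC >= 2
    with p < 0.05, n_down at FC <= -2 with p < 0.05, and null genes whose
    p-values are drawn at or above 0.05 or whose |FC| is below 2."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_up):
        rows.append({"gene_id": f"up{i}",
                     "fold_change": float(rng.uniform(2.0, 8.0)),
                     "p_value": float(rng.uniform(1e-4, 0.049))})
    for i in range(n_down):
        rows.append({"gene_id": f"down{i}",
                     "fold_change": float(-rng.uniform(2.0, 8.0)),
                     "p_value": float(rng.uniform(1e-4, 0.049))})
    for i in range(n_null):
        if i % 2 == 0:
            fc = float(rng.uniform(1.01, 1.9) * rng.choice([-1, 1]))
            p = float(rng.uniform(1e-4, 1.0))
        else:
            fc = float(rng.uniform(1.01, 8.0) * rng.choice([-1, 1]))
            p = float(rng.uniform(0.05, 1.0))
        rows.append({"gene_id": f"null{i}", "fold_change": fc, "p_value": p})
    return pd.DataFrame(rows)


def _write_toy_tables(out: Path) -> None:
    toy_behavior_table().to_csv(out / "behavior.csv", index=False)
    toy_qpcr_table().to_csv(out / "qpcr.csv", index=False)
    planted_gene_table().to_csv(out / "genes.csv", index=False)
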