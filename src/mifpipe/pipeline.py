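"""End-to-end orchestration: group -> preprocess -> register -> segment ->
profile -> cluster, with resumable stage outputs.

Each stage writes its artifacts under the run directory together with a
content hash of its inputs and parameters; on re-runs a stage whose hash
matches and whose outputs exist is skipped. A stage failure stops the
pipeline and is recorded in the run report; downstream stages do not run.

Segmentation can run in three modes: train a network from ground-truth
label maps found next to the images, load a checkpoint, or bypass the
network entirely and feed ground-truth instance maps to profiling (used
to test profiling/clustering in isolation from training stochasticity).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import segmentation as seg
from .clustering import EmbeddingParams, cluster, cluster_profiles, \
    composition, embed, plot_cluster_heatmap, plot_embedding
from .dataset import DEFAULT_NAMING_PATTERN, CyclicDataset, group_images
from .errors import StageError
from .losses import LossWeights
from .network import ArchConfig, MultiTaskUNet
from .phenotypes import default_rules, load_rules
from .preprocess import preprocess_dataset
from .profiling import profile_cells
from .registration import RegistrationConfig, RegistrationResult, \
    align_cycle_set, align_dataset
from .synth import load_manifest


@dataclass
class PipelineConfig:
    input_dir: str = "."
    out_dir: str = "run"
    naming_pattern: str = DEFAULT_NAMING_PATTERN
    manifest_path: Optional[str] = None
    rules_path: Optional[str] = None

    # preprocessing
    p_low: float = 25.0
    p_high: float = 99.0
    gaussian_sigma: float = 1.0

    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    alignment_fov: int = 0

    # segmentation: exactly one of {train, checkpoint, ground-truth bypass}
    checkpoint: Optional[str] = None
    train: bool = False
    use_ground_truth_masks: bool = False
    cd45_marker: str = "CD45"
    dapi_marker: str = "DAPI"
    arch: ArchConfig = field(default_factory=ArchConfig)
    train_config: seg.TrainConfig = field(default_factory=seg.TrainConfig)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    min_cell_area: int = 10

    # profiling / clustering
    mad_k: float = 5.0
    threshold_method: str = "mean_minus_3sd"
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    min_cluster_size: Optional[int] = None
    supervised_umap: bool = False

    seed: int = 0

    def __post_init__(self):
        modes = sum([self.train, self.checkpoint is not None,
                     self.use_ground_truth_masks])
        if modes != 1:
            raise ValueError(
                "exactly one of train / checkpoint / use_ground_truth_masks "
                "must be selected for segmentation")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("registration", RegistrationConfig),
                         ("arch", ArchConfig),
                         ("train_config", seg.TrainConfig),
                         ("loss_weights", LossWeights),
                         ("embedding", EmbeddingParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)


def _hash_inputs(paths, params: str) -> str:
    h = hashlib.sha256(params.encode())
    for p in sorted(str(p) for p in paths):
        h.update(p.encode())
        h.update(Path(p).read_bytes())
    return h.hexdigest()


def _params_json(config: PipelineConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)
    return json.dumps(dataclasses.asdict(config), default=enc, sort_keys=True)


class _Stage:
    """Bookkeeping for one resumable stage."""

    def __init__(self, name: str, out_dir: Path, inputs, params: str):
        self.name = name
        self.hash_file = out_dir / f"{name}.hash"
        self.digest = _hash_inputs(inputs, params)

    def can_skip(self, outputs) -> bool:
        return (self.hash_file.exists()
                and self.hash_file.read_text() == self.digest
                and all(Path(o).exists() for o in outputs))

    def mark_done(self):
        self.hash_file.write_text(self.digest)


def run(config: PipelineConfig) -> Dict:
    """Execute the pipeline; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict = {"stages": {}, "failed_stage": None}
    t_start = time.time()

    try:
        _run_stages(config, out, report)
    except StageError as err:
        report["failed_stage"] = err.stage
        report["error"] = str(err)
    report["elapsed_s"] = round(time.time() - t_start, 2)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


def _stage_record(report, name, skipped=False, **info):
    rec = {"skipped": skipped, **info}
    report["stages"][name] = rec
    return rec


def _run_stages(config: PipelineConfig, out: Path, report: Dict) -> None:
    params = _params_json(config)
    input_dir = Path(config.input_dir)
    image_files = sorted(p for p in input_dir.glob("*.tif*"))

    # short-circuit: when every persisted stage is up to date, skip all
    reg_stage = _Stage("register", out, image_files, params)
    seg_stage = _Stage("segment", out, image_files, params)
    prof_stage = _Stage("profile", out, image_files, params)
    clus_stage = _Stage("cluster", out, image_files, params)
    existing_inst = sorted(out.glob("instances_f*.tif"))
    if (reg_stage.can_skip([out / "shifts.json"])
            and existing_inst and seg_stage.can_skip(existing_inst)
            and prof_stage.can_skip([out / "cells.csv"])
            and clus_stage.can_skip([out / "cells_clustered.csv",
                                     out / "composition.csv"])):
        for name in ("group", "preprocess", "register", "segment",
                     "profile", "cluster"):
            _stage_record(report, name, skipped=True)
        return

    # -- group + preprocess + register ------------------------------------
    try:
        manifest = load_manifest(config.manifest_path) \
            if config.manifest_path else None
        dataset, group_report = group_images(image_files,
                                             config.naming_pattern,
                                             manifest=manifest)
    except Exception as e:
        raise StageError("group", str(e)) from e
    _stage_record(report, "group", n_matched=group_report.n_matched,
                  n_skipped=len(group_report.skipped),
                  n_fovs=dataset.n_fovs, n_cycles=dataset.n_cycles,
                  n_channels=dataset.n_channels)

    pre = preprocess_dataset(dataset, config.p_low, config.p_high,
                             config.gaussian_sigma)
    _stage_record(report, "preprocess",
                  n_images=len(pre.images))

    shifts_path = out / "shifts.json"
    stage = reg_stage
    try:
        if stage.can_skip([shifts_path]):
            reg = RegistrationResult.from_json(shifts_path)
            _stage_record(report, "register", skipped=True)
        else:
            reg = align_cycle_set(pre, config.alignment_fov,
                                  config.registration)
            # retry failed cycles with the remaining FOVs
            retried_with = []
            for fov in range(dataset.n_fovs):
                if fov == config.alignment_fov:
                    continue
                if not any(e.failed for e in reg.cycles.values()):
                    break
                retry = align_cycle_set(pre, fov, config.registration)
                retried_with.append(fov)
                for j, e in reg.cycles.items():
                    if e.failed and not retry.cycles[j].failed:
                        reg.cycles[j] = retry.cycles[j]
            reg.to_json(shifts_path)
            stage.mark_done()
            _stage_record(
                report, "register",
                shifts={j: e.final_shift for j, e in reg.cycles.items()},
                failed_cycles=[j for j, e in reg.cycles.items() if e.failed],
                retried_with_fovs=retried_with)
    except StageError:
        raise
    except Exception as e:
        raise StageError("register", str(e)) from e

    aligned, failed_cycles = align_dataset(pre, reg)

    # -- segment -----------------------------------------------------------
    inst_paths = [out / f"instances_f{i:02d}.tif"
                  for i in range(dataset.n_fovs)]
    stage = seg_stage
    try:
        if stage.can_skip(inst_paths):
            instance_maps = {i: tifffile.imread(p)
                             for i, p in enumerate(inst_paths)}
            _stage_record(report, "segment", skipped=True)
        else:
            instance_maps = _segment(config, input_dir, out, aligned,
                                     dataset, report)
            for i, p in enumerate(inst_paths):
                tifffile.imwrite(p, instance_maps[i].astype(np.int32))
            stage.mark_done()
    except StageError:
        raise
    except Exception as e:
        raise StageError("segment", str(e)) from e
    n_cells = sum(int(m.max()) for m in instance_maps.values())
    report["stages"]["segment"]["n_cells"] = n_cells

    # -- profile -----------------------------------------------------------
    cells_path = out / "cells.csv"
    stage = prof_stage
    try:
        rules = load_rules(config.rules_path) if config.rules_path \
            else default_rules()
        # quantification uses background-subtracted absolute intensities;
        # percentile normalization is for registration/segmentation inputs
        pre_quant = preprocess_dataset(dataset, config.p_low, config.p_high,
                                       config.gaussian_sigma,
                                       normalize=False)
        aligned_quant, _ = align_dataset(pre_quant, reg)
        stacks = {}
        for i in range(dataset.n_fovs):
            stacks[i] = {
                aligned_quant.marker(j, c): np.asarray(
                    aligned_quant.pair(i, j, c).stain.pixels)
                for j in range(dataset.n_cycles)
                for c in range(dataset.n_channels)
                if j not in failed_cycles
            }
        margin = int(max((max(abs(e.final_shift[0]), abs(e.final_shift[1]))
                          for e in reg.cycles.values() if not e.failed),
                         default=0))
        # rules whose markers were lost with a failed cycle cannot run
        available = set(stacks[0]) if stacks else set()
        usable_rules = [r for r in rules if r.markers <= available]
        dropped_rules = [r.name for r in rules if r.markers - available]
        table = profile_cells(instance_maps, stacks, mad_k=config.mad_k,
                              threshold_method=config.threshold_method,
                              rules=usable_rules, border_margin=margin)
        table.to_csv(cells_path)
        stage.mark_done()
        _stage_record(report, "profile", n_cells=len(table),
                      n_filtered=n_cells - len(table),
                      dropped_rules=dropped_rules,
                      phenotypes=table.phenotypes.value_counts().to_dict())
    except StageError:
        raise
    except Exception as e:
        raise StageError("profile", str(e)) from e

    # -- cluster -----------------------------------------------------------
    try:
        emb = embed(table, config.embedding,
                    phenotype_labels=table.phenotypes
                    if config.supervised_umap else None)
        assign = cluster(emb, config.min_cluster_size)
        df = table.data.copy()
        df["phenotype"] = table.phenotypes.values
        df["umap_1"] = emb.coords[:, 0]
        df["umap_2"] = emb.coords[:, 1]
        df["cluster"] = assign.labels
        df.to_csv(out / "cells_clustered.csv", index=False)
        plot_embedding(emb, assign.labels, out / "umap_clusters.png")
        if assign.n_clusters > 0:
            profiles = cluster_profiles(table, assign)
            profiles.to_csv(out / "cluster_profiles.csv")
            plot_cluster_heatmap(profiles, out / "cluster_heatmap.png")
        composition(assign, table.phenotypes).to_csv(
            out / "composition.csv")
        clus_stage.mark_done()
        _stage_record(report, "cluster", n_clusters=assign.n_clusters,
                      n_noise=assign.n_noise)
    except StageError:
        raise
    except Exception as e:
        raise StageError("cluster", str(e)) from e


def _segment(config: PipelineConfig, input_dir: Path, out: Path,
             aligned: CyclicDataset, dataset: CyclicDataset,
             report: Dict) -> Dict[int, np.ndarray]:
    """Produce per-FOV instance maps by the configured mode."""
    if config.use_ground_truth_masks:
        maps = {}
        for i in range(dataset.n_fovs):
            candidates = sorted(input_dir.glob(f"*f{i:02d}_labels.tif"))
            if not candidates:
                raise StageError("segment",
                                 f"no ground-truth label map for FOV {i}")
            maps[i] = tifffile.imread(candidates[0]).astype(np.int32)
        _stage_record(report, "segment", mode="ground_truth")
        return maps

    slots = {m: (j, c) for (j, c), m in aligned.manifest.items()}
    for name in (config.cd45_marker, config.dapi_marker):
        if name not in slots:
            raise StageError("segment", f"marker {name!r} not in manifest")

    if config.train:
        imgs, insts = [], []
        for i in range(dataset.n_fovs):
            j, c = slots[config.cd45_marker]
            cd45 = np.asarray(aligned.pair(i, j, c).stain.pixels)
            j, c = slots[config.dapi_marker]
            dapi = np.asarray(aligned.pair(i, j, c).stain.pixels)
            imgs.append((cd45, dapi))
            labels = sorted(input_dir.glob(f"*f{i:02d}_labels.tif"))
            if not labels:
                raise StageError("segment",
                                 f"training needs a label map for FOV {i}")
            insts.append(tifffile.imread(labels[0]).astype(np.int32))
        per_fov = seg.make_training_samples(
            imgs, insts, config.train_config.tile_size,
            config.train_config.overlap_fraction)
        n_val = max(1, int(round(len(per_fov)
                                 * config.train_config.val_fraction)))
        train_s = [s for fov in per_fov[:-n_val] for s in fov]
        val_s = [s for fov in per_fov[-n_val:] for s in fov]
        model, hist = seg.train_with_restarts(
            config.arch, train_s, val_s, config.train_config,
            config.loss_weights)
        model.save(out / "checkpoint.pkl")
        _stage_record(report, "segment", mode="train",
                      best_val_accuracy=hist.best_val_accuracy)
    else:
        model = MultiTaskUNet.load(config.checkpoint)
        _stage_record(report, "segment", mode="checkpoint")

    maps = {}
    for i in range(dataset.n_fovs):
        j, c = slots[config.cd45_marker]
        cd45 = np.asarray(aligned.pair(i, j, c).stain.pixels)
        j, c = slots[config.dapi_marker]
        dapi = np.asarray(aligned.pair(i, j, c).stain.pixels)
        mask = seg.predict_fov(model, cd45, dapi,
                               overlap=config.train_config.overlap_fraction)
        tifffile.imwrite(out / f"classmask_f{i:02d}.tif", mask)
        maps[i] = seg.extract_instances(mask, min_area=config.min_cell_area)
    return maps
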