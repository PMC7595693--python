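"""Batch orchestration of the full workflow over an image manifest.

Stages run in dependency order — segment, extract, distance, normalize,
profile — and each stage is idempotent: re-running it overwrites only its
own outputs (label TIFFs for segment; its store tables otherwise), so
users can iterate on segmentation parameters without re-measuring
distances.  Per-image failures are logged and skipped; the batch
continues and the run report names every failure.

Determinism contract: identical config and inputs give identical store
contents and exported CSVs regardless of worker count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import image_io
from .distances import DistanceParams, measure_all_objects
from .extraction import extract_features
from .quantify import (
    DEFAULT_VOLUME_WINDOW,
    GRANULE_THRESHOLD,
    calibrate_single_molecule,
    cumulative_profile,
    estimate_molecules,
)
from .segmentation import SegmentationParams, segment_structure
from .store import ObjectStore

logger = logging.getLogger("subcelldist")

STAGES = ("segment", "extract", "distance", "normalize", "profile")

__all__ = ["PipelineConfig", "RunReport", "load_config", "run_pipeline", "STAGES"]


@dataclass
class PipelineConfig:
    images: list[image_io.ImageEntry]
    store_path: Path
    labels_dir: Path
    segmentation: dict[str, SegmentationParams]
    pairs: list[dict]  # {structure_1, structure_2, n_candidates, exhaustive}
    calibration_structures: list[str] = field(default_factory=list)
    volume_window: tuple[int, int] = DEFAULT_VOLUME_WINDOW
    granule_threshold: float = GRANULE_THRESHOLD
    profile_step_um: float = 0.05
    profile_max_um: float = 5.0
    weight_mode: str = "intensity"
    workers: int = 1

    def validate(self) -> list[str]:
        """Collect every config error before any work starts."""
        errors = []
        seen = set()
        for entry in self.images:
            if entry.image_id in seen:
                errors.append(f"duplicate image_id {entry.image_id!r}")
            seen.add(entry.image_id)
            for structure, p in entry.paths.items():
                if not Path(p).exists():
                    errors.append(f"{entry.image_id}/{structure}: missing file {p}")
        structures = {s for e in self.images for s in e.paths}
        for pair in self.pairs:
            for key in ("structure_1", "structure_2"):
                if pair[key] not in structures:
                    errors.append(f"distance pair references unknown structure {pair[key]!r}")
        for s in self.calibration_structures:
            if s not in structures:
                errors.append(f"calibration references unknown structure {s!r}")
        if self.weight_mode not in ("intensity", "molecules", "object_count"):
            errors.append(f"unknown weight_mode {self.weight_mode!r}")
        return errors


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file (see README)."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    images = image_io.load_manifest(path)
    store_path = Path(doc.get("store", "subcelldist.db"))
    if not store_path.is_absolute():
        store_path = path.parent / store_path
    labels_dir = Path(doc.get("labels_dir", store_path.parent / "labels"))
    seg = {
        name: SegmentationParams(**(cfg.get("segmentation", {}) or {}))
        for name, cfg in (doc.get("structures") or {}).items()
    }
    cal = doc.get("calibration") or {}
    prof = doc.get("profile") or {}
    return PipelineConfig(
        images=images,
        store_path=store_path,
        labels_dir=labels_dir,
        segmentation=seg,
        pairs=list(doc.get("pairs") or []),
        calibration_structures=list(cal.get("structures") or []),
        volume_window=tuple(cal.get("volume_window", DEFAULT_VOLUME_WINDOW)),
        granule_threshold=float(cal.get("granule_threshold", GRANULE_THRESHOLD)),
        profile_step_um=float(prof.get("step_um", 0.05)),
        profile_max_um=float(prof.get("max_distance_um", 5.0)),
        weight_mode=str(prof.get("weight_mode", "intensity")),
        workers=int(doc.get("workers", 1)),
    )


@dataclass
class RunReport:
    stages: list[str]
    object_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    distance_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    failures: list[tuple[str, str, str]] = field(default_factory=list)  # (image, stage, msg)

    @property
    def ok(self) -> bool:
        return not self.failures


def _label_path(cfg: PipelineConfig, image_id: str, structure: str) -> Path:
    return cfg.labels_dir / f"{image_id}_{structure}_labels.tif"


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> RunReport:
    """Execute the requested stages in dependency order over all images."""
    errors = cfg.validate()
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    stages = tuple(s for s in STAGES if s in stages)
    report = RunReport(stages=list(stages))
    cfg.labels_dir.mkdir(parents=True, exist_ok=True)
    cfg.store_path.parent.mkdir(parents=True, exist_ok=True)
    store = ObjectStore(cfg.store_path)
    try:
        for entry in cfg.images:
            for stage in stages:
                try:
                    _run_stage(cfg, store, entry, stage, report)
                except Exception as exc:  # keep batch alive; report the failure
                    logger.error("%s/%s failed: %s", entry.image_id, stage, exc)
                    report.failures.append((entry.image_id, stage, str(exc)))
                    break  # later stages depend on this one for this image
    finally:
        store.close()
    return report


def _run_stage(cfg, store, entry, stage, report) -> None:
    image_id = entry.image_id
    if stage == "segment":
        for structure, path in entry.paths.items():
            raw = image_io.read_zstack(path, entry.voxel_size, structure, image_id=image_id)
            params = cfg.segmentation.get(structure, SegmentationParams())
            labels = segment_structure(raw, params)
            image_io.write_mask(labels, _label_path(cfg, image_id, structure))
            store.log_run(stage, image_id, json.dumps({"structure": structure, "params": str(params)}))
            logger.info("%s/%s: %d objects segmented", image_id, structure, int(labels.max()))
    elif stage == "extract":
        for structure, path in entry.paths.items():
            lp = _label_path(cfg, image_id, structure)
            if not lp.exists():
                raise FileNotFoundError(f"no label map for {image_id}/{structure}; run segment first")
            labels = image_io.read_mask(lp)
            raw = image_io.read_zstack(path, entry.voxel_size, structure, image_id=image_id)
            objects = extract_features(labels, raw)
            store.delete_image_objects(image_id, structure)
            n = store.upsert_objects(objects)
            report.object_counts[(image_id, structure)] = n
            logger.info("%s/%s: %d objects extracted", image_id, structure, n)
    elif stage == "distance":
        for pair in cfg.pairs:
            s1, s2 = pair["structure_1"], pair["structure_2"]
            o1 = store.get_objects(image_id, s1)
            o2 = store.get_objects(image_id, s2)
            if not o2:
                raise ValueError(f"no {s2!r} objects stored for image {image_id}")
            params = DistanceParams(
                voxel_size=entry.voxel_size,
                n_candidates=int(pair.get("n_candidates", 3)),
                exhaustive=bool(pair.get("exhaustive", False)),
            )
            records = measure_all_objects(o1, o2, params, n_workers=cfg.workers)
            pair_name = f"{s1}__{s2}"
            store.replace_distances(image_id, pair_name, records)
            report.distance_counts[(image_id, pair_name)] = len(records)
            logger.info("%s/%s: %d distances", image_id, pair_name, len(records))
    elif stage == "normalize":
        for structure in cfg.calibration_structures:
            objects = store.get_objects(image_id, structure)
            if not objects:
                raise ValueError(f"no {structure!r} objects stored for image {image_id}")
            cal = calibrate_single_molecule(objects, cfg.volume_window)
            est = estimate_molecules(objects, cal, cfg.granule_threshold)
            store.replace_measurements(image_id, structure, est)
            logger.info(
                "%s/%s: single-molecule intensity %.1f from %d objects",
                image_id, structure, cal.mean_single_molecule_intensity,
                cal.n_calibration_objects,
            )
    elif stage == "profile":
        for pair in cfg.pairs:
            s1, s2 = pair["structure_1"], pair["structure_2"]
            pair_name = f"{s1}__{s2}"
            records = store.get_distances(image_id, pair_name)
            if not records:
                raise ValueError(f"no distances stored for {image_id}/{pair_name}")
            objects = store.get_objects(image_id, s1)
            estimates = store.get_measurements(image_id, s1) or None
            mode = cfg.weight_mode
            if mode == "molecules" and estimates is None:
                raise ValueError(
                    f"weight_mode='molecules' but no molecule estimates for {image_id}/{s1}"
                )
            prof = cumulative_profile(
                records,
                objects=objects,
                estimates=estimates,
                step_um=cfg.profile_step_um,
                max_distance_um=cfg.profile_max_um,
                weight_mode=mode,
            )
            store.replace_profile(pair_name, prof)
    else:
        raise ValueError(f"unknown stage {stage!r}")


def profiles_frame(store_path: str | Path, config: PipelineConfig | None = None) -> pd.DataFrame:
    """All stored profiles as a tidy table, with condition labels if known."""
    with ObjectStore(store_path) as store:
        df = store.table_frame("profiles")
    df = df.sort_values(["image_id", "structure_pair", "weight_mode", "distance_um"]).reset_index(
        drop=True
    )
    if config is not None:
        cond = {e.image_id: e.condition for e in config.images}
        df.insert(1, "condition", df["image_id"].map(cond).fillna(""))
    return df


def aggregate_profiles(df: pd.DataFrame, by: str = "condition") -> pd.DataFrame:
    """Mean +/- s.d. of cumulative percent per grid point across images."""
    grouped = df.groupby([by, "structure_pair", "weight_mode", "distance_um"])["cumulative_percent"]
    out = grouped.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_percent", "std": "sd_percent", "count": "n_images"})
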