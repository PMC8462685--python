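"""End-to-end orchestration: simulate/load, augment, detect, merge, count, evaluate.

A run is a pure function of its :class:`PipelineConfig` (which embeds the
global seed): stage order is fixed — generate or load scenes, optionally
expand them with augmentations, run the individual-cell and glia-cluster
detection streams, merge the streams, count glia inside surviving clusters,
and evaluate against consistently merged ground truth.  Every artifact is
written under the run directory together with provenance metadata (config
hash, seed, package version), so a run can be re-created bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .annotations import (
    CellClass,
    Detection,
    GroundTruthRecord,
    map_class,
    write_detection_csv,
)
from .augmentation import AugmentationSpec, expand_dataset
from .counting import ClusterCountResult, CountingParams, count_cluster, count_rmse
from .detection import ReferenceDetector, ReferenceDetectorParams
from .evaluation import APReport, evaluate_workflow
from .merging import MergeParams, merge_ground_truth, merge_predictions_with_provenance
from .synthetic import SceneConfig, SceneTruth, make_scene

__all__ = [
    "PipelineConfig",
    "SceneResult",
    "RunResult",
    "run_pipeline",
    "export_training_set",
    "filter_background",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full pipeline run.

    Exactly one input source: a tuple of synthetic ``scene_configs`` (their
    seeds are re-derived from the global ``seed``) or an ``input_dir``
    holding images plus an annotation CSV.
    """

    scene_configs: tuple[SceneConfig, ...] = ()
    input_dir: str | None = None
    scheme: str = "six"
    use_dapi: bool = False
    keep_background_patches: bool = False
    augmentation: AugmentationSpec | None = None
    detector: ReferenceDetectorParams = field(default_factory=ReferenceDetectorParams)
    merge: MergeParams = field(default_factory=MergeParams)
    counting: CountingParams = field(default_factory=CountingParams)
    tile_size: int = 512
    export_training: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if bool(self.scene_configs) == (self.input_dir is not None):
            raise ValueError(
                "exactly one input source: scene_configs or input_dir"
            )
        if self.scheme not in ("two", "six", "seven"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass
class SceneResult:
    name: str
    image: np.ndarray
    truth_records: tuple[GroundTruthRecord, ...]
    cell_detections: list[Detection]
    cluster_detections: list[Detection]
    merged: list[Detection]
    merged_gt: list[GroundTruthRecord]
    cluster_counts: list[tuple[Detection, ClusterCountResult]]


@dataclass
class RunResult:
    out_dir: Path
    report: APReport
    scenes: list[SceneResult]
    count_rmse_per_color: dict[str, float]

    @property
    def mean_ap(self) -> float:
        return self.report.mean_ap


def _config_hash(config: PipelineConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in sorted(obj.items())}
        return obj

    blob = json.dumps(enc(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def filter_background(
    samples: Sequence[tuple], keep_background: bool
) -> list:
    """Drop samples whose annotation list is empty unless told to keep them."""
    if keep_background:
        return list(samples)
    return [s for s in samples if len(s[1]) > 0]


def _derive_scene_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(max(n, 1))
    return [int(s % (2**31)) for s in state[:n]]


def _split_gt(records: Sequence[GroundTruthRecord]):
    cells = [r for r in records if r.label.phenotype != "glia_cluster"]
    clusters = [r for r in records if r.label.phenotype == "glia_cluster"]
    return cells, clusters


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunResult:
    """Execute all stages and write the run directory; returns the results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    # ------------------------------------------------------------------ load
    if config.scene_configs:
        seeds = _derive_scene_seeds(config.seed, len(config.scene_configs))
        samples = []
        for i, (scene_cfg, scene_seed) in enumerate(zip(config.scene_configs, seeds)):
            image, truth = make_scene(dataclasses.replace(scene_cfg, seed=scene_seed))
            samples.append((image, tuple(truth.records), f"scene_{i:03d}"))
        log.append(f"simulated {len(samples)} scenes (seed {config.seed})")
    else:
        from .annotations import read_annotation_csv
        import imageio.v3 as iio

        indir = Path(config.input_dir)
        ann = read_annotation_csv(indir / "annotations.csv")
        by_image: dict[str, list[GroundTruthRecord]] = {}
        for img_path, rec in ann:
            by_image.setdefault(img_path, []).append(rec)
        samples = []
        for img_path, recs in sorted(by_image.items()):
            fp = indir / img_path
            arr = (
                tifffile.imread(fp) if fp.suffix in (".tif", ".tiff") else iio.imread(fp)
            )
            samples.append((np.asarray(arr), tuple(recs), Path(img_path).stem))
        log.append(f"loaded {len(samples)} images from {indir}")

    # --------------------------------------------------------------- augment
    if config.augmentation is not None:
        augmented = expand_dataset(samples, config.augmentation)
        samples = [(s.image, s.annotations, s.name) for s in augmented]
        log.append(f"augmented to {len(samples)} samples")

    # ------------------------------------------------------ detect and merge
    cell_detector = ReferenceDetector(
        params=config.detector, scheme=config.scheme, stream="cells"
    )
    cluster_detector = ReferenceDetector(params=config.detector, stream="clusters")
    eval_scheme = "two" if config.scheme == "two" else "seven"

    scene_results: list[SceneResult] = []
    est_by_color: dict[str, list[int]] = {"red": [], "green": [], "yellow": []}
    true_by_color: dict[str, list[int]] = {"red": [], "green": [], "yellow": []}

    for image, records, name in samples:
        cells = cell_detector(image)
        clusters = (
            cluster_detector(image) if config.scheme != "two" else []
        )
        prov = merge_predictions_with_provenance(cells, clusters, config.merge)
        merged = list(prov.kept_clusters) + list(prov.kept_cells)
        log.append(
            f"{name}: {len(cells)} cells + {len(clusters)} clusters -> "
            f"{len(merged)} merged ({len(prov.absorbed)} glia absorbed)"
        )

        gt_cells, gt_clusters = _split_gt(records)
        if config.scheme == "two":
            if gt_clusters:
                log.append(
                    f"{name}: dropping {len(gt_clusters)} cluster annotations "
                    "(no cluster class in the two-class scheme)"
                )
            merged_gt = [
                dataclasses.replace(r, label=map_class(r.label, "two"))
                for r in gt_cells
            ]
        else:
            merged_gt = merge_ground_truth(gt_cells, gt_clusters, config.merge)

        # ------------------------------------------------------------ count
        counts: list[tuple[Detection, ClusterCountResult]] = []
        for cl in prov.kept_clusters:
            result = count_cluster(
                image,
                cl,
                merged,
                config.counting,
                pixel_size=(
                    config.scene_configs[0].pixel_size if config.scene_configs else 1.0
                ),
            )
            counts.append((cl, result))
        # pair estimated counts with matched ground-truth clusters for RMSE
        gt_cluster_recs = [r for r in merged_gt if r.label.phenotype == "glia_cluster"]
        for cl, result in counts:
            best = None
            best_frac = 0.0
            for rec in gt_cluster_recs:
                frac = cl.box.intersection_area(rec.box) / min(
                    cl.box.area, rec.box.area
                )
                if frac > best_frac:
                    best, best_frac = rec, frac
            if best is not None and best_frac > 0.5 and best.member_counts:
                for color in ("red", "green", "yellow"):
                    est_by_color[color].append(result.counts[color])
                    true_by_color[color].append(best.member_counts.get(color, 0))

        scene_results.append(
            SceneResult(
                name,
                image,
                tuple(records),
                cells,
                clusters,
                merged,
                merged_gt,
                counts,
            )
        )

    # -------------------------------------------------------------- evaluate
    all_merged = [d for s in scene_results for d in s.merged]
    all_gt = [r for s in scene_results for r in s.merged_gt]
    report = evaluate_workflow(all_merged, all_gt, eval_scheme)
    rmse_per_color = {
        color: count_rmse(est_by_color[color], true_by_color[color])
        for color in est_by_color
        if est_by_color[color]
    }

    # ----------------------------------------------------------------- write
    _write_artifacts(config, out, scene_results, report, rmse_per_color, log)
    return RunResult(out, report, scene_results, rmse_per_color)


def _write_artifacts(config, out, scene_results, report, rmse_per_color, log):
    images_dir = out / "images"
    images_dir.mkdir(exist_ok=True)
    det_rows, merged_rows, count_rows = [], [], []
    for s in scene_results:
        tifffile.imwrite(images_dir / f"{s.name}.tif", s.image)
        det_rows += [(f"{s.name}.tif", d) for d in s.cell_detections]
        det_rows += [(f"{s.name}.tif", d) for d in s.cluster_detections]
        merged_rows += [(f"{s.name}.tif", d) for d in s.merged]
        for i, (cl, res) in enumerate(s.cluster_counts):
            count_rows.append(
                {
                    "image": f"{s.name}.tif",
                    "cluster_id": i,
                    "x1": cl.box.x_min,
                    "y1": cl.box.y_min,
                    "x2": cl.box.x_max,
                    "y2": cl.box.y_max,
                    "n_red": res.counts["red"],
                    "n_green": res.counts["green"],
                    "n_yellow": res.counts["yellow"],
                    "area_red": res.areas_um2["red"],
                    "area_green": res.areas_um2["green"],
                    "area_yellow": res.areas_um2["yellow"],
                    "thr_gfp": res.thresholds["gfp"],
                    "thr_rfp": res.thresholds["rfp"],
                }
            )
    write_detection_csv(out / "detections.csv", det_rows)
    write_detection_csv(out / "merged_detections.csv", merged_rows)
    pd.DataFrame(count_rows).to_csv(out / "cluster_counts.csv", index=False)
    payload = report.to_dict()
    payload["count_rmse_per_color"] = rmse_per_color
    (out / "evaluation.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (out / "run.log").write_text("\n".join(log) + "\n")
    meta = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "scheme": config.scheme,
        "package_version": _package_version(),
    }
    (out / "provenance.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _package_version() -> str:
    from . import __version__

    return __version__


# ---------------------------------------------------------------------------
# training-set export


def export_training_set(
    image: np.ndarray,
    records: Sequence[GroundTruthRecord],
    tile_size: int = 512,
    keep_background: bool = False,
    image_name: str = "scene",
) -> list[tuple[np.ndarray, list[GroundTruthRecord], str]]:
    """Tile an image on a grid and assign each box to the tile with its center.

    Box coordinates are shifted into the tile frame (and clipped to the tile
    when a box straddles a border).  Tiles without any annotation are dropped
    unless ``keep_background`` is set.  Every ground-truth box appears in
    exactly one tile.
    """
    if tile_size <= 0:
        raise ValueError("tile size must be positive")
    h, w = image.shape[:2]
    if tile_size > max(h, w):
        warnings.warn(
            f"tile size {tile_size} exceeds image extent {w}x{h}; using one tile"
        )
    n_cols = max(1, int(np.ceil(w / tile_size)))
    n_rows = max(1, int(np.ceil(h / tile_size)))
    tiles: list[tuple[np.ndarray, list[GroundTruthRecord], str]] = []
    for row in range(n_rows):
        for col in range(n_cols):
            x0, y0 = col * tile_size, row * tile_size
            x1, y1 = min(w, x0 + tile_size), min(h, y0 + tile_size)
            tile_records = []
            for rec in records:
                cx, cy = rec.box.center
                if x0 <= cx < x1 and y0 <= cy < y1:
                    from .annotations import BoundingBox

                    box = BoundingBox(
                        max(rec.box.x_min, x0) - x0,
                        max(rec.box.y_min, y0) - y0,
                        min(rec.box.x_max, x1) - x0,
                        min(rec.box.y_max, y1) - y0,
                    )
                    tile_records.append(dataclasses.replace(rec, box=box))
            if tile_records or keep_background:
                tiles.append(
                    (
                        image[y0:y1, x0:x1],
                        tile_records,
                        f"{image_name}_r{row}c{col}",
                    )
                )
    return tiles
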