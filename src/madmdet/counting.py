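"""Area-based counting of glia inside detected clusters.

Individual glial somas cannot be delineated inside a dense cluster at low
magnification, so the number of cells of each MADM color is estimated from
the *area* of reporter-positive signal: pixels belonging to cells are
segmented with an adaptive threshold, cleaned up with morphological opening
and closing, partitioned by color, and the per-color area is divided by a
per-cell area quantum (default 2000 um^2) and rounded.

The adaptive threshold for a cluster combines background and in-cluster
statistics::

    threshold = (mean_BKG + mean_cluster) / 2 + (SD_BKG + SD_cluster) / 2

where background statistics come from pixels outside all object boxes in the
patch and cluster statistics from pixels inside the cluster box after
detected neurons have been masked out.

Counting quality is summarized by the root-mean-square error between
estimated and true member counts over a set of clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skimage.morphology import closing, disk, opening

from .annotations import BoundingBox, Detection

__all__ = [
    "CountingParams",
    "ClusterCountResult",
    "cluster_threshold",
    "clean_mask",
    "count_cluster",
    "count_rmse",
]


@dataclass(frozen=True)
class CountingParams:
    """Tunables of area-based counting.

    area_per_cell
        Area quantum in um^2 attributed to one glial cell (default 2000).
    selem_radius_um
        Radius (um) of the disk structuring element used for morphological
        opening and closing; converted to pixels via the image pixel size.
    rounding
        ``"half_away"`` (0.5 rounds up, the default) or ``"half_even"``.
    """

    area_per_cell: float = 2000.0
    selem_radius_um: float = 2.0
    rounding: str = "half_away"

    def __post_init__(self) -> None:
        if self.area_per_cell <= 0:
            raise ValueError("area_per_cell must be positive")
        if self.selem_radius_um <= 0:
            raise ValueError("selem_radius_um must be positive")
        if self.rounding not in ("half_away", "half_even"):
            raise ValueError(f"unknown rounding convention {self.rounding!r}")

    def round_count(self, cells: float) -> int:
        if self.rounding == "half_away":
            return int(math.floor(cells + 0.5))
        return int(round(cells))


@dataclass(frozen=True)
class ClusterCountResult:
    """Per-color estimated counts and the intermediate quantities behind them."""

    counts: Mapping[str, int]
    areas_um2: Mapping[str, float]
    thresholds: Mapping[str, float]
    clipped: bool = False

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def cluster_threshold(
    cluster_pixels: np.ndarray, background_pixels: np.ndarray
) -> float:
    """Adaptive intensity threshold separating cell signal from background.

    Midpoint of the background and in-cluster means plus the average of the
    two standard deviations.  Both pixel sets must be non-empty.
    """
    cluster_pixels = np.asarray(cluster_pixels, dtype=np.float64).ravel()
    background_pixels = np.asarray(background_pixels, dtype=np.float64).ravel()
    if background_pixels.size == 0:
        raise ValueError(
            "empty background pixel set: use a larger patch around the cluster"
        )
    if cluster_pixels.size == 0:
        raise ValueError("empty cluster pixel set")
    return float(
        0.5 * (background_pixels.mean() + cluster_pixels.mean())
        + 0.5 * (background_pixels.std() + cluster_pixels.std())
    )


def clean_mask(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Morphological opening then closing with a disk structuring element."""
    if radius_px < 1:
        return mask
    selem = disk(radius_px)
    return closing(opening(mask, selem), selem)


def _box_slice(box: BoundingBox, shape: tuple[int, int]) -> tuple[slice, slice, bool]:
    h, w = shape
    x0, y0 = int(math.floor(box.x_min)), int(math.floor(box.y_min))
    x1, y1 = int(math.ceil(box.x_max)), int(math.ceil(box.y_max))
    clipped = x0 < 0 or y0 < 0 or x1 > w or y1 > h
    return (
        slice(max(0, y0), min(h, y1)),
        slice(max(0, x0), min(w, x1)),
        clipped,
    )


def count_cluster(
    image: np.ndarray,
    cluster: Detection,
    all_detections: Sequence[Detection],
    params: CountingParams = CountingParams(),
    pixel_size: float = 1.0,
) -> ClusterCountResult:
    """Estimate per-color glia counts inside one detected cluster.

    Pipeline: mask out detected-neuron boxes inside the cluster; compute the
    per-channel adaptive threshold (background statistics from pixels outside
    *all* object boxes in the patch); threshold; morphological opening and
    closing; assign colors per pixel (above threshold in both reporter
    channels = yellow, otherwise the single positive channel); convert areas
    to um^2 and divide by the per-cell quantum.

    ``image`` is an ``(H, W, C)`` raster with GFP in channel 0 and RFP in
    channel 1 (a DAPI channel, if present, is ignored).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] < 2:
        raise ValueError("image must be (H, W, >=2) with GFP and RFP channels")
    h, w = img.shape[:2]

    ys, xs, clipped = _box_slice(cluster.box, (h, w))
    inside = np.zeros((h, w), dtype=bool)
    inside[ys, xs] = True
    if not inside.any():
        raise ValueError("cluster box lies entirely outside the image")

    outside_objects = np.ones((h, w), dtype=bool)
    neuron_mask = np.zeros((h, w), dtype=bool)
    for det in list(all_detections) + [cluster]:
        oys, oxs, _ = _box_slice(det.box, (h, w))
        outside_objects[oys, oxs] = False
        if det.label.phenotype == "neuron":
            neuron_mask[oys, oxs] = True

    cluster_region = inside & ~neuron_mask
    radius_px = max(1, round(params.selem_radius_um / pixel_size))

    channel_names = {"gfp": 0, "rfp": 1}
    thresholds: dict[str, float] = {}
    masks: dict[str, np.ndarray] = {}
    for name, ch in channel_names.items():
        channel = img[:, :, ch]
        thr = cluster_threshold(channel[cluster_region], channel[outside_objects])
        thresholds[name] = thr
        masks[name] = clean_mask((channel > thr) & cluster_region, radius_px)

    yellow = masks["gfp"] & masks["rfp"]
    red = masks["rfp"] & ~masks["gfp"]
    green = masks["gfp"] & ~masks["rfp"]

    px_area = pixel_size * pixel_size
    areas = {
        "red": float(red.sum()) * px_area,
        "green": float(green.sum()) * px_area,
        "yellow": float(yellow.sum()) * px_area,
    }
    counts = {
        color: params.round_count(area / params.area_per_cell)
        for color, area in areas.items()
    }
    return ClusterCountResult(counts, areas, thresholds, clipped=clipped)


def count_rmse(
    estimates: Sequence[float], truths: Sequence[float]
) -> float:
    """Root-mean-square error between estimated and true cluster member counts."""
    est = np.asarray(estimates, dtype=np.float64)
    tru = np.asarray(truths, dtype=np.float64)
    if est.shape != tru.shape:
        raise ValueError(
            f"length mismatch: {est.size} estimates vs {tru.size} truths"
        )
    if est.size == 0:
        raise ValueError("empty count lists")
    return float(np.sqrt(np.mean((est - tru) ** 2)))
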