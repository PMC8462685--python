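"""The detector contract, preprocessing, a classical reference detector, and
an adapter for externally produced predictions.

The workflow is detector-agnostic: any callable that takes a multichannel
image and returns a list of :class:`~madmdet.annotations.Detection` under a
declared class scheme satisfies the contract (a trained deep detector such
as RetinaNet plugs in through :func:`load_external_predictions`, which reads
its serialized predictions).  The package ships a deterministic classical
reference detector so the merging, counting, and evaluation stages can be
exercised end to end without any trained model:

1. per-channel foreground threshold at ``mean + k * SD`` of the background,
   with background statistics refined once by excluding the first-pass
   foreground;
2. connected components of the combined reporter foreground above a minimum
   area become candidates;
3. color is assigned yellow when both reporter channels are above threshold
   inside the component, otherwise the dominant channel's color;
4. phenotype by footprint area (large = glia, larger still = cluster);
5. confidence is the component's peak intensity over the dynamic ceiling.

Zero-centering (per-channel mean subtraction) is the standard preprocessing
applied before handing an image to a trained detector; the reference
detector's statistics are translation-invariant so it accepts either form.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.measure import label as cc_label, regionprops

from .annotations import (
    AnnotationError,
    BoundingBox,
    CellClass,
    Detection,
    read_detection_csv,
    scheme_classes,
)

__all__ = [
    "zero_center",
    "ReferenceDetectorParams",
    "ReferenceDetector",
    "reference_detect",
    "load_external_predictions",
]


def zero_center(image: np.ndarray) -> np.ndarray:
    """Subtract each channel's mean so channel means are zero.

    Accepts ``(H, W)`` or ``(H, W, C)`` images and returns float64.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("cannot zero-center an empty image")
    if img.ndim == 2:
        return img - img.mean()
    if img.ndim == 3:
        return img - img.mean(axis=(0, 1), keepdims=True)
    raise ValueError(f"expected a 2-D or 3-D image, got shape {img.shape}")


@dataclass(frozen=True)
class ReferenceDetectorParams:
    """Tunables of the classical reference detector.

    k_background
        Multiplier in the per-channel foreground threshold mean + k * SD.
    min_area_um2
        Components smaller than this are discarded as speckle.
    neuron_glia_split_um2
        Footprint area at or above which a component is called glia.
    cluster_min_area_um2
        Footprint area at or above which a component is a glia cluster
        (used by the cluster detection stream / seven-class scheme).
    yellow_ratio
        Minimum ratio of the weaker to the stronger channel's mean excess
        for a yellow call (0 disables the extra check; the both-channels-
        above-threshold rule always applies).
    ceiling
        Dynamic ceiling used for confidence scaling.
    """

    k_background: float = 2.0
    min_area_um2: float = 25.0
    neuron_glia_split_um2: float = 500.0
    cluster_min_area_um2: float = 3500.0
    yellow_ratio: float = 0.0
    ceiling: float = 255.0

    def __post_init__(self) -> None:
        for name in ("k_background", "min_area_um2", "neuron_glia_split_um2",
                     "cluster_min_area_um2", "ceiling"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.yellow_ratio <= 1.0):
            raise ValueError("yellow_ratio must be in [0, 1]")


def _channel_threshold(channel: np.ndarray, k: float) -> tuple[float, float]:
    """Background mean and foreground threshold, one refinement pass."""
    mean, sd = channel.mean(), channel.std()
    background = channel[channel <= mean + k * sd]
    if background.size:
        mean, sd = background.mean(), background.std()
    return float(mean), float(mean + k * sd)


def reference_detect(
    image: np.ndarray,
    params: ReferenceDetectorParams = ReferenceDetectorParams(),
    pixel_size: float = 1.0,
    scheme: str = "six",
) -> list[Detection]:
    """Run the classical reference detector on a (H, W, >=2) image.

    Channel 0 is GFP, channel 1 is RFP; any further channels (DAPI) are
    ignored.  Under ``scheme="seven"`` components at or above the cluster
    area become ``glia_cluster`` detections; under ``"six"``/``"two"`` they
    are labeled as (large) glia.  Returned boxes are component tight boxes.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] < 2:
        raise ValueError("image must be (H, W, >=2) with GFP and RFP channels")
    scheme_classes(scheme)  # validates the scheme name
    gfp = img[:, :, 0]
    rfp = img[:, :, 1]

    stats = [_channel_threshold(gfp, params.k_background),
             _channel_threshold(rfp, params.k_background)]
    fg = (gfp > stats[0][1]) | (rfp > stats[1][1])

    px_area = pixel_size * pixel_size
    detections: list[Detection] = []
    labels = cc_label(fg, connectivity=2)
    for region in regionprops(labels):
        area_um2 = region.area * px_area
        if area_um2 < params.min_area_um2:
            continue
        y0, x0, y1, x1 = region.bbox
        box = BoundingBox(float(x0), float(y0), float(x1), float(y1))
        coords = tuple(region.coords.T)
        mean_g, mean_r = float(gfp[coords].mean()), float(rfp[coords].mean())
        peak = float(max(gfp[coords].max(), rfp[coords].max()))
        confidence = min(1.0, peak / params.ceiling)

        above_g = mean_g > stats[0][1]
        above_r = mean_r > stats[1][1]
        excess_g = mean_g - stats[0][0]
        excess_r = mean_r - stats[1][0]
        if above_g and above_r and (
            params.yellow_ratio == 0.0
            or min(excess_g, excess_r) >= params.yellow_ratio * max(excess_g, excess_r)
        ):
            color = "yellow"
        elif excess_g > excess_r:
            color = "green"
        elif excess_r > excess_g:
            color = "red"
        else:
            color = "yellow"  # exact tie: channel-symmetric fallback

        if area_um2 >= params.cluster_min_area_um2 and scheme == "seven":
            label = CellClass("glia_cluster")
        else:
            phenotype = "glia" if area_um2 >= params.neuron_glia_split_um2 else "neuron"
            label = (
                CellClass(phenotype)
                if scheme == "two"
                else CellClass(phenotype, color)
            )
        detections.append(Detection(box, label, confidence))
    return detections


@dataclass(frozen=True)
class ReferenceDetector:
    """Detector-contract wrapper around :func:`reference_detect`.

    ``stream="cells"`` returns individual-cell detections only (components at
    or above the cluster area are dropped — a cell model does not see
    clusters); ``stream="clusters"`` returns only ``glia_cluster``
    detections; ``stream="all"`` returns everything the scheme allows.
    DAPI is excluded from the detector input by default: only the two
    reporter channels are thresholded.
    """

    params: ReferenceDetectorParams = field(default_factory=ReferenceDetectorParams)
    scheme: str = "six"
    stream: str = "all"
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.stream not in ("cells", "clusters", "all"):
            raise ValueError(f"unknown stream {self.stream!r}")

    def __call__(self, image: np.ndarray) -> list[Detection]:
        if self.stream == "clusters":
            dets = reference_detect(image, self.params, self.pixel_size, scheme="seven")
            return [d for d in dets if d.label.phenotype == "glia_cluster"]
        if self.stream == "cells":
            dets = reference_detect(image, self.params, self.pixel_size, scheme="seven")
            cells = [d for d in dets if d.label.phenotype != "glia_cluster"]
            if self.scheme == "two":
                cells = [
                    dataclasses.replace(d, label=CellClass(d.label.phenotype))
                    for d in cells
                ]
            return cells
        return reference_detect(image, self.params, self.pixel_size, self.scheme)


def load_external_predictions(
    path: str | Path, class_scheme: str = "six"
) -> list[tuple[str, Detection]]:
    """Read a detection CSV produced by an external model and validate it.

    Rows are ``image_path,x1,y1,x2,y2,class_name,confidence``; every label
    must belong to ``class_scheme`` and every confidence to [0, 1].
    """
    valid = set(scheme_classes(class_scheme))
    out = read_detection_csv(path)
    for i, (_img, det) in enumerate(out):
        if det.label not in valid:
            raise AnnotationError(
                f"line {i + 1}: class {det.label.name!r} not in the "
                f"{class_scheme}-class scheme "
                f"({sorted(c.name for c in valid)})"
            )
    return out
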