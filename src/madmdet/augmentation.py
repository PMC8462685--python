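"""Fluorophore-aware data augmentation: color swap and saturation emulation.

Two augmentations exploit the symmetry of a two-reporter labeling system:

* **Color swap** exchanges the GFP and RFP channels and relabels red <-> green
  consistently (yellow cells express both reporters and are invariant).  It
  is an exact involution and balances color classes in a training set.
* **Saturation emulation** multiplies intensities by a factor > 1 (default
  1.5) and applies a ceiling at the maximum representable intensity, mimicking
  acquisition at higher laser power where dense structures saturate.

Neither augmentation moves, adds, or removes bounding boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Iterable, Sequence, TypeVar

import numpy as np

from .annotations import CellClass, Detection, GroundTruthRecord

__all__ = ["AugmentationSpec", "color_swap", "swap_label", "saturate", "expand_dataset", "AugmentedSample"]

_SWAP = {"red": "green", "green": "red", "yellow": "yellow", None: None}

_R = TypeVar("_R", Detection, GroundTruthRecord)


@dataclass(frozen=True)
class AugmentationSpec:
    """Which augmentations to apply when expanding a dataset."""

    enable_swap: bool = True
    enable_saturation: bool = True
    saturation_factor: float = 1.5
    ceiling: int | None = None  # None: use the image dtype maximum

    def __post_init__(self) -> None:
        if self.saturation_factor <= 1:
            raise ValueError("saturation_factor must be > 1")


def swap_label(label: CellClass) -> CellClass:
    """Relabel red <-> green; yellow, colorless and cluster labels unchanged."""
    return CellClass(label.phenotype, _SWAP[label.color])


def color_swap(
    image: np.ndarray, annotations: Sequence[_R]
) -> tuple[np.ndarray, list[_R]]:
    """Exchange the GFP (channel 0) and RFP (channel 1) channels and relabel.

    Boxes are unchanged; a DAPI channel (index 2) is unchanged; applying the
    swap twice returns the original image and labels exactly.
    """
    if image.ndim != 3 or image.shape[2] < 2:
        raise ValueError("image must be (H, W, >=2) with GFP and RFP channels")
    swapped = image.copy()
    swapped[:, :, 0] = image[:, :, 1]
    swapped[:, :, 1] = image[:, :, 0]
    out: list[_R] = []
    for a in annotations:
        new = _dc_replace(a, label=swap_label(a.label))
        counts = getattr(a, "member_counts", None)
        if counts is not None:
            new = _dc_replace(
                new, member_counts={_SWAP[c]: n for c, n in counts.items()}
            )
        out.append(new)
    return swapped, out


def saturate(
    image: np.ndarray, factor: float = 1.5, ceiling: int | None = None
) -> np.ndarray:
    """Brighten by ``factor`` and clip: pixel' = min(ceil(pixel * factor), ceiling).

    The scaled value is rounded toward +infinity before clipping, so integer
    images stay integer and the operator is pixelwise monotone (output >=
    input everywhere).  ``factor`` must be >= 1 — this operator only brightens.
    """
    if factor < 1:
        raise ValueError(f"saturation factor must be >= 1, got {factor}")
    if ceiling is None:
        if not np.issubdtype(image.dtype, np.integer):
            raise ValueError("ceiling must be given for non-integer images")
        ceiling = int(np.iinfo(image.dtype).max)
    scaled = np.ceil(np.asarray(image, dtype=np.float64) * factor)
    return np.minimum(scaled, ceiling).astype(image.dtype)


@dataclass(frozen=True)
class AugmentedSample:
    """One dataset variant with its provenance tag."""

    image: np.ndarray
    annotations: tuple
    name: str
    provenance: str  # "original", "swap", "saturate", "swap+saturate"


def expand_dataset(
    samples: Iterable[tuple[np.ndarray, Sequence[_R], str]],
    spec: AugmentationSpec = AugmentationSpec(),
) -> list[AugmentedSample]:
    """Expand (image, annotations, name) samples with the enabled augmentations.

    With both augmentations enabled each input yields four variants
    (original, swapped, saturated, swapped+saturated); with only the swap,
    two.  Variant provenance is recorded on every output sample.
    """
    out: list[AugmentedSample] = []
    for image, annotations, name in samples:
        variants: list[tuple[np.ndarray, Sequence[_R], str]] = [
            (image, annotations, "original")
        ]
        if spec.enable_swap:
            sw_img, sw_ann = color_swap(image, annotations)
            variants.append((sw_img, sw_ann, "swap"))
        if spec.enable_saturation:
            for v_img, v_ann, v_tag in list(variants):
                sat_img = saturate(v_img, spec.saturation_factor, spec.ceiling)
                tag = "saturate" if v_tag == "original" else f"{v_tag}+saturate"
                variants.append((sat_img, v_ann, tag))
        for v_img, v_ann, v_tag in variants:
            suffix = "" if v_tag == "original" else "_" + v_tag.replace("+", "_")
            out.append(
                AugmentedSample(v_img, tuple(v_ann), f"{name}{suffix}", v_tag)
            )
    return out
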