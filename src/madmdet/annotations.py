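"""Core annotation data model: boxes, cell classes, detections, ground truth, and IO.

Coordinate convention
---------------------
All boxes are axis-aligned pixel rectangles in 0-based, half-open
coordinates: a box covers the pixel set ``[x_min, x_max) x [y_min, y_max)``,
so ``area = (x_max - x_min) * (y_max - y_min)`` with no off-by-one terms.
VOC-style XML (1-based, inclusive) is converted on read and write.

Class schemes
-------------
Three schemes are supported, mirroring how a detector can be configured:

* ``two``   — color-independent: ``neuron``, ``glia``
* ``six``   — ``{red, green, yellow} x {neuron, glia}``
* ``seven`` — the six classes plus ``glia_cluster``

File formats
------------
Annotation CSV rows are ``image_path,x1,y1,x2,y2,class_name`` (the
RetinaNet-style training format; a header is tolerated but not required).
Detection CSV rows append a ``confidence`` column.  VOC-style XML is the
dialect produced by common box-labeling tools such as LabelImg.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AnnotationError",
    "BoundingBox",
    "CellClass",
    "Detection",
    "GroundTruthRecord",
    "SCHEMES",
    "scheme_classes",
    "iou",
    "centroid_to_box",
    "map_class",
    "read_detection_csv",
    "write_detection_csv",
    "read_annotation_csv",
    "write_annotation_csv",
    "read_voc_xml",
    "write_voc_xml",
]

PHENOTYPES = ("neuron", "glia", "glia_cluster")
COLORS = ("red", "green", "yellow")
SCHEMES = ("two", "six", "seven")


class AnnotationError(ValueError):
    """Raised for invalid boxes, labels, or malformed annotation files."""


@dataclass(frozen=True, order=True)
class BoundingBox:
    """Axis-aligned pixel rectangle, 0-based, half-open on both axes."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(v) for v in vals):
            raise AnnotationError(f"non-finite coordinates in box {vals}")
        if min(vals) < 0:
            raise AnnotationError(f"negative coordinates in box {vals}")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise AnnotationError(
                f"box {vals} has zero or negative area "
                "(requires x_max > x_min and y_max > y_min)"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def intersection_area(self, other: "BoundingBox") -> float:
        w = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        h = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        if w <= 0 or h <= 0:
            return 0.0
        return w * h

    def overlaps(self, other: "BoundingBox") -> bool:
        """True when the intersection has strictly positive area."""
        return self.intersection_area(other) > 0


@dataclass(frozen=True)
class CellClass:
    """A cell category: phenotype (neuron / glia / glia_cluster) plus MADM color.

    ``color`` is ``None`` exactly when the label is color-independent — i.e.
    for the ``glia_cluster`` class and for two-class-scheme labels.
    """

    phenotype: str
    color: str | None = None

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise AnnotationError(
                f"unknown phenotype {self.phenotype!r}; expected one of {PHENOTYPES}"
            )
        if self.color is not None and self.color not in COLORS:
            raise AnnotationError(
                f"unknown color {self.color!r}; expected one of {COLORS} or None"
            )
        if self.phenotype == "glia_cluster" and self.color is not None:
            raise AnnotationError("glia_cluster carries no color")

    @property
    def name(self) -> str:
        if self.color is None:
            return self.phenotype
        return f"{self.color}_{self.phenotype}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name

    @classmethod
    def from_name(cls, name: str) -> "CellClass":
        """Parse ``red_neuron`` / ``red neuron`` / ``glia`` / ``glia_cluster``."""
        token = name.strip().lower().replace(" ", "_")
        if token == "glia_cluster":
            return cls("glia_cluster")
        if token in ("neuron", "glia"):
            return cls(token)
        if "_" in token:
            color, _, phenotype = token.partition("_")
            if color in COLORS and phenotype in ("neuron", "glia"):
                return cls(phenotype, color)
        raise AnnotationError(
            f"unknown class name {name!r}; valid names: {sorted(ALL_CLASS_NAMES)}"
        )


TWO_CLASSES = (CellClass("neuron"), CellClass("glia"))
SIX_CLASSES = tuple(
    CellClass(p, c) for c in COLORS for p in ("neuron", "glia")
)
SEVEN_CLASSES = SIX_CLASSES + (CellClass("glia_cluster"),)
ALL_CLASS_NAMES = {c.name for c in TWO_CLASSES + SEVEN_CLASSES}


def scheme_classes(scheme: str) -> tuple[CellClass, ...]:
    """The label set of a class scheme (``two``, ``six`` or ``seven``)."""
    if scheme == "two":
        return TWO_CLASSES
    if scheme == "six":
        return SIX_CLASSES
    if scheme == "seven":
        return SEVEN_CLASSES
    raise AnnotationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


@dataclass(frozen=True)
class Detection:
    """Detector output unit: box + class label + confidence in [0, 1].

    ``evidence`` records individual-cell detections absorbed into this one
    during stream merging; it is provenance metadata and does not affect the
    geometric content of the detection.
    """

    box: BoundingBox
    label: CellClass
    confidence: float
    evidence: tuple["Detection", ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0) or not math.isfinite(self.confidence):
            raise AnnotationError(
                f"confidence {self.confidence} outside [0, 1] for {self.label.name}"
            )


@dataclass(frozen=True)
class GroundTruthRecord:
    """Annotation unit: box + class label, plus per-color member counts for clusters."""

    box: BoundingBox
    label: CellClass
    member_counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.member_counts is not None:
            if self.label.phenotype != "glia_cluster":
                raise AnnotationError("member_counts only valid for glia_cluster records")
            bad = [c for c in self.member_counts if c not in COLORS]
            if bad:
                raise AnnotationError(f"unknown member-count colors {bad}")
            if any(v < 0 for v in self.member_counts.values()):
                raise AnnotationError("member counts must be non-negative")
            if sum(self.member_counts.values()) < 2:
                raise AnnotationError("a glia cluster contains at least 2 cells")

    @property
    def member_total(self) -> int:
        return 0 if self.member_counts is None else sum(self.member_counts.values())


# ---------------------------------------------------------------------------
# geometry


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes: overlap area / union area, in [0, 1]."""
    inter = a.intersection_area(b)
    if inter == 0:
        return 0.0
    return inter / (a.area + b.area - inter)


def centroid_to_box(
    centroid: tuple[float, float],
    side: float,
    image_extent: tuple[float, float],
) -> BoundingBox:
    """Fixed-size square box centered on a cell centroid, clipped to the image.

    This is how centroid-style individual-cell annotations are turned into
    training boxes.  At an image border the box shrinks (stays centered on the
    cell) rather than shifting inward.
    """
    cx, cy = centroid
    width, height = image_extent
    if side <= 0:
        raise AnnotationError(f"box side must be positive, got {side}")
    if not (0 <= cx < width and 0 <= cy < height):
        raise AnnotationError(
            f"centroid {centroid} outside image extent {image_extent}"
        )
    half = side / 2.0
    return BoundingBox(
        max(0.0, cx - half),
        max(0.0, cy - half),
        min(float(width), cx + half),
        min(float(height), cy + half),
    )


def map_class(label: CellClass, target_scheme: str) -> CellClass:
    """Map a label into another class scheme.

    six -> two drops the color; six -> seven embeds unchanged; glia_cluster
    cannot be mapped into a scheme without a cluster class.
    """
    if target_scheme not in SCHEMES:
        raise AnnotationError(f"unknown scheme {target_scheme!r}; expected one of {SCHEMES}")
    if label.phenotype == "glia_cluster":
        if target_scheme == "seven":
            return label
        raise AnnotationError(
            f"glia_cluster has no counterpart in the {target_scheme}-class scheme"
        )
    if target_scheme == "two":
        return CellClass(label.phenotype)
    # six / seven require a color
    if label.color is None:
        raise AnnotationError(
            f"cannot map color-independent label {label.name!r} into the "
            f"{target_scheme}-class scheme (color unknown)"
        )
    return label


# ---------------------------------------------------------------------------
# CSV IO (RetinaNet-style annotation rows, plus a confidence column for detections)

_ANN_COLUMNS = ["image_path", "x1", "y1", "x2", "y2", "class_name"]
_DET_COLUMNS = _ANN_COLUMNS + ["confidence"]


def _read_rows(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    try:
        df = pd.read_csv(path, header=None, names=columns, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns)
    if len(df) and str(df.iloc[0]["x1"]).strip().lower() == "x1":
        df = df.iloc[1:].reset_index(drop=True)
    return df


def _row_to_parts(row: pd.Series, lineno: int) -> tuple[BoundingBox, CellClass]:
    try:
        x1, y1, x2, y2 = (float(row[c]) for c in ("x1", "y1", "x2", "y2"))
    except (TypeError, ValueError) as exc:
        raise AnnotationError(f"line {lineno}: malformed coordinates ({exc})") from None
    try:
        box = BoundingBox(x1, y1, x2, y2)
    except AnnotationError as exc:
        raise AnnotationError(f"line {lineno}: {exc}") from None
    try:
        label = CellClass.from_name(str(row["class_name"]))
    except AnnotationError as exc:
        raise AnnotationError(f"line {lineno}: {exc}") from None
    return box, label


def read_annotation_csv(path: str | Path) -> list[tuple[str, GroundTruthRecord]]:
    """Read ``image_path,x1,y1,x2,y2,class_name`` rows as ground-truth records."""
    df = _read_rows(path, _ANN_COLUMNS)
    out: list[tuple[str, GroundTruthRecord]] = []
    for i, row in df.iterrows():
        box, label = _row_to_parts(row, i + 1)
        out.append((str(row["image_path"]), GroundTruthRecord(box, label)))
    return out


def write_annotation_csv(
    path: str | Path,
    records: Iterable[tuple[str, GroundTruthRecord]],
) -> None:
    rows = [
        (img, r.box.x_min, r.box.y_min, r.box.x_max, r.box.y_max, r.label.name)
        for img, r in records
    ]
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(path, index=False, header=False)


def read_detection_csv(path: str | Path) -> list[tuple[str, Detection]]:
    """Read detection rows (annotation columns plus a trailing confidence)."""
    df = _read_rows(path, _DET_COLUMNS)
    out: list[tuple[str, Detection]] = []
    for i, row in df.iterrows():
        box, label = _row_to_parts(row, i + 1)
        try:
            conf = float(row["confidence"])
        except (TypeError, ValueError):
            raise AnnotationError(
                f"line {i + 1}: malformed confidence {row['confidence']!r}"
            ) from None
        if not (0.0 <= conf <= 1.0):
            raise AnnotationError(f"line {i + 1}: confidence {conf} outside [0, 1]")
        out.append((str(row["image_path"]), Detection(box, label, conf)))
    return out


def write_detection_csv(
    path: str | Path,
    detections: Iterable[tuple[str, Detection]],
) -> None:
    rows = [
        (
            img,
            d.box.x_min,
            d.box.y_min,
            d.box.x_max,
            d.box.y_max,
            d.label.name,
            d.confidence,
        )
        for img, d in detections
    ]
    pd.DataFrame(rows, columns=_DET_COLUMNS).to_csv(path, index=False, header=False)


# ---------------------------------------------------------------------------
# VOC-style XML (LabelImg dialect)
#
# VOC coordinates are 1-based inclusive; conversion to 0-based half-open is
# x_min <- xmin - 1, x_max <- xmax (and likewise for y).


def read_voc_xml(path: str | Path) -> list[GroundTruthRecord]:
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"XML file not found: {path}")
    root = ET.parse(path).getroot()
    records: list[GroundTruthRecord] = []
    for idx, obj in enumerate(root.iter("object")):
        name_el = obj.find("name")
        if name_el is None or not (name_el.text or "").strip():
            raise AnnotationError(f"object {idx}: missing name element")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise AnnotationError(f"object {idx}: missing bndbox element")
        try:
            xmin = float(bnd.findtext("xmin"))  # type: ignore[arg-type]
            ymin = float(bnd.findtext("ymin"))  # type: ignore[arg-type]
            xmax = float(bnd.findtext("xmax"))  # type: ignore[arg-type]
            ymax = float(bnd.findtext("ymax"))  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise AnnotationError(f"object {idx}: malformed bndbox coordinates") from None
        box = BoundingBox(xmin - 1, ymin - 1, xmax, ymax)
        label = CellClass.from_name(name_el.text)  # type: ignore[arg-type]
        counts_el = obj.find("member_counts")
        counts = None
        if counts_el is not None:
            counts = {c: int(counts_el.get(c, 0)) for c in COLORS if counts_el.get(c)}
        records.append(GroundTruthRecord(box, label, counts))
    return records


def write_voc_xml(
    path: str | Path,
    records: Sequence[GroundTruthRecord],
    image_filename: str = "image.tif",
    image_size: tuple[int, int] | None = None,
) -> None:
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = image_filename
    if image_size is not None:
        size = ET.SubElement(root, "size")
        ET.SubElement(size, "width").text = str(image_size[0])
        ET.SubElement(size, "height").text = str(image_size[1])
        ET.SubElement(size, "depth").text = "3"
    for rec in records:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = rec.label.name
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = _fmt(rec.box.x_min + 1)
        ET.SubElement(bnd, "ymin").text = _fmt(rec.box.y_min + 1)
        ET.SubElement(bnd, "xmax").text = _fmt(rec.box.x_max)
        ET.SubElement(bnd, "ymax").text = _fmt(rec.box.y_max)
        if rec.member_counts:
            counts_el = ET.SubElement(obj, "member_counts")
            for color, n in sorted(rec.member_counts.items()):
                counts_el.set(color, str(n))
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))
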