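"""Rule-based fusion of the individual-cell and glia-cluster detection streams.

Two detectors look at the same image: one trained (or configured) for
individual cells and one dedicated to glia clusters.  Their outputs are
fused with three ordered rules:

(i)   keep every detected cluster with confidence above ``t_high`` (0.5);
(ii)  keep clusters with confidence above ``t_low`` (0.3) that have
      overlapping individual glial cells — the cells are evidence that a
      cluster is really there — and remove those individual glia;
(iii) eliminate redundant clusters: among clusters whose pairwise overlap
      fraction exceeds ``redundancy_fraction``, only the highest-confidence
      one survives.

"Overlapping" in rule (ii) means any positive intersection area between the
glia box and the cluster box.  The rule-(iii) overlap fraction is the
intersection area over the *smaller* box's area (IoU is available as a
configuration alternative), compared strictly against the threshold.
Neurons are never removed by clusters.

A cluster kept through rule (ii) records the glia it absorbed in its
``evidence`` field.  When merging is re-applied to its own output, recorded
evidence still counts as support, which makes the operation a fixed point
even though the supporting glia are no longer present as separate
detections.

Ground-truth annotations are merged with the same rules with every
confidence treated as 1.0, so that merged predictions are evaluated against
consistently merged ground truth; absorbed ground-truth glia are added to
the cluster's per-color member counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

from .annotations import BoundingBox, Detection, GroundTruthRecord, iou as _iou

__all__ = [
    "MergeParams",
    "overlap_fraction",
    "merge_predictions",
    "merge_ground_truth",
    "MergeProvenance",
    "merge_predictions_with_provenance",
]


@dataclass(frozen=True)
class MergeParams:
    """Thresholds of the three merging rules."""

    t_high: float = 0.5
    t_low: float = 0.3
    redundancy_fraction: float = 0.5
    redundancy_measure: str = "smaller_box"  # or "iou"

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_low <= self.t_high <= 1.0):
            raise ValueError("need 0 <= t_low <= t_high <= 1")
        if not (0.0 < self.redundancy_fraction <= 1.0):
            raise ValueError("redundancy_fraction must be in (0, 1]")
        if self.redundancy_measure not in ("smaller_box", "iou"):
            raise ValueError(f"unknown redundancy measure {self.redundancy_measure!r}")


def overlap_fraction(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection area divided by the smaller box's area, in [0, 1]."""
    inter = a.intersection_area(b)
    if inter == 0:
        return 0.0
    return inter / min(a.area, b.area)


def _redundant(a: Detection, b: Detection, params: MergeParams) -> bool:
    if params.redundancy_measure == "iou":
        frac = _iou(a.box, b.box)
    else:
        frac = overlap_fraction(a.box, b.box)
    return frac > params.redundancy_fraction


@dataclass(frozen=True)
class MergeProvenance:
    """Audit record of one merge: what survived and what was absorbed.

    Indices refer to positions in the input ``clusters`` and ``cells``
    sequences; ``kept_clusters`` carries the surviving detections with their
    absorbed glia attached as ``evidence``.
    """

    kept_clusters: tuple[Detection, ...]
    kept_cluster_indices: tuple[int, ...]
    kept_cells: tuple[Detection, ...]
    kept_cell_indices: tuple[int, ...]
    absorbed: tuple[tuple[int, int], ...]  # (cell index, absorbing cluster index)


def _merge(
    cells: Sequence[Detection],
    clusters: Sequence[Detection],
    params: MergeParams,
) -> MergeProvenance:
    for det in cells:
        if det.label.phenotype == "glia_cluster":
            raise ValueError("cell stream contains a glia_cluster detection")
    for det in clusters:
        if det.label.phenotype != "glia_cluster":
            raise ValueError(
                f"cluster stream contains a non-cluster detection ({det.label.name})"
            )

    glia_idx = [i for i, c in enumerate(cells) if c.label.phenotype == "glia"]

    # rules (i) and (ii): confidence gate, with low-confidence clusters
    # rescued by overlapping individual-glia evidence (current or recorded)
    kept: list[int] = []
    for ci, cl in enumerate(clusters):
        if cl.confidence > params.t_high:
            kept.append(ci)
        elif cl.confidence > params.t_low:
            if cl.evidence or any(
                cl.box.overlaps(cells[gi].box) for gi in glia_idx
            ):
                kept.append(ci)

    # rule (iii): non-maximum suppression of redundant clusters, greedy by
    # confidence (ties: larger area, then input order — deterministic)
    order = sorted(
        kept,
        key=lambda i: (-clusters[i].confidence, -clusters[i].box.area, i),
    )
    surviving: list[int] = []
    for i in order:
        if not any(_redundant(clusters[i], clusters[j], params) for j in surviving):
            surviving.append(i)
    final = sorted(surviving)

    # a glia is removed exactly when it overlaps a surviving cluster
    absorbed: list[tuple[int, int]] = []
    kept_cell_idx: list[int] = []
    for idx, cell in enumerate(cells):
        if cell.label.phenotype == "glia":
            hits = [ci for ci in final if clusters[ci].box.overlaps(cell.box)]
            if hits:
                best = max(
                    hits, key=lambda ci: overlap_fraction(cell.box, clusters[ci].box)
                )
                absorbed.append((idx, best))
                continue
        kept_cell_idx.append(idx)

    # attach each absorbed glia as evidence to every surviving cluster it
    # overlaps (not only its primary owner), so rule-(ii) support survives
    # re-application of the merge to its own output
    final_dets: list[Detection] = []
    for ci in final:
        cl = clusters[ci]
        new_evidence = tuple(
            cells[gi]
            for gi, _owner in absorbed
            if cl.box.overlaps(cells[gi].box)
        )
        if new_evidence:
            cl = dataclasses.replace(cl, evidence=cl.evidence + new_evidence)
        final_dets.append(cl)

    return MergeProvenance(
        kept_clusters=tuple(final_dets),
        kept_cluster_indices=tuple(final),
        kept_cells=tuple(cells[i] for i in kept_cell_idx),
        kept_cell_indices=tuple(kept_cell_idx),
        absorbed=tuple(absorbed),
    )


def merge_predictions(
    cells: Sequence[Detection],
    clusters: Sequence[Detection],
    params: MergeParams = MergeParams(),
) -> list[Detection]:
    """Fuse the two detection streams; returns surviving clusters then cells.

    Every output detection is one of the inputs (boxes, labels and
    confidences are never altered); the operation only removes.
    """
    prov = _merge(cells, clusters, params)
    return list(prov.kept_clusters) + list(prov.kept_cells)


def merge_predictions_with_provenance(
    cells: Sequence[Detection],
    clusters: Sequence[Detection],
    params: MergeParams = MergeParams(),
) -> MergeProvenance:
    """As :func:`merge_predictions`, returning the full audit record."""
    return _merge(cells, clusters, params)


def merge_ground_truth(
    gt_cells: Sequence[GroundTruthRecord],
    gt_clusters: Sequence[GroundTruthRecord],
    params: MergeParams = MergeParams(),
) -> list[GroundTruthRecord]:
    """Merge ground-truth annotations with the same rules, confidences = 1.

    Every annotated cluster passes the rule-(i) gate; annotated individual
    glia overlapping a cluster are absorbed into the cluster record (their
    colors increment the cluster's member counts); neurons are untouched.
    """
    cells = [Detection(r.box, r.label, 1.0) for r in gt_cells]
    clusters = [Detection(r.box, r.label, 1.0) for r in gt_clusters]
    prov = _merge(cells, clusters, params)

    extra_counts: dict[int, dict[str, int]] = {}
    for cell_i, cluster_i in prov.absorbed:
        color = gt_cells[cell_i].label.color
        if color is not None:
            extra_counts.setdefault(cluster_i, {}).setdefault(color, 0)
            extra_counts[cluster_i][color] += 1

    out: list[GroundTruthRecord] = []
    for cluster_i in prov.kept_cluster_indices:
        rec = gt_clusters[cluster_i]
        extra = extra_counts.get(cluster_i, {})
        if extra:
            counts = dict(rec.member_counts or {})
            for color, n in extra.items():
                counts[color] = counts.get(color, 0) + n
            if sum(counts.values()) >= 2:
                rec = dataclasses.replace(rec, member_counts=counts)
        out.append(rec)
    for cell_i in prov.kept_cell_indices:
        out.append(gt_cells[cell_i])
    return out
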