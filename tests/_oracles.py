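"""Independent brute-force oracles and random-instance generators for tests.

Everything here is deliberately written as direct enumeration of the rule
definitions, sharing no code paths with the package implementation, so the
tests compare two independent routes to the same answer.
"""

from __future__ import annotations

import itertools

import numpy as np

from madmdet.annotations import BoundingBox, CellClass, Detection, GroundTruthRecord


# ---------------------------------------------------------------------------
# geometry helpers (re-derived, not imported)


def _inter_area(a: BoundingBox, b: BoundingBox) -> float:
    w = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    h = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    return w * h if (w > 0 and h > 0) else 0.0


def _iou(a: BoundingBox, b: BoundingBox) -> float:
    inter = _inter_area(a, b)
    union = (
        (a.x_max - a.x_min) * (a.y_max - a.y_min)
        + (b.x_max - b.x_min) * (b.y_max - b.y_min)
        - inter
    )
    return inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------
# average-precision oracle: explicit PR enumeration


def brute_force_ap(predictions, ground_truth, iou_threshold=0.5) -> float:
    """AP by direct enumeration of cumulative PR pairs and the adjusted curve."""
    n_gt = len(ground_truth)
    order = sorted(
        range(len(predictions)), key=lambda i: (-predictions[i].confidence, i)
    )
    taken: set[int] = set()
    hits: list[bool] = []
    for i in order:
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(ground_truth):
            if j in taken:
                continue
            v = _iou(predictions[i].box, gt.box)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou > iou_threshold:
            taken.add(best_j)
            hits.append(True)
        else:
            hits.append(False)
    pairs = []
    tp = 0
    for k, hit in enumerate(hits, start=1):
        tp += int(hit)
        pairs.append((tp / n_gt, tp / k))
    # p'(r) = max precision at recall >= r; integrate the step curve
    ap, prev_r = 0.0, 0.0
    for r in sorted({r for r, _p in pairs}):
        if r > prev_r:
            p_adj = max(p for r2, p in pairs if r2 >= r)
            ap += (r - prev_r) * p_adj
            prev_r = r
    return ap


# ---------------------------------------------------------------------------
# merging oracle: subset enumeration of the three rules


def brute_force_merge(cells, clusters, params):
    """Merged output by exhaustive enumeration (<= a handful of clusters).

    Rule (iii) survivors are found by enumerating all subsets and selecting
    the unique subset S satisfying the suppression fixpoint: a kept cluster
    is in S iff no higher-priority member of S is redundant with it.
    """
    glia = [c for c in cells if c.label.phenotype == "glia"]

    def overlaps(a, b):
        return _inter_area(a, b) > 0

    def redundant(a, b):
        inter = _inter_area(a.box, b.box)
        smaller = min(
            (a.box.x_max - a.box.x_min) * (a.box.y_max - a.box.y_min),
            (b.box.x_max - b.box.x_min) * (b.box.y_max - b.box.y_min),
        )
        return inter / smaller > params.redundancy_fraction if smaller > 0 else False

    kept = []
    for cl in clusters:
        if cl.confidence > params.t_high:
            kept.append(cl)
        elif cl.confidence > params.t_low and (
            cl.evidence or any(overlaps(cl.box, g.box) for g in glia)
        ):
            kept.append(cl)

    def priority(cl):
        area = (cl.box.x_max - cl.box.x_min) * (cl.box.y_max - cl.box.y_min)
        return (-cl.confidence, -area, kept.index(cl))

    solutions = []
    for mask in itertools.product([False, True], repeat=len(kept)):
        subset = [cl for cl, m in zip(kept, mask) if m]
        ok = True
        for cl, m in zip(kept, mask):
            suppressed = any(
                priority(other) < priority(cl) and redundant(other, cl)
                for other in subset
                if other is not cl
            )
            if m == suppressed:
                ok = False
                break
        if ok:
            solutions.append(subset)
    assert len(solutions) == 1, "suppression fixpoint must be unique"
    final = solutions[0]

    out_cells = []
    for cell in cells:
        if cell.label.phenotype == "glia" and any(
            overlaps(cl.box, cell.box) for cl in final
        ):
            continue
        out_cells.append(cell)
    return final, out_cells


# ---------------------------------------------------------------------------
# random instance generators (seeded by the caller)


def random_box(rng, size_lo, size_hi, extent=200.0) -> BoundingBox:
    w = rng.uniform(size_lo, size_hi)
    h = rng.uniform(size_lo, size_hi)
    x = rng.uniform(0, extent - w)
    y = rng.uniform(0, extent - h)
    return BoundingBox(x, y, x + w, y + h)


def random_merge_instance(rng):
    """Up to 5 cluster and 10 cell detections with random boxes/confidences."""
    clusters = [
        Detection(random_box(rng, 20, 60), CellClass("glia_cluster"), round(float(rng.uniform()), 3))
        for _ in range(int(rng.integers(0, 6)))
    ]
    cells = []
    for _ in range(int(rng.integers(0, 11))):
        phenotype = "glia" if rng.uniform() < 0.5 else "neuron"
        color = ("red", "green", "yellow")[int(rng.integers(0, 3))]
        cells.append(
            Detection(random_box(rng, 8, 20), CellClass(phenotype, color), round(float(rng.uniform()), 3))
        )
    return cells, clusters


def random_ap_instance(rng):
    """Up to 10 predictions against up to 5 ground-truth boxes of one class."""
    label = CellClass("neuron", "red")
    n_gt = int(rng.integers(1, 6))
    gts = [GroundTruthRecord(random_box(rng, 10, 30, 100.0), label) for _ in range(n_gt)]
    preds = []
    for _ in range(int(rng.integers(0, 11))):
        if gts and rng.uniform() < 0.6:
            # jittered copy of a ground-truth box: plausible detection
            base = gts[int(rng.integers(0, n_gt))].box
            dx, dy = rng.uniform(-6, 6), rng.uniform(-6, 6)
            box = BoundingBox(
                max(0.0, base.x_min + dx),
                max(0.0, base.y_min + dy),
                base.x_max + dx + 6.001,
                base.y_max + dy + 6.001,
            )
        else:
            box = random_box(rng, 10, 30, 100.0)
        preds.append(Detection(box, label, round(float(rng.uniform()), 3)))
    return preds, gts
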