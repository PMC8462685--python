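"""Stream-merging rules against a brute-force oracle, plus the declared
fixed-point and monotonicity properties."""

import numpy as np
import pytest

from _oracles import brute_force_merge, random_merge_instance
from madmdet.annotations import BoundingBox, CellClass, Detection, GroundTruthRecord
from madmdet.merging import (
    MergeParams,
    merge_ground_truth,
    merge_predictions,
    merge_predictions_with_provenance,
    overlap_fraction,
)


def cluster(x1, y1, x2, y2, conf):
    return Detection(BoundingBox(x1, y1, x2, y2), CellClass("glia_cluster"), conf)


def glia(x1, y1, x2, y2, conf=0.7, color="red"):
    return Detection(BoundingBox(x1, y1, x2, y2), CellClass("glia", color), conf)


def neuron(x1, y1, x2, y2, conf=0.7):
    return Detection(BoundingBox(x1, y1, x2, y2), CellClass("neuron", "red"), conf)


def signature(dets):
    return sorted((d.box, d.label.name, d.confidence) for d in dets)


class TestOverlapFraction:
    def test_identical_boxes(self):
        b = BoundingBox(0, 0, 10, 10)
        assert overlap_fraction(b, b) == 1.0

    def test_disjoint(self):
        assert overlap_fraction(BoundingBox(0, 0, 10, 10), BoundingBox(20, 20, 30, 30)) == 0.0

    def test_containment_normalizes_by_smaller(self):
        small = BoundingBox(0, 0, 10, 10)
        big = BoundingBox(0, 0, 20, 20)
        assert overlap_fraction(small, big) == 1.0
        assert overlap_fraction(big, small) == 1.0


class TestMergeRules:
    def test_high_confidence_cluster_kept_without_support(self):
        out = merge_predictions([], [cluster(0, 0, 50, 50, 0.6)])
        assert len(out) == 1

    def test_supported_low_confidence_cluster_absorbs_glia(self):
        cl = cluster(0, 0, 50, 50, 0.35)
        g = glia(10, 10, 30, 30)
        out = merge_predictions([g], [cl])
        assert signature(out) == signature([cl])

    def test_unsupported_low_confidence_cluster_dropped(self):
        cl = cluster(0, 0, 50, 50, 0.25)
        g = glia(10, 10, 30, 30)
        out = merge_predictions([g], [cl])
        assert signature(out) == signature([g])

    def test_redundant_cluster_loses_to_higher_confidence(self):
        a = cluster(0, 0, 40, 40, 0.8)
        b = cluster(10, 10, 45, 45, 0.6)  # overlap fraction > 0.5 of b
        out = merge_predictions([], [a, b])
        assert signature(out) == signature([a])

    def test_neurons_never_removed(self):
        cl = cluster(0, 0, 50, 50, 0.9)
        n = neuron(10, 10, 25, 25)
        out = merge_predictions([n], [cl])
        assert signature(out) == signature([cl, n])

    def test_thresholds_compare_strictly(self):
        # "above 0.5" / "above 0.3": boundary values do not pass
        at_high = cluster(0, 0, 50, 50, 0.5)
        assert merge_predictions([], [at_high]) == []
        at_low = cluster(0, 0, 50, 50, 0.3)
        assert merge_predictions([glia(10, 10, 30, 30)], [at_low], MergeParams()) == [
            glia(10, 10, 30, 30)
        ]

    def test_stream_validation(self):
        with pytest.raises(ValueError):
            merge_predictions([cluster(0, 0, 10, 10, 0.9)], [])
        with pytest.raises(ValueError):
            merge_predictions([], [glia(0, 0, 10, 10)])


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        params = MergeParams()
        for _ in range(400):
            cells, clusters = random_merge_instance(rng)
            got = merge_predictions(cells, clusters, params)
            want_clusters, want_cells = brute_force_merge(cells, clusters, params)
            assert signature(got) == signature(want_clusters + want_cells)

    def test_two_cluster_worked_example(self):
        # conf 0.8 and 0.6 with overlap fraction ~0.7: only 0.8 survives
        a = cluster(0, 0, 40, 40, 0.8)
        b = cluster(8, 8, 42, 42, 0.6)
        assert overlap_fraction(a.box, b.box) > 0.5
        got = merge_predictions([], [a, b])
        want_clusters, _ = brute_force_merge([], [a, b], MergeParams())
        assert signature(got) == signature(want_clusters) == signature([a])


class TestDeclaredProperties:
    def test_conservation_output_subset_of_input(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            cells, clusters = random_merge_instance(rng)
            out = merge_predictions(cells, clusters)
            pool = signature(cells + clusters)
            for item in signature(out):
                assert item in pool

    def test_fixed_point_under_reapplication(self):
        rng = np.random.default_rng(8)
        params = MergeParams()
        for _ in range(200):
            cells, clusters = random_merge_instance(rng)
            out = merge_predictions(cells, clusters, params)
            out_clusters = [d for d in out if d.label.phenotype == "glia_cluster"]
            out_cells = [d for d in out if d.label.phenotype != "glia_cluster"]
            again = merge_predictions(out_cells, out_clusters, params)
            assert signature(again) == signature(out)

    def test_raising_t_high_never_adds_clusters(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            cells, clusters = random_merge_instance(rng)
            previous = None
            for t_high in (0.3, 0.45, 0.6, 0.75, 0.9, 1.0):
                out = merge_predictions(
                    cells, clusters, MergeParams(t_high=t_high, t_low=0.3)
                )
                n = sum(1 for d in out if d.label.phenotype == "glia_cluster")
                if previous is not None:
                    assert n <= previous
                previous = n


class TestGroundTruthMerging:
    def test_cluster_absorbs_overlapping_glia_into_counts(self):
        gt_cluster = GroundTruthRecord(
            BoundingBox(0, 0, 60, 60), CellClass("glia_cluster"), {"red": 2}
        )
        gt_glia = [
            GroundTruthRecord(BoundingBox(5, 5, 20, 20), CellClass("glia", "red")),
            GroundTruthRecord(BoundingBox(30, 30, 50, 50), CellClass("glia", "green")),
            GroundTruthRecord(BoundingBox(40, 5, 58, 25), CellClass("glia", "red")),
        ]
        out = merge_ground_truth(gt_glia, [gt_cluster])
        assert len(out) == 1
        assert out[0].member_counts == {"red": 4, "green": 1}

    def test_no_clusters_unchanged(self):
        gt = [GroundTruthRecord(BoundingBox(0, 0, 10, 10), CellClass("glia", "red"))]
        assert merge_ground_truth(gt, []) == gt

    def test_neuron_inside_cluster_retained(self):
        gt_cluster = GroundTruthRecord(
            BoundingBox(0, 0, 60, 60), CellClass("glia_cluster"), {"red": 2}
        )
        gt_neuron = GroundTruthRecord(BoundingBox(10, 10, 25, 25), CellClass("neuron", "red"))
        out = merge_ground_truth([gt_neuron], [gt_cluster])
        assert gt_neuron in out


class TestProvenance:
    def test_absorbed_glia_recorded_with_owner(self):
        cl = cluster(0, 0, 50, 50, 0.9)
        g = glia(10, 10, 30, 30)
        prov = merge_predictions_with_provenance([g, neuron(60, 60, 70, 70)], [cl])
        assert prov.absorbed == ((0, 0),)
        assert prov.kept_clusters[0].evidence == (g,)
        assert prov.kept_cell_indices == (1,)
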