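"""Box geometry, class-scheme mapping, and annotation-file round trips."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from madmdet.annotations import (
    AnnotationError,
    BoundingBox,
    CellClass,
    Detection,
    GroundTruthRecord,
    centroid_to_box,
    iou,
    map_class,
    read_annotation_csv,
    read_detection_csv,
    read_voc_xml,
    write_annotation_csv,
    write_detection_csv,
    write_voc_xml,
)


def bb(x1, y1, x2, y2):
    return BoundingBox(x1, y1, x2, y2)


class TestBoundingBox:
    @pytest.mark.parametrize(
        "coords",
        [(0, 0, 0, 10), (0, 0, 10, 0), (5, 5, 5, 5), (10, 0, 5, 10), (-1, 0, 5, 5)],
    )
    def test_degenerate_boxes_rejected(self, coords):
        with pytest.raises(AnnotationError):
            BoundingBox(*coords)

    def test_non_finite_rejected(self):
        with pytest.raises(AnnotationError):
            BoundingBox(0, 0, math.inf, 10)

    def test_area_uses_half_open_convention(self):
        assert bb(0, 0, 10, 10).area == 100


class TestIoU:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0, 0, 10, 10), (0, 0, 10, 10), 1.0),
            ((0, 0, 10, 10), (20, 20, 30, 30), 0.0),
            # intersection 5x10 = 50, union 100 + 100 - 50 = 150
            ((0, 0, 10, 10), (5, 0, 15, 10), 50 / 150),
            ((0, 0, 10, 10), (10, 0, 20, 10), 0.0),  # touching edges, no area
        ],
    )
    def test_known_values(self, a, b, expected):
        assert iou(bb(*a), bb(*b)) == pytest.approx(expected)

    @given(
        st.tuples(*[st.floats(0, 100) for _ in range(2)]),
        st.tuples(*[st.floats(1, 50) for _ in range(2)]),
        st.tuples(*[st.floats(0, 100) for _ in range(2)]),
        st.tuples(*[st.floats(1, 50) for _ in range(2)]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_symmetric_and_bounded(self, o1, s1, o2, s2):
        a = bb(o1[0], o1[1], o1[0] + s1[0], o1[1] + s1[1])
        b = bb(o2[0], o2[1], o2[0] + s2[0], o2[1] + s2[1])
        v = iou(a, b)
        assert v == iou(b, a)
        assert 0.0 <= v <= 1.0
        assert iou(a, a) == 1.0


class TestCentroidToBox:
    @pytest.mark.parametrize(
        "centroid, expected",
        [
            ((50, 50), (40, 40, 60, 60)),
            ((5, 5), (0, 0, 15, 15)),  # clipped at the origin
            ((99, 50), (89, 40, 100, 60)),  # clipped at the right edge
        ],
    )
    def test_fixed_size_box_with_border_clipping(self, centroid, expected):
        box = centroid_to_box(centroid, side=20, image_extent=(100, 100))
        assert (box.x_min, box.y_min, box.x_max, box.y_max) == expected

    def test_centroid_outside_image_rejected(self):
        with pytest.raises(AnnotationError):
            centroid_to_box((120, 50), 20, (100, 100))


class TestClassScheme:
    @pytest.mark.parametrize(
        "label, scheme, expected",
        [
            (CellClass("neuron", "red"), "two", CellClass("neuron")),
            (CellClass("glia", "yellow"), "two", CellClass("glia")),
            (CellClass("glia", "green"), "seven", CellClass("glia", "green")),
            (CellClass("glia_cluster"), "seven", CellClass("glia_cluster")),
        ],
    )
    def test_mapping(self, label, scheme, expected):
        assert map_class(label, scheme) == expected

    def test_cluster_has_no_six_class_counterpart(self):
        with pytest.raises(AnnotationError):
            map_class(CellClass("glia_cluster"), "six")

    def test_two_scheme_mapping_idempotent(self):
        once = map_class(CellClass("neuron", "red"), "two")
        assert map_class(once, "two") == once

    def test_unknown_class_name_lists_valid_ones(self):
        with pytest.raises(AnnotationError, match="glia_cluster"):
            CellClass.from_name("blue neuron")


class TestCsvRoundTrip:
    def records(self):
        return [
            ("a.tif", Detection(bb(0, 0, 10, 10), CellClass("neuron", "red"), 0.9)),
            ("a.tif", Detection(bb(5, 5, 25, 30), CellClass("glia", "yellow"), 0.25)),
            ("b.tif", Detection(bb(1, 2, 3, 4), CellClass("glia_cluster"), 0.5)),
        ]

    def test_detection_round_trip(self, tmp_path):
        path = tmp_path / "det.csv"
        write_detection_csv(path, self.records())
        assert read_detection_csv(path) == self.records()

    def test_annotation_round_trip(self, tmp_path):
        rows = [
            (img, GroundTruthRecord(d.box, d.label))
            for img, d in self.records()
            if d.label.phenotype != "glia_cluster"
        ]
        path = tmp_path / "ann.csv"
        write_annotation_csv(path, rows)
        assert read_annotation_csv(path) == rows

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("image_path,x1,y1,x2,y2,class_name\n")
        assert read_annotation_csv(path) == []

    def test_unknown_class_reports_line_and_valid_names(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a.tif,0,0,10,10,red_neuron\na.tif,0,0,10,10,blue neuron\n")
        with pytest.raises(AnnotationError, match=r"line 2.*red_neuron"):
            read_annotation_csv(path)

    def test_inverted_coordinates_report_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a.tif,10,0,5,10,red_neuron\n")
        with pytest.raises(AnnotationError, match="line 1"):
            read_annotation_csv(path)

    def test_confidence_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a.tif,0,0,10,10,red_neuron,1.3\n")
        with pytest.raises(AnnotationError, match="line 1"):
            read_detection_csv(path)


class TestVocXml:
    def test_one_based_inclusive_converted(self, tmp_path):
        path = tmp_path / "ann.xml"
        path.write_text(
            "<annotation><object><name>glia_cluster</name>"
            "<bndbox><xmin>1</xmin><ymin>1</ymin><xmax>10</xmax><ymax>10</ymax>"
            "</bndbox></object></annotation>"
        )
        (rec,) = read_voc_xml(path)
        assert (rec.box.x_min, rec.box.y_min, rec.box.x_max, rec.box.y_max) == (0, 0, 10, 10)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "none.xml"
        path.write_text("<annotation></annotation>")
        assert read_voc_xml(path) == []

    def test_missing_bndbox_names_object_index(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text(
            "<annotation><object><name>red_glia</name></object></annotation>"
        )
        with pytest.raises(AnnotationError, match="object 0"):
            read_voc_xml(path)

    def test_round_trip_preserves_records(self, tmp_path):
        records = [
            GroundTruthRecord(bb(0, 0, 10, 10), CellClass("glia", "red")),
            GroundTruthRecord(
                bb(20, 30, 80, 90), CellClass("glia_cluster"), {"red": 3, "yellow": 1}
            ),
        ]
        path = tmp_path / "rt.xml"
        write_voc_xml(path, records, image_size=(100, 100))
        assert read_voc_xml(path) == records
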