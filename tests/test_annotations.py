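"""Selection tables, class mapping and soft ground-truth labels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from katydet.annotations import (
    Annotation,
    ClassMap,
    SelectionTableError,
    assign_labels,
    centralization_penalty,
    collect_background,
    read_selection_table,
    write_selection_table,
)
from katydet.signals import Recording, Segment


@pytest.fixture
def class_map():
    return ClassMap(
        class_names=["sp_a", "sp_b", "sp_c"],
        merges={"sp_a_variant": "sp_a"},
        penalty_classes=frozenset(["sp_b"]),
        focal_advance={"sp_a": 0.05},
    )


def seg(start_s=0.0, provenance="insitu"):
    return Segment(samples=np.zeros(76_800), start_s=start_s, provenance=provenance)


class TestSelectionTables:
    def test_round_trip(self, tmp_path, class_map):
        anns = [
            Annotation(1.0, 1.5, 8000, 12000, "sp_a"),
            Annotation(2.25, 2.3, 20000, 30000, "sp_b"),
        ]
        path = tmp_path / "t.selections.txt"
        write_selection_table(anns, path)
        back = read_selection_table(path)
        assert back == anns

    def test_times_preserved_to_6_decimals(self, tmp_path):
        anns = [Annotation(1.123456789, 2.987654321, 100.0, 200.0, "x")]
        path = tmp_path / "t.txt"
        write_selection_table(anns, path)
        back = read_selection_table(path)[0]
        assert abs(back.begin_s - 1.123456789) < 1e-6
        assert abs(back.end_s - 2.987654321) < 1e-6

    def test_empty_sequence_header_only(self, tmp_path):
        path = tmp_path / "empty.txt"
        write_selection_table([], path)
        assert read_selection_table(path) == []
        assert "Begin Time (s)" in path.read_text().splitlines()[0]

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("Selection\tBegin Time (s)\tEnd Time (s)\tTags\n1\t0.0\t1.0\tx\n")
        with pytest.raises(SelectionTableError, match="Low Freq"):
            read_selection_table(path)

    def test_unparsable_cell_reports_row(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(
            "Begin Time (s)\tEnd Time (s)\tLow Freq (Hz)\tHigh Freq (Hz)\tTags\n"
            "0.0\toops\t100\t200\tx\n"
        )
        with pytest.raises(SelectionTableError, match="row 1"):
            read_selection_table(path)

    def test_begin_after_end_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(
            "Begin Time (s)\tEnd Time (s)\tLow Freq (Hz)\tHigh Freq (Hz)\tTags\n"
            "2.0\t1.0\t100\t200\tx\n"
        )
        with pytest.raises(SelectionTableError):
            read_selection_table(path)

    def test_duplicate_views_deduplicated(self, tmp_path):
        path = tmp_path / "v.txt"
        path.write_text(
            "Selection\tView\tBegin Time (s)\tEnd Time (s)\tLow Freq (Hz)\tHigh Freq (Hz)\tTags\n"
            "1\tSpectrogram 1\t0.0\t1.0\t100\t200\tx\n"
            "1\tWaveform 1\t0.0\t1.0\t100\t200\tx\n"
        )
        assert len(read_selection_table(path)) == 1


class TestAssignLabels:
    def test_contained_annotation_scores_one(self, class_map):
        s = seg(start_s=0.8)
        labels = assign_labels(s, [Annotation(1.0, 1.2, 8e3, 1e4, "sp_a")], class_map)
        assert labels[0] == 1.0 and labels[1] == 0.0 and labels[2] == 0.0

    def test_segment_inside_long_annotation_scores_one(self, class_map):
        labels = assign_labels(seg(0.0), [Annotation(0.0, 5.0, 8e3, 1e4, "sp_c")], class_map)
        assert labels[2] == 1.0

    def test_partial_overlap_rule(self, class_map):
        # overlap 0.2 s, annotation 0.6 s -> 0.2/0.6
        labels = assign_labels(seg(0.0), [Annotation(0.6, 1.2, 8e3, 1e4, "sp_a")], class_map)
        assert labels[0] == pytest.approx(0.2 / 0.6)

    def test_no_overlap_all_zero(self, class_map):
        labels = assign_labels(seg(0.0), [Annotation(5.0, 5.5, 8e3, 1e4, "sp_a")], class_map)
        assert not labels.any()

    def test_merged_tag_maps_to_same_class(self, class_map):
        labels = assign_labels(seg(0.8), [Annotation(1.0, 1.2, 8e3, 1e4, "sp_a_variant")], class_map)
        assert labels[0] == 1.0

    def test_background_contributes_nothing(self, class_map):
        labels = assign_labels(seg(0.0), [Annotation(0.0, 2.0, 0, 48e3, "background")], class_map)
        assert not labels.any()

    def test_unknown_tag_is_configuration_error(self, class_map):
        with pytest.raises(KeyError, match="mystery"):
            assign_labels(seg(0.0), [Annotation(0.1, 0.3, 8e3, 1e4, "mystery")], class_map)

    def test_same_class_annotations_combine_by_max(self, class_map):
        anns = [
            Annotation(0.1, 0.3, 8e3, 1e4, "sp_a"),   # contained -> 1.0
            Annotation(0.6, 1.2, 8e3, 1e4, "sp_a"),   # partial -> 1/3
        ]
        assert assign_labels(seg(0.0), anns, class_map)[0] == 1.0

    @settings(deadline=None, max_examples=40)
    @given(st.permutations(range(4)))
    def test_order_invariance(self, order):
        class_map = ClassMap(class_names=["sp_a", "sp_b", "sp_c"])
        anns = [
            Annotation(0.1, 0.3, 8e3, 1e4, "sp_a"),
            Annotation(0.5, 1.1, 8e3, 1e4, "sp_a"),
            Annotation(0.2, 0.9, 8e3, 1e4, "sp_b"),
            Annotation(0.75, 0.95, 8e3, 1e4, "sp_c"),
        ]
        ref = assign_labels(seg(0.0), anns, class_map)
        shuffled = assign_labels(seg(0.0), [anns[i] for i in order], class_map)
        np.testing.assert_array_equal(ref, shuffled)

    def test_penalty_applied_only_to_focal(self, class_map):
        # short sp_b call near the segment edge: relative [0.65, 0.70]
        ann = Annotation(0.65, 0.70, 8e3, 1e4, "sp_b")
        focal = assign_labels(seg(0.0, provenance="focal"), [ann], class_map)
        insitu = assign_labels(seg(0.0, provenance="insitu"), [ann], class_map)
        assert insitu[1] == 1.0  # contained, no penalty off focal
        assert focal[1] == pytest.approx(0.375)  # 1 - 0.25/0.4

    @settings(deadline=None, max_examples=100)
    @given(
        begin=st.floats(0.0, 3.0),
        dur=st.floats(0.01, 2.0),
        start=st.floats(0.0, 2.4),
    )
    def test_scores_always_in_unit_interval(self, begin, dur, start):
        class_map = ClassMap(class_names=["sp_a"], penalty_classes=frozenset(["sp_a"]))
        s = Segment(samples=np.zeros(76_800), start_s=start, provenance="focal")
        labels = assign_labels(s, [Annotation(begin, begin + dur, 8e3, 1e4, "sp_a")], class_map)
        assert 0.0 <= labels[0] <= 1.0


class TestCentralizationPenalty:
    @pytest.mark.parametrize(
        "rel_begin,rel_end,expected",
        [
            (0.30, 0.35, 1.0),     # inside central 25-75%
            (0.38, 0.42, 1.0),     # spans the mid-epoch
            (0.65, 0.70, 0.375),   # delta = 0.25 -> 1 - 0.25/0.4
            (0.00, 0.05, 1 - 0.35 / 0.4),  # left edge, delta = 0.35
        ],
    )
    def test_penalty_factor(self, rel_begin, rel_end, expected):
        s = seg(0.0, provenance="focal")
        f = centralization_penalty(s, Annotation(rel_begin + 1e-9, rel_end, 8e3, 1e4, "sp_a"))
        assert f == pytest.approx(expected, abs=1e-6)

    def test_long_annotation_not_penalized(self):
        assert centralization_penalty(seg(0.0), Annotation(0.0, 0.5, 8e3, 1e4, "x")) == 1.0

    def test_clipping_before_evaluation(self):
        # annotation hangs off the segment start; the clipped part spans the centre
        s = seg(1.0)
        assert centralization_penalty(s, Annotation(0.9, 1.15, 8e3, 1e4, "x")) == pytest.approx(
            1 - 0.25 / 0.4
        )

    @settings(deadline=None, max_examples=100)
    @given(begin=st.floats(0.0, 0.79), dur=st.floats(0.005, 0.39))
    def test_factor_never_negative_for_overlapping(self, begin, dur):
        s = seg(0.0)
        f = centralization_penalty(s, Annotation(begin + 1e-9, min(begin + dur, 2.0), 8e3, 1e4, "x"))
        assert 0.0 <= f <= 1.0


class TestCollectBackground:
    def make_recording(self, duration_s=4.0):
        return Recording(samples=np.zeros(int(duration_s * 96_000)), rate=96_000,
                         provenance="insitu", identifier="r")

    def test_counts_match_enumeration_oracle(self):
        cm = ClassMap(class_names=["sp_a"])
        anns = [Annotation(0.35, 1.35, 0, 48e3, "background")]
        rec = self.make_recording()
        training, additive = collect_background(rec, anns, cm)

        def enumerate_contained(advance):
            starts = np.arange(0, int((4.0 - 0.8) / advance) + 1) * advance
            return [s for s in starts if s >= 0.35 and s + 0.8 <= 1.35 + 1e-9]

        assert len(training) == len(enumerate_contained(0.2))
        assert len(additive) == len(enumerate_contained(0.1)) == 2

    def test_no_background_annotations_empty(self):
        cm = ClassMap(class_names=["sp_a"])
        t, a = collect_background(self.make_recording(), [], cm)
        assert t == [] and a == []

    def test_segment_touching_call_excluded(self):
        cm = ClassMap(class_names=["sp_a"])
        anns = [
            Annotation(0.0, 4.0, 0, 48e3, "background"),
            Annotation(1.0, 1.1, 8e3, 1e4, "sp_a"),
        ]
        t, a = collect_background(self.make_recording(), anns, cm)
        for s in t + a:
            assert s.end_s <= 1.0 + 1e-9 or s.start_s >= 1.1 - 1e-9

    def test_rejects_non_insitu_recording(self):
        cm = ClassMap(class_names=["sp_a"])
        rec = Recording(samples=np.zeros(96_000), rate=96_000, provenance="focal")
        with pytest.raises(ValueError):
            collect_background(rec, [], cm)


class TestClassMap:
    def test_background_tag_cannot_be_class(self):
        with pytest.raises(ValueError):
            ClassMap(class_names=["background", "x"])

    def test_merge_target_must_exist(self):
        with pytest.raises(ValueError):
            ClassMap(class_names=["a"], merges={"b": "zzz"})

    def test_per_class_focal_advance(self):
        cm = ClassMap(class_names=["a", "b"], focal_advance={"a": 0.05})
        assert cm.advance_for("a") == 0.05
        assert cm.advance_for("b") == 0.2
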