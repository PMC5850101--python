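"""Data model and delimited-text I/O."""

import math

import numpy as np
import pytest

from rmqsar.data import (ActivitySet, DataError, DescriptorMatrix,
                         SubsetPartition, align, read_activity_table,
                         read_descriptor_table, read_partition,
                         write_activity_table, write_descriptor_table,
                         write_partition)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestReadDescriptorTable:
    def test_well_formed(self, tmp_path):
        p = _write(tmp_path, "d.csv", "id,a,b\nc1,1,2\nc2,3,4\nc3,5,6\n")
        dm = read_descriptor_table(p)
        assert dm.n_compounds == 3 and dm.n_descriptors == 2
        assert dm.compound_ids == ["c1", "c2", "c3"]
        assert not dm.missing_mask.any()
        assert dm.values[2, 1] == 6.0

    def test_blank_cell_becomes_missing(self, tmp_path):
        p = _write(tmp_path, "d.csv", "id,a,b\nc1,1,\nc2,3,4\n")
        dm = read_descriptor_table(p)
        assert dm.missing_mask[0, 1] and not dm.missing_mask[1, 1]

    def test_non_numeric_cell_becomes_missing(self, tmp_path):
        p = _write(tmp_path, "d.csv", "id,a\nc1,n/a\nc2,2\n")
        dm = read_descriptor_table(p)
        assert dm.missing_mask[0, 0]

    def test_duplicate_descriptor_name_rejected(self, tmp_path):
        p = _write(tmp_path, "d.csv", "id,a,a\nc1,1,2\n")
        with pytest.raises(DataError, match="a"):
            read_descriptor_table(p)

    def test_ragged_row_rejected_with_row_number(self, tmp_path):
        p = _write(tmp_path, "d.csv", "id,a,b\nc1,1,2\nc2,3\n")
        with pytest.raises(DataError, match="row 3"):
            read_descriptor_table(p)

    def test_duplicate_compound_id_rejected(self, tmp_path):
        p = _write(tmp_path, "d.csv", "id,a\nc1,1\nc1,2\n")
        with pytest.raises(DataError, match="duplicate"):
            read_descriptor_table(p)

    @pytest.mark.parametrize("delim", [",", "\t", ";"])
    def test_delimiter_autodetect(self, tmp_path, delim):
        p = _write(tmp_path, "d.txt", f"id{delim}a\nc1{delim}1\nc2{delim}2\n")
        dm = read_descriptor_table(p)
        assert dm.descriptor_names == ["a"]


class TestActivity:
    def test_ic50_to_log10(self, tmp_path):
        p = _write(tmp_path, "a.csv", "id,ic50\nc1,1000\n")
        act = read_activity_table(p, ic50_given=True)
        assert act.log10_ic50[0] == pytest.approx(3.0)

    def test_dataset_minimum(self, tmp_path):
        p = _write(tmp_path, "a.csv", "id,ic50\nc1,0.8\n")
        act = read_activity_table(p)
        assert act.log10_ic50[0] == pytest.approx(math.log10(0.8), abs=1e-12)
        assert act.log10_ic50[0] == pytest.approx(-0.0969, abs=1e-4)

    def test_negative_ic50_rejected(self, tmp_path):
        p = _write(tmp_path, "a.csv", "id,ic50\nc1,-5\n")
        with pytest.raises(DataError):
            read_activity_table(p)

    def test_log10_input_mode(self, tmp_path):
        p = _write(tmp_path, "a.csv", "id,log\nc1,2.0\n")
        act = read_activity_table(p, ic50_given=False)
        assert act.ic50[0] == pytest.approx(100.0)


class TestAlign:
    def test_identical_sets_unchanged(self, planted_small):
        dm, act, _ = planted_small
        dm2, act2 = align(dm, act)
        assert dm2.compound_ids == dm.compound_ids
        np.testing.assert_array_equal(act2.log10_ic50, act.log10_ic50)

    def test_missing_id_dropped(self, planted_small):
        dm, act, _ = planted_small
        act_short = act.subset(np.arange(1, len(act.compound_ids)))
        dm2, act2 = align(dm, act_short)
        assert dm2.n_compounds == dm.n_compounds - 1
        assert dm.compound_ids[0] not in dm2.compound_ids
        assert dm2.compound_ids == act2.compound_ids

    def test_disjoint_sets_rejected(self, planted_small):
        dm, _, _ = planted_small
        other = ActivitySet.from_ic50(["zz1", "zz2"], [10.0, 20.0])
        with pytest.raises(DataError):
            align(dm, other)


class TestRoundTrip:
    def test_descriptor_round_trip_bit_exact(self, tmp_path, planted_small):
        dm, _, _ = planted_small
        p = tmp_path / "out.csv"
        write_descriptor_table(dm, p)
        back = read_descriptor_table(p)
        assert back.descriptor_names == dm.descriptor_names
        assert back.compound_ids == dm.compound_ids
        finite = ~dm.missing_mask
        np.testing.assert_array_equal(back.values[finite], dm.values[finite])
        np.testing.assert_array_equal(back.missing_mask, dm.missing_mask)

    def test_activity_and_partition_round_trip(self, tmp_path, planted_small):
        dm, act, _ = planted_small
        pa = tmp_path / "act.csv"
        write_activity_table(act, pa)
        act2 = read_activity_table(pa)
        np.testing.assert_array_equal(act2.ic50, act.ic50)
        n = dm.n_compounds
        labels = ["train"] * (n - 4) + ["val"] * 2 + ["test"] * 2
        part = SubsetPartition(list(dm.compound_ids), labels)
        pp = tmp_path / "part.csv"
        write_partition(part, pp)
        part2 = read_partition(pp)
        assert part2.labels == part.labels


class TestInvariants:
    def test_partition_requires_all_subsets(self):
        with pytest.raises(DataError, match="test"):
            SubsetPartition(["a", "b"], ["train", "val"])

    def test_matrix_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            DescriptorMatrix(["a"], ["x", "y"], np.ones((1, 3)))

    def test_column_selection_by_name_order(self, planted_small):
        dm, _, _ = planted_small
        names = [dm.descriptor_names[5], dm.descriptor_names[1]]
        sub = dm.select_columns(names)
        np.testing.assert_array_equal(sub.values[:, 0], dm.values[:, 5])
        np.testing.assert_array_equal(sub.values[:, 1], dm.values[:, 1])
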