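"""Representation-agnostic accessors: the dense and sparse forms of any
table must answer identically, matching a brute-force dense oracle."""

import itertools

import pytest

from biomlite import (
    BiomError,
    BiomUnknownIDError,
    FixtureSpec,
    build_table,
    generate_fixture,
    get_column,
    get_metadata,
    get_row,
    get_value,
    nnz,
    read_v1,
    read_v2,
    set_metadata,
    to_dense,
    to_sparse,
    write_v1,
    write_v2,
)


class TestGetValue:
    def test_worked_example_entries(self, worked_table):
        assert get_value(worked_table, "row2", "col2") == 3
        assert get_value(worked_table, "row1", "col1") == 0

    def test_sparse_form_answers_identically(self, worked_table):
        s = to_sparse(worked_table)
        assert get_value(s, "row2", "col2") == 3
        assert get_value(s, "row1", "col1") == 0  # absent position reads as zero

    def test_unknown_ids_name_the_axis(self, worked_table):
        with pytest.raises(BiomUnknownIDError) as exc:
            get_value(worked_table, "nope", "col1")
        assert exc.value.axis == "row"
        with pytest.raises(BiomUnknownIDError) as exc:
            get_value(worked_table, "row1", "nope")
        assert exc.value.axis == "column"


class TestVectorAccessors:
    def test_worked_example_row_and_column(self, worked_table):
        assert get_row(worked_table, "row2") == [2, 3]
        assert get_column(to_sparse(worked_table), "col1") == [0, 2]

    def test_empty_column_axis_gives_empty_row(self):
        t = build_table({"rows": [{"id": "r"}], "matrix_type": "sparse"})
        assert get_row(t, "r") == []


def test_exhaustive_2x2_binary_agreement():
    """All 16 binary 2x2 grids: dense form, sparse form and the raw grid
    (the oracle) agree for every accessor at every position."""
    for bits in itertools.product([0, 1], repeat=4):
        grid = [[bits[0], bits[1]], [bits[2], bits[3]]]
        t = build_table(
            {
                "matrix_type": "dense",
                "shape": [2, 2],
                "rows": [{"id": "r0"}, {"id": "r1"}],
                "columns": [{"id": "c0"}, {"id": "c1"}],
                "data": grid,
            }
        )
        s = to_sparse(t)
        for i, j in itertools.product(range(2), repeat=2):
            assert get_value(t, f"r{i}", f"c{j}") == grid[i][j]
            assert get_value(s, f"r{i}", f"c{j}") == grid[i][j]
        for i in range(2):
            assert get_row(t, f"r{i}") == get_row(s, f"r{i}") == grid[i]
        for j in range(2):
            expected = [grid[0][j], grid[1][j]]
            assert get_column(t, f"c{j}") == get_column(s, f"c{j}") == expected


@pytest.mark.parametrize("element_type", ["int", "float"])
def test_random_fixture_agreement_with_dense_oracle(element_type):
    for seed in range(3):
        t = generate_fixture(FixtureSpec(7, 9, density=0.4, element_type=element_type, seed=seed))
        d, s = to_dense(t), to_sparse(t)
        grid = d.data  # the oracle: raw row-major rendering
        for i, rid in enumerate(t.row_ids()):
            assert get_row(d, rid) == get_row(s, rid) == grid[i]
            for j, cid in enumerate(t.column_ids()):
                assert get_value(d, rid, cid) == get_value(s, rid, cid) == grid[i][j]
        for j, cid in enumerate(t.column_ids()):
            col = [grid[i][j] for i in range(t.shape[0])]
            assert get_column(d, cid) == get_column(s, cid) == col


class TestNnz:
    def test_worked_example_counts_three(self, worked_table):
        assert nnz(worked_table) == 3
        assert nnz(to_sparse(worked_table)) == 3

    def test_empty_and_all_zero_tables(self):
        assert nnz(build_table({})) == 0
        t = build_table(
            {
                "matrix_type": "dense",
                "shape": [4, 4],
                "rows": [{"id": f"r{i}"} for i in range(4)],
                "columns": [{"id": f"c{i}"} for i in range(4)],
                "data": [[0] * 4 for _ in range(4)],
            }
        )
        assert nnz(t) == 0


class TestMetadata:
    def test_partial_map_update_leaves_others_absent(self, worked_table):
        set_metadata(worked_table, "rows", "taxonomy", {"row1": "g__X"})
        assert get_metadata(worked_table, "rows", "taxonomy") == ["g__X", None]

    def test_sequence_form_overwrites_all(self, worked_table):
        set_metadata(worked_table, "columns", "env", ["soil", "gut"])
        assert get_metadata(worked_table, "columns", "env") == ["soil", "gut"]
        set_metadata(worked_table, "columns", "env", ["soil", None])
        assert get_metadata(worked_table, "columns", "env") == ["soil", None]

    def test_wrong_length_sequence_rejected(self, worked_table):
        with pytest.raises(BiomError):
            set_metadata(worked_table, "rows", "k", ["only one"])

    def test_unknown_id_in_map_rejected(self, worked_table):
        with pytest.raises(BiomUnknownIDError):
            set_metadata(worked_table, "rows", "k", {"rowX": 1})

    def test_bad_axis_rejected(self, worked_table):
        with pytest.raises(BiomError):
            get_metadata(worked_table, "diagonal", "k")

    def test_metadata_round_trips_through_both_file_versions(self, tmp_path, worked_table):
        set_metadata(worked_table, "rows", "taxonomy", {"row1": ["k__Bacteria", "g__X"]})
        set_metadata(worked_table, "columns", "ph", [6.5, 7.0])
        via_v1 = read_v1(write_v1(worked_table))
        assert get_metadata(via_v1, "rows", "taxonomy") == [["k__Bacteria", "g__X"], None]
        assert get_metadata(via_v1, "columns", "ph") == [6.5, 7.0]
        p = tmp_path / "m.biom"
        write_v2(worked_table, p)
        via_v2 = read_v2(p)
        assert get_metadata(via_v2, "rows", "taxonomy") == [["k__Bacteria", "g__X"], None]
        assert get_metadata(via_v2, "columns", "ph") == [6.5, 7.0]
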