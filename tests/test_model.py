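"""Core model: construction with defaulting, guarded mutation, validation."""

import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biomlite import (
    AxisEntry,
    BiomConsistencyError,
    BiomError,
    BiomTable,
    BiomTypeError,
    FixtureSpec,
    build_table,
    generate_fixture,
    set_field,
    validate,
)
from biomlite.model import DEFAULT_FORMAT, DEFAULT_FORMAT_URL, infer_element_type


class TestConstruction:
    def test_empty_field_map_gets_documented_defaults(self):
        t = build_table({})
        assert t.id is None
        assert t.shape == (0, 0)
        assert t.rows == [] and t.columns == []
        assert t.matrix_type == "sparse" and t.data == []
        assert t.matrix_element_type == "float"
        assert t.format == DEFAULT_FORMAT
        assert t.format_url == DEFAULT_FORMAT_URL
        assert t.table_type == "OTU table"
        assert t.comment is None
        # creation_date defaults to a parseable ISO 8601 timestamp
        datetime.datetime.fromisoformat(t.creation_date)
        assert validate(t).is_valid

    def test_worked_example_builds_and_validates(self, worked_table):
        t = worked_table
        assert t.id == "My Biom"
        assert t.shape == (2, 2)
        assert [e.id for e in t.rows] == ["row1", "row2"]
        assert [e.id for e in t.columns] == ["col1", "col2"]
        assert t.matrix_type == "dense"
        assert t.data == [[0, 1], [2, 3]]
        assert t.matrix_element_type == "int"
        report = validate(t)
        assert report.is_valid and not report.issues

    def test_shape_inferred_from_axes(self):
        t = build_table({"rows": [{"id": "a"}, {"id": "b"}], "matrix_type": "sparse"})
        assert t.shape == (2, 0)

    def test_shape_contradiction_rejected(self):
        with pytest.raises(BiomConsistencyError) as exc:
            build_table(
                {"shape": [1, 2], "rows": [{"id": "r"}], "columns": [{"id": "c"}]}
            )
        assert "columns" in str(exc.value)

    @pytest.mark.parametrize(
        "fields, bad_field",
        [
            ({"id": ["not", "text"]}, "id"),
            ({"format": 7}, "format"),
            ({"matrix_type": "diagonal"}, "matrix_type"),
            ({"shape": [1, -1]}, "shape"),
            ({"rows": [{"id": ""}]}, "rows"),
            ({"rows": "row1,row2"}, "rows"),
            ({"comment": 0}, "comment"),
        ],
    )
    def test_type_errors_name_offending_field(self, fields, bad_field):
        with pytest.raises(BiomTypeError) as exc:
            build_table(fields)
        assert exc.value.field == bad_field

    def test_build_idempotent_on_own_output(self, worked_table):
        assert build_table(worked_table.to_field_map()) == worked_table

    def test_build_idempotent_on_random_fixtures(self):
        for seed in range(5):
            t = generate_fixture(FixtureSpec(7, 5, density=0.4, seed=seed))
            assert build_table(t.to_field_map()) == t

    def test_unknown_fields_kept_in_passthrough(self):
        t = build_table({"my_extension": {"a": 1}})
        assert t.passthrough == {"my_extension": {"a": 1}}

    @pytest.mark.parametrize(
        "values, expected",
        [([], "float"), ([1, 2], "int"), ([1, 2.5], "float"), (["a", 1], "unicode")],
    )
    def test_element_type_inference(self, values, expected):
        assert infer_element_type(values) == expected

    def test_dense_default_payload_is_zero_grid(self):
        t = build_table(
            {
                "matrix_type": "dense",
                "rows": [{"id": "r"}],
                "columns": [{"id": "c1"}, {"id": "c2"}],
            }
        )
        assert t.data == [[0.0, 0.0]]
        assert validate(t).is_valid


class TestGuardedSetters:
    def test_id_rejects_sequence(self, worked_table):
        with pytest.raises(BiomTypeError):
            worked_table.id = []
        assert worked_table.id == "My Biom"  # unchanged

    def test_id_accepts_text_and_none(self, worked_table):
        worked_table.id = None
        assert worked_table.id is None
        worked_table.id = "renamed"
        assert worked_table.id == "renamed"

    def test_comment_set_and_read_back(self, worked_table):
        set_field(worked_table, "comment", "hello")
        assert worked_table.comment == "hello"

    def test_unknown_field_rejected(self, worked_table):
        with pytest.raises(BiomError):
            set_field(worked_table, "n_rows", 3)

    def test_inconsistent_rows_rejected_atomically(self, worked_table):
        before = worked_table.to_field_map()
        with pytest.raises(BiomConsistencyError):
            worked_table.rows = [{"id": "only_one"}]
        assert worked_table == build_table(before)

    def test_matrix_type_flip_without_payload_change_rejected(self, worked_table):
        with pytest.raises(BiomConsistencyError):
            worked_table.matrix_type = "sparse"  # payload is still a grid

    def test_shape_set_allowed_only_when_consistent(self, worked_table):
        worked_table.shape = (2, 2)  # no-op, consistent
        with pytest.raises(BiomConsistencyError):
            worked_table.shape = (3, 2)

    def test_element_type_narrowing_rejected_on_mismatch(self, worked_table):
        # data holds ints; unicode would not conform
        with pytest.raises(BiomConsistencyError):
            worked_table.matrix_element_type = "unicode"
        worked_table.matrix_element_type = "float"  # widening is fine
        assert worked_table.matrix_element_type == "float"

    @settings(max_examples=60, deadline=None)
    @given(
        field_value=st.one_of(
            st.tuples(st.just("id"), st.none() | st.text()),
            st.tuples(st.just("comment"), st.none() | st.text()),
            st.tuples(
                st.sampled_from(
                    ["format", "format_url", "table_type", "generated_by", "creation_date"]
                ),
                st.text(),
            ),
        )
    )
    def test_set_then_readback_for_legal_pairs(self, field_value):
        field, value = field_value
        t = build_table({})
        set_field(t, field, value)
        assert getattr(t, field) == value


class TestValidate:
    def test_duplicate_row_id_reported_once_at_rows(self, worked_table):
        worked_table._rows[1].id = "row1"
        report = validate(worked_table)
        assert len(report.errors) == 1
        assert report.errors[0].field_path == "rows"
        assert "duplicate" in report.errors[0].message

    def test_out_of_bounds_triple_reported(self):
        t = build_table(
            {
                "matrix_type": "sparse",
                "shape": [2, 2],
                "rows": [{"id": "r1"}, {"id": "r2"}],
                "columns": [{"id": "c1"}, {"id": "c2"}],
                "data": [[0, 0, 1.0]],
            }
        )
        t._data.append([5, 0, 1.0])
        report = validate(t)
        assert len(report.errors) == 1
        assert "out of bounds" in report.errors[0].message

    def test_duplicate_sparse_position_is_error(self):
        t = build_table({"shape": [1, 1], "rows": [{"id": "r"}], "columns": [{"id": "c"}]})
        t._data = [[0, 0, 1.0], [0, 0, 2.0]]
        report = validate(t)
        assert any("duplicate entry" in e.message for e in report.errors)

    def test_explicit_zero_triple_is_warning_not_error(self):
        t = build_table({"shape": [1, 1], "rows": [{"id": "r"}], "columns": [{"id": "c"}]})
        t._data = [[0, 0, 0.0]]
        report = validate(t)
        assert report.is_valid
        assert any("explicit zero" in w.message for w in report.warnings)

    def test_unknown_table_type_is_warning(self):
        t = build_table({"table_type": "Antibody table"})
        report = validate(t)
        assert report.is_valid
        assert any(w.field_path == "table_type" for w in report.warnings)

    def test_axis_entry_helpers(self):
        e = AxisEntry("r1", {"k": 1})
        assert e.to_dict() == {"id": "r1", "metadata": {"k": 1}}
        assert AxisEntry.coerce({"id": "r1", "metadata": {"k": 1}}) == e
        copy = e.copy()
        copy.metadata["k"] = 2
        assert e.metadata["k"] == 1
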