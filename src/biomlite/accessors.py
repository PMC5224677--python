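"""Representation-agnostic data access and metadata get/set.

Every accessor addresses the matrix by row/column *id* (the stable keys
in BIOM workflows) and returns the same answer whether the table is
held dense or sparse; index-addressed variants are offered alongside.
A position absent from a sparse payload reads as the element type's
zero (0, 0.0 or "") — sparse means "zero omitted", not "missing".
"""

from __future__ import annotations

from typing import Any, Mapping, Sequence

from .model import (
    BiomError,
    BiomTable,
    BiomTypeError,
    zero_of,
)

_AXES = {"rows": "rows", "observation": "rows", "columns": "columns", "sample": "columns"}


def get_value_at(table: BiomTable, row: int, col: int) -> Any:
    """Matrix value at 0-based (row, col) indices."""
    n_rows, n_cols = table.shape
    if not (0 <= row < n_rows and 0 <= col < n_cols):
        raise IndexError(f"position ({row}, {col}) out of bounds for shape {table.shape}")
    if table.matrix_type == "dense":
        return table.data[row][col]
    return table._coo().get((row, col), zero_of(table.matrix_element_type))


def get_value(table: BiomTable, row_id: str, col_id: str) -> Any:
    """Matrix value at (row_id, col_id)."""
    return get_value_at(table, table.row_index(row_id), table.column_index(col_id))


def get_row(table: BiomTable, row_id: str) -> list:
    """One matrix row, as a list of length ``n_cols``."""
    r = table.row_index(row_id)
    if table.matrix_type == "dense":
        return list(table.data[r])
    out = [zero_of(table.matrix_element_type)] * table.shape[1]
    for (tr, tc), v in table._coo().items():
        if tr == r:
            out[tc] = v
    return out


def get_column(table: BiomTable, col_id: str) -> list:
    """One matrix column, as a list of length ``n_rows``."""
    c = table.column_index(col_id)
    if table.matrix_type == "dense":
        return [row[c] for row in table.data]
    out = [zero_of(table.matrix_element_type)] * table.shape[0]
    for (tr, tc), v in table._coo().items():
        if tc == c:
            out[tr] = v
    return out


def nnz(table: BiomTable) -> int:
    """Count of nonzero matrix entries, representation-agnostic.

    Explicit zeros in a non-canonical sparse payload are not counted.
    """
    zero = zero_of(table.matrix_element_type)
    if table.matrix_type == "dense":
        return sum(1 for row in table.data for v in row if v != zero)
    return sum(1 for _, _, v in table.data if v != zero)


def _axis_entries(table: BiomTable, axis: str):
    try:
        name = _AXES[axis]
    except KeyError:
        raise BiomError(f"axis must be 'rows' or 'columns', got {axis!r}") from None
    return name, (table.rows if name == "rows" else table.columns)


def get_metadata(table: BiomTable, axis: str, key: str) -> list:
    """Metadata values for ``key`` along an axis, aligned with axis
    order; ``None`` where an entry lacks the key."""
    _, entries = _axis_entries(table, axis)
    return [
        e.metadata.get(key) if isinstance(e.metadata, dict) else None for e in entries
    ]


def set_metadata(
    table: BiomTable, axis: str, key: str, values: Sequence | Mapping[str, Any]
) -> BiomTable:
    """Set metadata ``key`` along an axis; returns the mutated table.

    ``values`` is either a full sequence aligned with the axis (every
    entry overwritten; ``None`` removes the key) or an id -> value map
    (only the named entries touched).  A sequence of the wrong length
    or an unknown id raises without modifying anything.
    """
    if not isinstance(key, str):
        raise BiomTypeError("metadata", f"key must be text, got {type(key).__name__}")
    name, entries = _axis_entries(table, axis)

    if isinstance(values, Mapping):
        index = table.row_index if name == "rows" else table.column_index
        updates = [(index(entry_id), value) for entry_id, value in values.items()]
    else:
        if not isinstance(values, (list, tuple)):
            raise BiomTypeError(
                "metadata", f"values must be a sequence or mapping, got {type(values).__name__}"
            )
        if len(values) != len(entries):
            raise BiomError(
                f"{name} metadata sequence has length {len(values)}, axis has {len(entries)} entries"
            )
        updates = list(enumerate(values))

    for i, value in updates:
        entry = entries[i]
        if not isinstance(entry.metadata, dict):
            entry.metadata = {}
        if value is None:
            entry.metadata.pop(key, None)
        else:
            entry.metadata[key] = value
    return table
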