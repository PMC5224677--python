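"""Core data model for Biological Observation Matrix (BIOM) tables.

A BIOM table is a (usually sparse) matrix of counts of observations
(OTUs, taxa, genes, ...) per sample, together with per-axis metadata and
a small set of provenance header fields.  This module defines the
in-memory :class:`BiomTable`, construction with defaulting, integrity
validation, and guarded attribute mutation.  Serialization lives in
:mod:`biomlite.io_v1` (JSON, format 1.0) and :mod:`biomlite.io_v2`
(HDF5, format 2.1).

Representation
--------------
The matrix payload is held either *dense* — a row-major grid including
zeros — or *sparse* — a list of ``[row, col, value]`` triples with
0-based indices and zeros omitted.  All accessors (see
:mod:`biomlite.accessors`) are agnostic to which representation is in
use.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

__version__ = "1.0.0"

DEFAULT_FORMAT = "Biological Observation Matrix 1.0.0"
DEFAULT_FORMAT_URL = "http://biom-format.org"
DEFAULT_TABLE_TYPE = "OTU table"
GENERATED_BY = f"biomlite {__version__}"

MATRIX_TYPES = ("dense", "sparse")
ELEMENT_TYPES = ("int", "float", "unicode")

#: Table kinds named by the format specification.  Unknown values are
#: flagged as warnings, not errors (producers drift).
KNOWN_TABLE_TYPES = frozenset(
    {
        "OTU table",
        "Pathway table",
        "Function table",
        "Ortholog table",
        "Gene table",
        "Metabolite table",
        "Taxon table",
    }
)

#: Header fields of a table, in canonical order.
FIELDS = (
    "id",
    "format",
    "format_url",
    "table_type",
    "generated_by",
    "creation_date",
    "matrix_type",
    "matrix_element_type",
    "shape",
    "rows",
    "columns",
    "data",
    "comment",
)


# ---------------------------------------------------------------------------
# Exceptions


class BiomError(Exception):
    """Base class for all errors raised by biomlite."""


class BiomTypeError(BiomError, TypeError):
    """A field was assigned a value of the wrong type.

    ``field`` names the offending header field.
    """

    def __init__(self, field_name: str, message: str):
        super().__init__(f"{field_name}: {message}")
        self.field = field_name


class BiomConsistencyError(BiomError, ValueError):
    """A mutation or construction would leave the table inconsistent."""

    def __init__(self, field_name: str, message: str):
        super().__init__(f"{field_name}: {message}")
        self.field = field_name


class BiomValidationError(BiomError, ValueError):
    """A document failed integrity validation; carries the full report."""

    def __init__(self, report: "ValidationReport", context: str = "document"):
        self.report = report
        lines = "; ".join(str(i) for i in report.errors[:5])
        super().__init__(f"{context} has {len(report.errors)} validation error(s): {lines}")


class BiomFormatError(BiomError, ValueError):
    """A serialized document could not be parsed or is structurally broken."""


class BiomUnknownIDError(BiomError, KeyError):
    """An id was not found on the requested axis."""

    def __init__(self, axis: str, identifier: Any):
        super().__init__(f"unknown {axis} id: {identifier!r}")
        self.axis = axis
        self.identifier = identifier


# ---------------------------------------------------------------------------
# Axis entries and validation report


@dataclass
class AxisEntry:
    """One row (observation) or column (sample): an id plus a metadata map.

    ``metadata`` maps text keys to arbitrary JSON-serializable values;
    ``None`` marks "no metadata recorded".
    """

    id: str
    metadata: dict | None = field(default_factory=dict)

    def copy(self) -> "AxisEntry":
        md = dict(self.metadata) if isinstance(self.metadata, dict) else self.metadata
        return AxisEntry(self.id, md)

    def to_dict(self) -> dict:
        return {"id": self.id, "metadata": self.metadata}

    @classmethod
    def coerce(cls, obj: Any) -> "AxisEntry":
        """Accept an AxisEntry or a ``{"id": ..., "metadata": ...}`` map."""
        if isinstance(obj, AxisEntry):
            return obj.copy()
        if isinstance(obj, Mapping):
            extra = set(obj) - {"id", "metadata"}
            if extra:
                raise BiomTypeError(
                    "rows/columns", f"unexpected axis-entry keys: {sorted(extra)}"
                )
            return cls(obj.get("id"), obj.get("metadata", {}))
        raise BiomTypeError(
            "rows/columns", f"axis entry must be a mapping or AxisEntry, got {type(obj).__name__}"
        )


@dataclass(frozen=True)
class ValidationIssue:
    field_path: str
    severity: str  # "error" | "warning"
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.field_path}: {self.message}"


@dataclass
class ValidationReport:
    """Structured list of specification violations found in a table."""

    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def is_valid(self) -> bool:
        return not self.errors

    def add(self, field_path: str, severity: str, message: str) -> None:
        self.issues.append(ValidationIssue(field_path, severity, message))

    def __str__(self) -> str:
        if not self.issues:
            return "0 errors, 0 warnings"
        head = f"{len(self.errors)} errors, {len(self.warnings)} warnings"
        return "\n".join([head] + [f"  {i}" for i in self.issues])

    def to_dict(self) -> dict:
        return {
            "n_errors": len(self.errors),
            "n_warnings": len(self.warnings),
            "issues": [
                {"field": i.field_path, "severity": i.severity, "message": i.message}
                for i in self.issues
            ],
        }


# ---------------------------------------------------------------------------
# Value-domain helpers


def _is_int(v: Any) -> bool:
    return isinstance(v, int) and not isinstance(v, bool)


def _is_number(v: Any) -> bool:
    return _is_int(v) or isinstance(v, float)


def value_conforms(value: Any, element_type: str) -> bool:
    """Does ``value`` belong to the value domain of ``element_type``?

    An ``int`` literal is acceptable in a float matrix (JSON does not
    distinguish ``0`` from ``0.0``); the reverse is not true.
    """
    if element_type == "int":
        return _is_int(value)
    if element_type == "float":
        return _is_number(value)
    if element_type == "unicode":
        return isinstance(value, str)
    return False


def zero_of(element_type: str) -> Any:
    """The "absent" value of a domain: 0, 0.0, or the empty string."""
    return {"int": 0, "float": 0.0, "unicode": ""}[element_type]


def infer_element_type(values: Iterable[Any]) -> str:
    """Infer int/float/unicode from observed values (empty -> float)."""
    saw_any = saw_float = saw_str = False
    for v in values:
        saw_any = True
        if isinstance(v, str):
            saw_str = True
        elif isinstance(v, float):
            saw_float = True
    if saw_str:
        return "unicode"
    if saw_float or not saw_any:
        return "float"
    return "int"


def _iter_payload_values(matrix_type: Any, data: Any):
    """Yield matrix values from either payload shape; tolerant of junk."""
    if not isinstance(data, list):
        return
    if matrix_type == "dense":
        for row in data:
            if isinstance(row, list):
                yield from row
    else:
        for triple in data:
            if isinstance(triple, (list, tuple)) and len(triple) == 3:
                yield triple[2]


def _now_iso() -> str:
    return datetime.datetime.now().replace(microsecond=0).isoformat()


# ---------------------------------------------------------------------------
# Field type-checkers (shared by the constructor and the guarded setters)


def _check_id(v: Any) -> Any:
    if v is not None and not isinstance(v, str):
        raise BiomTypeError("id", f"must be a string or None, got {type(v).__name__}")
    return v


def _check_text(field_name: str, v: Any) -> str:
    if not isinstance(v, str):
        raise BiomTypeError(field_name, f"must be a string, got {type(v).__name__}")
    return v


def _check_enum(field_name: str, v: Any, allowed: Sequence[str]) -> str:
    if not isinstance(v, str) or v not in allowed:
        raise BiomTypeError(field_name, f"must be one of {list(allowed)}, got {v!r}")
    return v


def _check_shape(v: Any) -> tuple[int, int]:
    ok = (
        isinstance(v, (list, tuple))
        and len(v) == 2
        and all(_is_int(x) and x >= 0 for x in v)
    )
    if not ok:
        raise BiomTypeError("shape", f"must be a pair of non-negative integers, got {v!r}")
    return (v[0], v[1])


def _check_axis(field_name: str, v: Any) -> list[AxisEntry]:
    if not isinstance(v, (list, tuple)):
        raise BiomTypeError(field_name, f"must be a sequence of axis entries, got {type(v).__name__}")
    entries = []
    for i, obj in enumerate(v):
        try:
            entry = AxisEntry.coerce(obj)
        except BiomTypeError as exc:
            raise BiomTypeError(field_name, f"entry {i}: {exc}") from None
        if not isinstance(entry.id, str) or not entry.id:
            raise BiomTypeError(field_name, f"entry {i}: id must be non-empty text, got {entry.id!r}")
        if entry.metadata is not None and not isinstance(entry.metadata, dict):
            raise BiomTypeError(
                field_name, f"entry {i}: metadata must be a mapping or None, got {type(entry.metadata).__name__}"
            )
        entries.append(entry)
    return entries


def _check_data(v: Any) -> list:
    if not isinstance(v, (list, tuple)):
        raise BiomTypeError("data", f"must be a sequence, got {type(v).__name__}")
    return [list(r) if isinstance(r, (list, tuple)) else r for r in v]


def _check_comment(v: Any) -> Any:
    if v is not None and not isinstance(v, str):
        raise BiomTypeError("comment", f"must be a string or None, got {type(v).__name__}")
    return v


_CHECKERS = {
    "id": _check_id,
    "format": lambda v: _check_text("format", v),
    "format_url": lambda v: _check_text("format_url", v),
    "table_type": lambda v: _check_text("table_type", v),
    "generated_by": lambda v: _check_text("generated_by", v),
    "creation_date": lambda v: _check_text("creation_date", v),
    "matrix_type": lambda v: _check_enum("matrix_type", v, MATRIX_TYPES),
    "matrix_element_type": lambda v: _check_enum("matrix_element_type", v, ELEMENT_TYPES),
    "shape": _check_shape,
    "rows": lambda v: _check_axis("rows", v),
    "columns": lambda v: _check_axis("columns", v),
    "data": _check_data,
    "comment": _check_comment,
}


# ---------------------------------------------------------------------------
# The table


class BiomTable:
    """One unified in-memory BIOM table, dense or sparse.

    Construct from a (possibly partial) field map; absent fields receive
    the documented defaults and the result always passes :func:`validate`
    with zero errors.  All attribute assignment is guarded: a value of
    the wrong type raises :class:`BiomTypeError`, and a structural change
    that would leave the table inconsistent (e.g. rows disagreeing with
    ``shape``) is rejected atomically with :class:`BiomConsistencyError`.

    Unknown top-level keys in the field map are preserved in
    ``passthrough`` and re-emitted by the writers.

    >>> t = BiomTable({"id": "My Biom", "matrix_type": "dense",
    ...                "shape": [2, 2],
    ...                "rows": [{"id": "row1", "metadata": {}},
    ...                         {"id": "row2", "metadata": {}}],
    ...                "columns": [{"id": "col1", "metadata": {}},
    ...                            {"id": "col2", "metadata": {}}],
    ...                "data": [[0, 1], [2, 3]]})
    >>> t.shape
    (2, 2)
    """

    __slots__ = (
        "_id",
        "_format",
        "_format_url",
        "_table_type",
        "_generated_by",
        "_creation_date",
        "_matrix_type",
        "_matrix_element_type",
        "_shape",
        "_rows",
        "_columns",
        "_data",
        "_comment",
        "passthrough",
        "_row_map",
        "_col_map",
        "_coo_map",
    )

    def __init__(self, fields: Mapping[str, Any] | None = None, **kwargs: Any):
        supplied: dict[str, Any] = dict(fields or {})
        supplied.update(kwargs)
        self._init_from_fields(supplied, strict=True)

    # -- construction -------------------------------------------------

    def _init_from_fields(self, supplied: dict[str, Any], *, strict: bool) -> None:
        self.passthrough = {k: v for k, v in supplied.items() if k not in FIELDS}
        self._row_map = self._col_map = self._coo_map = None

        checked: dict[str, Any] = {}
        for name in FIELDS:
            if name not in supplied:
                continue
            try:
                checked[name] = _CHECKERS[name](supplied[name])
            except BiomTypeError:
                if strict:
                    raise
                checked[name] = supplied[name]  # keep as-is; validate() will flag it

        rows = checked.get("rows", [])
        columns = checked.get("columns", [])
        if "shape" in checked:
            shape = checked["shape"]
        else:
            n_r = len(rows) if isinstance(rows, list) else 0
            n_c = len(columns) if isinstance(columns, list) else 0
            shape = (n_r, n_c)
        matrix_type = checked.get("matrix_type", "sparse")
        if "data" in checked:
            data = checked["data"]
        elif matrix_type == "dense":
            # a zero-filled grid keeps a dense default table consistent
            et = checked.get("matrix_element_type", "float")
            z = zero_of(et) if et in ELEMENT_TYPES else 0.0
            n_r, n_c = (shape if isinstance(shape, tuple) else (0, 0))
            data = [[z] * n_c for _ in range(n_r)]
        else:
            data = []
        element_type = checked.get(
            "matrix_element_type",
            infer_element_type(_iter_payload_values(matrix_type, data)),
        )

        self._id = checked.get("id")
        self._format = checked.get("format", DEFAULT_FORMAT)
        self._format_url = checked.get("format_url", DEFAULT_FORMAT_URL)
        self._table_type = checked.get("table_type", DEFAULT_TABLE_TYPE)
        self._generated_by = checked.get("generated_by", GENERATED_BY)
        self._creation_date = checked.get("creation_date", _now_iso())
        self._matrix_type = matrix_type
        self._matrix_element_type = element_type
        self._shape = shape
        self._rows = rows
        self._columns = columns
        self._data = data
        self._comment = checked.get("comment")

        if strict:
            report = validate(self)
            if not report.is_valid:
                first = report.errors[0]
                raise BiomConsistencyError(first.field_path, first.message)

    @classmethod
    def _from_fields_unchecked(cls, supplied: Mapping[str, Any]) -> "BiomTable":
        """Build without raising; callers run :func:`validate` themselves."""
        obj = object.__new__(cls)
        obj._init_from_fields(dict(supplied), strict=False)
        return obj

    # -- guarded attribute access -------------------------------------

    def _set_structural(self, attr: str, value: Any) -> None:
        """Commit a structural field only if the table stays consistent."""
        old = getattr(self, attr)
        setattr(self, attr, value)
        self._invalidate_caches()
        report = validate(self)
        if not report.is_valid:
            setattr(self, attr, old)
            self._invalidate_caches()
            first = report.errors[0]
            raise BiomConsistencyError(first.field_path, first.message)

    def _invalidate_caches(self) -> None:
        self._row_map = self._col_map = self._coo_map = None

    @property
    def id(self):
        return self._id

    @id.setter
    def id(self, v):
        self._id = _check_id(v)

    @property
    def format(self):
        return self._format

    @format.setter
    def format(self, v):
        self._format = _check_text("format", v)

    @property
    def format_url(self):
        return self._format_url

    @format_url.setter
    def format_url(self, v):
        self._format_url = _check_text("format_url", v)

    @property
    def table_type(self):
        return self._table_type

    @table_type.setter
    def table_type(self, v):
        self._table_type = _check_text("table_type", v)

    @property
    def generated_by(self):
        return self._generated_by

    @generated_by.setter
    def generated_by(self, v):
        self._generated_by = _check_text("generated_by", v)

    @property
    def creation_date(self):
        return self._creation_date

    @creation_date.setter
    def creation_date(self, v):
        self._creation_date = _check_text("creation_date", v)

    @property
    def matrix_type(self):
        return self._matrix_type

    @matrix_type.setter
    def matrix_type(self, v):
        self._set_structural("_matrix_type", _check_enum("matrix_type", v, MATRIX_TYPES))

    @property
    def matrix_element_type(self):
        return self._matrix_element_type

    @matrix_element_type.setter
    def matrix_element_type(self, v):
        self._set_structural(
            "_matrix_element_type", _check_enum("matrix_element_type", v, ELEMENT_TYPES)
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self._shape

    @shape.setter
    def shape(self, v):
        # permitted only when already consistent with rows/columns/data
        self._set_structural("_shape", _check_shape(v))

    @property
    def rows(self) -> list[AxisEntry]:
        return self._rows

    @rows.setter
    def rows(self, v):
        self._set_structural("_rows", _check_axis("rows", v))

    @property
    def columns(self) -> list[AxisEntry]:
        return self._columns

    @columns.setter
    def columns(self, v):
        self._set_structural("_columns", _check_axis("columns", v))

    @property
    def data(self):
        return self._data

    @data.setter
    def data(self, v):
        self._set_structural("_data", _check_data(v))

    @property
    def comment(self):
        return self._comment

    @comment.setter
    def comment(self, v):
        self._comment = _check_comment(v)

    # -- id -> index lookup (cached; invalidated on axis mutation) -----

    def row_index(self, row_id: str) -> int:
        if self._row_map is None:
            self._row_map = {e.id: i for i, e in enumerate(self._rows)}
        try:
            return self._row_map[row_id]
        except KeyError:
            raise BiomUnknownIDError("row", row_id) from None

    def column_index(self, col_id: str) -> int:
        if self._col_map is None:
            self._col_map = {e.id: i for i, e in enumerate(self._columns)}
        try:
            return self._col_map[col_id]
        except KeyError:
            raise BiomUnknownIDError("column", col_id) from None

    def row_ids(self) -> list[str]:
        return [e.id for e in self._rows]

    def column_ids(self) -> list[str]:
        return [e.id for e in self._columns]

    def _coo(self) -> dict[tuple[int, int], Any]:
        """(row, col) -> value map for the sparse payload (cached)."""
        if self._coo_map is None:
            self._coo_map = {(r, c): v for r, c, v in self._data}
        return self._coo_map

    # -- misc ----------------------------------------------------------

    def to_field_map(self) -> dict[str, Any]:
        """Field map that reconstructs this table via the constructor.

        Rows, columns, and the data payload are copied, so mutating the
        result does not touch the table.
        """
        out: dict[str, Any] = {
            "id": self._id,
            "format": self._format,
            "format_url": self._format_url,
            "table_type": self._table_type,
            "generated_by": self._generated_by,
            "creation_date": self._creation_date,
            "matrix_type": self._matrix_type,
            "matrix_element_type": self._matrix_element_type,
            "shape": list(self._shape),
            "rows": [e.copy() for e in self._rows],
            "columns": [e.copy() for e in self._columns],
            "data": [list(r) for r in self._data],
            "comment": self._comment,
        }
        out.update(self.passthrough)
        return out

    def __eq__(self, other: Any) -> bool:
        if not isinstance(other, BiomTable):
            return NotImplemented
        return all(
            getattr(self, "_" + f) == getattr(other, "_" + f) for f in FIELDS
        ) and self.passthrough == other.passthrough

    def __repr__(self) -> str:
        return (
            f"<BiomTable {self._id!r} {self._shape[0]}x{self._shape[1]} "
            f"{self._matrix_type} {self._matrix_element_type}>"
        )


# ---------------------------------------------------------------------------
# Module-level operations


def build_table(fields: Mapping[str, Any] | None = None) -> BiomTable:
    """Build a fully-populated, validated table from a partial field map.

    Idempotent on its own output: ``build_table(t.to_field_map()) == t``.
    """
    return BiomTable(fields or {})


def set_field(table: BiomTable, field_name: str, value: Any) -> BiomTable:
    """Set one header field with full type/consistency guarding.

    Returns the (mutated) table.  Raises :class:`BiomTypeError` for a
    value of the wrong type, :class:`BiomConsistencyError` for a
    structurally inconsistent one, and :class:`BiomError` for an unknown
    field name.
    """
    if field_name not in FIELDS:
        raise BiomError(f"unknown field: {field_name!r} (expected one of {list(FIELDS)})")
    setattr(table, field_name, value)
    return table


def validate(table: BiomTable) -> ValidationReport:
    """Check every table invariant; violations are reported, not raised.

    The report is empty exactly when the table conforms to the format
    specification.  Works on arbitrarily corrupted tables (every check
    is defensive), so broken documents loaded in lenient mode can be
    diagnosed.
    """
    rep = ValidationReport()

    if table._id is not None and not isinstance(table._id, str):
        rep.add("id", "error", f"must be a string or None, got {type(table._id).__name__}")
    for name in ("format", "format_url", "generated_by", "creation_date"):
        v = getattr(table, "_" + name)
        if not isinstance(v, str):
            rep.add(name, "error", f"must be a string, got {type(v).__name__}")
    if not isinstance(table._table_type, str):
        rep.add("table_type", "error", f"must be a string, got {type(table._table_type).__name__}")
    elif table._table_type not in KNOWN_TABLE_TYPES:
        rep.add("table_type", "warning", f"unknown table type {table._table_type!r}")
    if table._comment is not None and not isinstance(table._comment, str):
        rep.add("comment", "error", "must be a string or None")

    if table._matrix_type not in MATRIX_TYPES:
        rep.add("matrix_type", "error", f"must be one of {list(MATRIX_TYPES)}, got {table._matrix_type!r}")
        return rep
    et = table._matrix_element_type
    if et not in ELEMENT_TYPES:
        rep.add(
            "matrix_element_type", "error", f"must be one of {list(ELEMENT_TYPES)}, got {et!r}"
        )
        return rep

    shape_ok = (
        isinstance(table._shape, (list, tuple))
        and len(table._shape) == 2
        and all(_is_int(x) and x >= 0 for x in table._shape)
    )
    if not shape_ok:
        rep.add("shape", "error", f"must be a pair of non-negative integers, got {table._shape!r}")
        return rep
    n_rows, n_cols = table._shape

    for axis, n_expect in (("rows", n_rows), ("columns", n_cols)):
        entries = getattr(table, "_" + axis)
        if not isinstance(entries, list):
            rep.add(axis, "error", f"must be a sequence, got {type(entries).__name__}")
            continue
        seen: dict[Any, int] = {}
        for i, e in enumerate(entries):
            eid = e.id if isinstance(e, AxisEntry) else None
            if isinstance(e, AxisEntry) and not isinstance(e.metadata, (dict, type(None))):
                rep.add(f"{axis}[{i}].metadata", "error", "must be a mapping or None")
            if not isinstance(eid, str) or not eid:
                rep.add(f"{axis}[{i}].id", "error", f"id must be non-empty text, got {eid!r}")
                continue
            if eid in seen:
                rep.add(axis, "error", f"duplicate id {eid!r} at positions {seen[eid]} and {i}")
            else:
                seen[eid] = i
        if len(entries) != n_expect:
            rep.add(axis, "error", f"length {len(entries)} does not match shape ({n_expect})")

    data = table._data
    if not isinstance(data, list):
        rep.add("data", "error", f"must be a sequence, got {type(data).__name__}")
        return rep

    if table._matrix_type == "dense":
        if len(data) != n_rows:
            rep.add("data", "error", f"dense payload has {len(data)} rows, shape says {n_rows}")
        for i, row in enumerate(data):
            if not isinstance(row, list):
                rep.add(f"data[{i}]", "error", "dense row must be a sequence")
                continue
            if len(row) != n_cols:
                rep.add(f"data[{i}]", "error", f"dense row has {len(row)} entries, shape says {n_cols}")
            for j, v in enumerate(row):
                if not value_conforms(v, et):
                    rep.add(f"data[{i}][{j}]", "error", f"value {v!r} does not conform to element type {et!r}")
    else:
        seen_rc: set[tuple[Any, Any]] = set()
        for k, triple in enumerate(data):
            if not isinstance(triple, (list, tuple)) or len(triple) != 3:
                rep.add(f"data[{k}]", "error", "sparse entry must be a [row, col, value] triple")
                continue
            r, c, v = triple
            if not (_is_int(r) and 0 <= r < n_rows) or not (_is_int(c) and 0 <= c < n_cols):
                rep.add(
                    f"data[{k}]",
                    "error",
                    f"index ({r!r}, {c!r}) out of bounds for shape ({n_rows}, {n_cols})",
                )
                continue
            if (r, c) in seen_rc:
                rep.add(f"data[{k}]", "error", f"duplicate entry for position ({r}, {c})")
            seen_rc.add((r, c))
            if not value_conforms(v, et):
                rep.add(f"data[{k}]", "error", f"value {v!r} does not conform to element type {et!r}")
            elif v == zero_of(et):
                rep.add(f"data[{k}]", "warning", f"explicit zero stored at ({r}, {c})")

    return rep
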