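"""BIOM format 1.0 (JSON text) reading and writing.

The 1.0 document is a single JSON object.  Its ``data`` block is either
a row-major dense grid or a list of ``[row, col, value]`` triples,
selected by ``matrix_type``.  On disk the header uses the format's own
key names ``type`` and ``date``; in memory these are ``table_type`` and
``creation_date``.  Unknown top-level keys survive a round trip through
the table's ``passthrough`` map.
"""

from __future__ import annotations

import json
from typing import Any

from .model import (
    BiomFormatError,
    BiomTable,
    BiomValidationError,
    ValidationReport,
    validate,
    zero_of,
)

# on-disk key -> in-memory field
_KEY_TO_FIELD = {
    "id": "id",
    "format": "format",
    "format_url": "format_url",
    "type": "table_type",
    "generated_by": "generated_by",
    "date": "creation_date",
    "matrix_type": "matrix_type",
    "matrix_element_type": "matrix_element_type",
    "shape": "shape",
    "rows": "rows",
    "columns": "columns",
    "data": "data",
    "comment": "comment",
}


def read_v1(text: str | bytes, *, lenient: bool = False):
    """Parse a BIOM 1.0 JSON document into a :class:`BiomTable`.

    The document's ``matrix_type`` is preserved as the in-memory
    representation.  By default a document that violates the format
    specification is rejected with :class:`BiomValidationError`; with
    ``lenient=True`` the function loads what it can and returns a
    ``(table, report)`` pair instead.

    Raises
    ------
    BiomFormatError
        For empty or malformed (non-JSON, non-object) input.
    """
    if isinstance(text, bytes):
        try:
            text = text.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise BiomFormatError(f"document is not valid UTF-8: {exc}") from None
    if not text or not text.strip():
        raise BiomFormatError("empty document")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise BiomFormatError(f"malformed JSON: {exc}") from None
    if not isinstance(doc, dict):
        raise BiomFormatError(f"top level must be a JSON object, got {type(doc).__name__}")

    fields: dict[str, Any] = {}
    for key, value in doc.items():
        fields[_KEY_TO_FIELD.get(key, key)] = value

    table = BiomTable._from_fields_unchecked(fields)
    report = validate(table)
    if lenient:
        return table, report
    if not report.is_valid:
        raise BiomValidationError(report)
    return table


def write_v1(table: BiomTable, *, indent: int | None = None) -> str:
    """Serialize a validated table as a BIOM 1.0 JSON document.

    The data dialect follows ``table.matrix_type``; sparse output is
    canonical — triples sorted by (row, col) with explicit zeros
    dropped.  Tables with validation errors are refused.
    """
    report = validate(table)
    if not report.is_valid:
        raise BiomValidationError(report, context="table")

    doc: dict[str, Any] = {
        "id": table.id,
        "format": table.format,
        "format_url": table.format_url,
        "type": table.table_type,
        "generated_by": table.generated_by,
        "date": table.creation_date,
        "matrix_type": table.matrix_type,
        "matrix_element_type": table.matrix_element_type,
        "shape": list(table.shape),
        "rows": [e.to_dict() for e in table.rows],
        "columns": [e.to_dict() for e in table.columns],
        "data": _encode_data(table),
    }
    if table.comment is not None:
        doc["comment"] = table.comment
    for key, value in table.passthrough.items():
        doc.setdefault(key, value)
    return json.dumps(doc, ensure_ascii=False, separators=(",", ": "), indent=indent)


def _encode_data(table: BiomTable) -> list:
    et = table.matrix_element_type
    if table.matrix_type == "dense":
        if et == "int":
            return [[int(v) for v in row] for row in table.data]
        return [list(row) for row in table.data]
    zero = zero_of(et)
    triples = sorted((r, c, v) for r, c, v in table.data if v != zero)
    if et == "int":
        return [[r, c, int(v)] for r, c, v in triples]
    return [[r, c, v] for r, c, v in triples]


def read_v1_file(path, *, lenient: bool = False):
    """:func:`read_v1` on the contents of ``path`` (UTF-8)."""
    with open(path, "rb") as fh:
        return read_v1(fh.read(), lenient=lenient)


def write_v1_file(table: BiomTable, path, *, indent: int | None = None) -> None:
    """Write :func:`write_v1` output to ``path`` (UTF-8)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_v1(table, indent=indent))
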