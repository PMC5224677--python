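"""BIOM format 2.1 (HDF5) reading and writing, plus version sniffing.

The 2.1 container stores the matrix twice: compressed sparse row
(CSR) under ``observation/matrix`` and compressed sparse column
(CSC, i.e. CSR of the transpose) under ``sample/matrix``, each as the
classic ``data`` / ``indices`` / ``indptr`` dataset trio.  Axis ids are
variable-length text datasets; per-axis metadata is one dataset per
metadata key holding a JSON-encoded value per entry (JSON ``null``
marks "key absent for this entry").  Table-level header fields live in
root attributes.  Zeros are never stored.

Numeric matrices go through :mod:`scipy.sparse`; unicode-element
matrices (which scipy cannot hold) use a small pure-Python CSR builder.
"""

from __future__ import annotations

import json
from typing import Any

import h5py
import numpy as np
from scipy import sparse as sp

from .model import (
    AxisEntry,
    BiomFormatError,
    BiomTable,
    BiomValidationError,
    validate,
    zero_of,
)

HDF5_MAGIC = b"\x89HDF\r\n\x1a\n"

_REQUIRED_ATTRS = (
    "id",
    "type",
    "format-url",
    "format-version",
    "generated-by",
    "creation-date",
    "shape",
    "nnz",
)


def sniff_version(prefix: bytes | str) -> str:
    """Classify a file prefix as ``"v1"``, ``"v2"``, or ``"unknown"``.

    A 2.1 file starts with the fixed HDF5 signature; a 1.0 file is JSON
    text whose first non-whitespace character opens an object.
    """
    if isinstance(prefix, str):
        prefix = prefix.encode("utf-8", errors="replace")
    if prefix.startswith(HDF5_MAGIC):
        return "v2"
    stripped = prefix.decode("utf-8", errors="replace").lstrip()
    if stripped.startswith("{"):
        return "v1"
    return "unknown"


# ---------------------------------------------------------------------------
# Writing


def write_v2(
    table: BiomTable,
    path,
    *,
    compression: str | None = "gzip",
    compression_opts: int | None = None,
) -> None:
    """Write a validated table as a BIOM 2.1 HDF5 container.

    Both the observation-oriented (CSR) and sample-oriented (CSC)
    encodings are emitted; matrix datasets are gzip-compressed by
    default.  Tables with validation errors are refused.
    """
    report = validate(table)
    if not report.is_valid:
        raise BiomValidationError(report, context="table")

    n_rows, n_cols = table.shape
    et = table.matrix_element_type
    triples = _nonzero_triples(table)
    count = len(triples)

    try:
        f = h5py.File(path, "w")
    except OSError as exc:
        raise BiomFormatError(f"cannot create {path}: {exc}") from None
    with f:
        f.attrs["id"] = table.id if table.id is not None else ""
        f.attrs["type"] = table.table_type
        f.attrs["format-url"] = table.format_url
        f.attrs["format-version"] = np.array([2, 1], dtype=np.int64)
        f.attrs["generated-by"] = table.generated_by
        f.attrs["creation-date"] = table.creation_date
        f.attrs["shape"] = np.array([n_rows, n_cols], dtype=np.int64)
        f.attrs["nnz"] = np.int64(count)
        # provenance fields beyond the 2.1 attribute set, kept for fidelity
        f.attrs["format"] = table.format
        if table.comment is not None:
            f.attrs["comment"] = table.comment
        if table.passthrough:
            f.attrs["passthrough"] = json.dumps(table.passthrough, ensure_ascii=False)

        row_csr = _csr_arrays(triples, n_rows, et, transpose=False)
        col_csr = _csr_arrays(triples, n_cols, et, transpose=True)
        for group_name, entries, (data, indices, indptr) in (
            ("observation", table.rows, row_csr),
            ("sample", table.columns, col_csr),
        ):
            g = f.create_group(group_name)
            _write_text_dataset(g, "ids", [e.id for e in entries], compression, compression_opts)
            mg = g.create_group("matrix")
            kw = _compress_kw(compression, compression_opts, count)
            if et == "unicode":
                mg.create_dataset("data", data=data, dtype=h5py.string_dtype(), **kw)
            else:
                mg.create_dataset("data", data=data, **kw)
            mg.create_dataset("indices", data=indices, **kw)
            mg.create_dataset(
                "indptr", data=indptr, **_compress_kw(compression, compression_opts, len(indptr))
            )
            _write_metadata_group(g, entries, compression, compression_opts)


def _nonzero_triples(table: BiomTable) -> list[tuple[int, int, Any]]:
    zero = zero_of(table.matrix_element_type)
    if table.matrix_type == "dense":
        return [
            (r, c, v)
            for r, row in enumerate(table.data)
            for c, v in enumerate(row)
            if v != zero
        ]
    return sorted((r, c, v) for r, c, v in table.data if v != zero)


def _csr_arrays(triples, n_major: int, et: str, *, transpose: bool):
    """(data, indices, indptr) of the CSR encoding along rows or columns."""
    if transpose:
        ordered = sorted((c, r, v) for r, c, v in triples)
    else:
        ordered = sorted(triples)
    if et == "unicode":
        data: Any = [v for _, _, v in ordered]
        indices = np.array([minor for _, minor, _ in ordered], dtype=np.int64)
        indptr = np.zeros(n_major + 1, dtype=np.int64)
        for major, _, _ in ordered:
            indptr[major + 1] += 1
        np.cumsum(indptr, out=indptr)
        return data, indices, indptr
    dtype = np.int64 if et == "int" else np.float64
    if not triples:
        mat = sp.csr_matrix((n_major, 0), dtype=dtype)
        return mat.data, mat.indices.astype(np.int64), mat.indptr.astype(np.int64)
    major = np.array([t[0] for t in ordered])
    minor = np.array([t[1] for t in ordered])
    vals = np.array([t[2] for t in ordered], dtype=dtype)
    n_minor = int(minor.max()) + 1 if len(minor) else 0
    mat = sp.csr_matrix((vals, (major, minor)), shape=(n_major, n_minor))
    return mat.data, mat.indices.astype(np.int64), mat.indptr.astype(np.int64)


def _compress_kw(compression, compression_opts, n: int) -> dict:
    # gzip requires chunked storage, which zero-length datasets cannot have
    if compression is None or n == 0:
        return {}
    kw: dict[str, Any] = {"compression": compression}
    if compression_opts is not None:
        kw["compression_opts"] = compression_opts
    return kw


def _write_text_dataset(group, name, values, compression, compression_opts) -> None:
    kw = _compress_kw(compression, compression_opts, len(values))
    group.create_dataset(name, data=values, dtype=h5py.string_dtype(), **kw)


def _write_metadata_group(group, entries, compression, compression_opts) -> None:
    mdg = group.create_group("metadata")
    keys = sorted({k for e in entries if isinstance(e.metadata, dict) for k in e.metadata})
    for key in keys:
        values = [
            json.dumps(e.metadata[key], ensure_ascii=False)
            if isinstance(e.metadata, dict) and key in e.metadata
            else "null"
            for e in entries
        ]
        _write_text_dataset(mdg, key, values, compression, compression_opts)


# ---------------------------------------------------------------------------
# Reading


def read_v2(path) -> BiomTable:
    """Read a BIOM 2.1 HDF5 container into a sparse :class:`BiomTable`.

    The observation (CSR) and sample (CSC) encodings are both decoded
    and cross-checked; a malformed container raises
    :class:`BiomFormatError` naming the missing or inconsistent piece.
    """
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise BiomFormatError(f"cannot open {path} as HDF5: {exc}") from None
    with f:
        for attr in _REQUIRED_ATTRS:
            if attr not in f.attrs:
                raise BiomFormatError(f"missing required root attribute {attr!r}")
        shape = [int(x) for x in f.attrs["shape"]]
        count = int(f.attrs["nnz"])

        row_triples, row_ids, row_md = _read_axis(f, "observation", transpose=False)
        col_triples, col_ids, col_md = _read_axis(f, "sample", transpose=True)
        for group_name, tri in (("observation", row_triples), ("sample", col_triples)):
            if len(tri) != count:
                raise BiomFormatError(
                    f"nnz attribute ({count}) disagrees with {group_name}/matrix/data ({len(tri)})"
                )
        row_map = {(r, c): v for r, c, v in row_triples}
        col_map = {(r, c): v for r, c, v in col_triples}
        if row_map != col_map:
            raise BiomFormatError(
                "observation (CSR) and sample (CSC) matrix encodings disagree"
            )

        raw_id = _decode(f.attrs["id"])
        fields: dict[str, Any] = {
            "id": raw_id if raw_id != "" else None,
            "table_type": _decode(f.attrs["type"]),
            "format_url": _decode(f.attrs["format-url"]),
            "generated_by": _decode(f.attrs["generated-by"]),
            "creation_date": _decode(f.attrs["creation-date"]),
            "matrix_type": "sparse",
            "shape": shape,
            "rows": _axis_entries(row_ids, row_md),
            "columns": _axis_entries(col_ids, col_md),
            "data": [[r, c, v] for (r, c), v in sorted(row_map.items())],
        }
        if "format" in f.attrs:
            fields["format"] = _decode(f.attrs["format"])
        if "comment" in f.attrs:
            fields["comment"] = _decode(f.attrs["comment"])
        if "passthrough" in f.attrs:
            try:
                extra = json.loads(_decode(f.attrs["passthrough"]))
            except (json.JSONDecodeError, TypeError):
                extra = {}
            if isinstance(extra, dict):
                for k, v in extra.items():
                    fields.setdefault(k, v)

    table = BiomTable._from_fields_unchecked(fields)
    report = validate(table)
    if not report.is_valid:
        raise BiomValidationError(report, context=str(path))
    return table


def _read_axis(f, group_name: str, *, transpose: bool):
    if group_name not in f:
        raise BiomFormatError(f"missing required group {group_name!r}")
    g = f[group_name]
    for name in ("ids", "matrix"):
        if name not in g:
            raise BiomFormatError(f"missing required dataset/group {group_name}/{name}")
    mg = g["matrix"]
    for name in ("data", "indices", "indptr"):
        if name not in mg:
            raise BiomFormatError(f"missing required dataset {group_name}/matrix/{name}")

    ids = [_decode(x) for x in g["ids"][()]]
    raw = mg["data"][()]
    indices = [int(x) for x in mg["indices"][()]]
    indptr = [int(x) for x in mg["indptr"][()]]
    if len(indptr) != len(ids) + 1:
        raise BiomFormatError(
            f"{group_name}/matrix/indptr has length {len(indptr)}, expected {len(ids) + 1}"
        )
    values = _decode_values(raw)

    triples: list[tuple[int, int, Any]] = []
    for major in range(len(ids)):
        for k in range(indptr[major], indptr[major + 1]):
            minor = indices[k]
            r, c = (minor, major) if transpose else (major, minor)
            triples.append((r, c, values[k]))

    metadata: dict[str, list] = {}
    if "metadata" in g:
        for key, ds in g["metadata"].items():
            decoded = []
            for item in ds[()]:
                try:
                    decoded.append(json.loads(_decode(item)))
                except (json.JSONDecodeError, TypeError):
                    decoded.append(_decode(item))  # tolerate plain-text producers
            metadata[key] = decoded
    return triples, ids, metadata


def _axis_entries(ids: list[str], metadata: dict[str, list]) -> list[AxisEntry]:
    entries = [AxisEntry(i, {}) for i in ids]
    for key, values in metadata.items():
        for entry, value in zip(entries, values):
            if value is not None:
                entry.metadata[key] = value
    return entries


def _decode(x) -> Any:
    if isinstance(x, bytes):
        return x.decode("utf-8")
    return x


def _decode_values(raw) -> list:
    arr = np.asarray(raw)
    if arr.dtype.kind in "iu":
        return [int(v) for v in arr]
    if arr.dtype.kind == "f":
        return [float(v) for v in arr]
    return [_decode(v) for v in arr.tolist()]
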