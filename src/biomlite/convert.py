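"""Dense <-> sparse representation conversion and the unified read/write
entry points.

``to_dense``/``to_sparse`` are pure: they return a new table and leave
the input untouched.  Conversion preserves shape, the multiset of
nonzero values, and the element type (an int table densifies with
integer zeros, a float table with ``0.0``, a unicode table with the
empty string).  ``read``/``write`` dispatch on format version — sniffed
from content for reading, explicit for writing.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as sp

from .io_v1 import read_v1, write_v1_file
from .io_v2 import read_v2, sniff_version, write_v2
from .model import BiomFormatError, BiomTable, zero_of

_V1_NAMES = {"v1", "1", "1.0", "json"}
_V2_NAMES = {"v2", "2", "2.1", "hdf5"}


def to_dense(table: BiomTable) -> BiomTable:
    """Return a dense copy: a full grid with explicit zeros.

    Idempotent; every non-payload field is unchanged.
    """
    fields = table.to_field_map()
    fields["matrix_type"] = "dense"
    fields["data"] = dense_grid(table)
    return BiomTable(fields)


def to_sparse(table: BiomTable) -> BiomTable:
    """Return a sparse copy: canonical triples, sorted by (row, col).

    Zeros (explicit or implicit) are dropped, so
    ``to_dense(to_sparse(t))`` renders the same grid as ``t``.
    """
    zero = zero_of(table.matrix_element_type)
    if table.matrix_type == "sparse":
        triples = sorted((r, c, v) for r, c, v in table.data if v != zero)
    else:
        triples = [
            (r, c, v)
            for r, row in enumerate(table.data)
            for c, v in enumerate(row)
            if v != zero
        ]
    fields = table.to_field_map()
    fields["matrix_type"] = "sparse"
    fields["data"] = [[r, c, v] for r, c, v in triples]
    return BiomTable(fields)


def dense_grid(table: BiomTable) -> list[list]:
    """The dense row-major rendering of the payload, as nested lists."""
    n_rows, n_cols = table.shape
    et = table.matrix_element_type
    if table.matrix_type == "dense":
        return [list(row) for row in table.data]
    if et == "unicode":
        grid = [[""] * n_cols for _ in range(n_rows)]
        for r, c, v in table.data:
            grid[r][c] = v
        return grid
    dtype = np.int64 if et == "int" else np.float64
    if table.data:
        rows, cols, vals = zip(*table.data)
        mat = sp.coo_matrix(
            (np.array(vals, dtype=dtype), (rows, cols)), shape=(n_rows, n_cols)
        )
        arr = mat.toarray()
    else:
        arr = np.zeros((n_rows, n_cols), dtype=dtype)
    if et == "int":
        return [[int(v) for v in row] for row in arr]
    return [[float(v) for v in row] for row in arr]


def write(table: BiomTable, version: str, destination) -> None:
    """Export ``table`` to ``destination`` as format 1.0 or 2.1.

    ``version`` accepts ``"1.0"``/``"v1"`` or ``"2.1"``/``"v2"``.  The
    input table is not modified; a sparse table written as 1.0 keeps the
    sparse dialect, and any table written as 2.1 is stored sparsely.
    """
    name = str(version).lower()
    if name in _V1_NAMES:
        write_v1_file(table, destination)
    elif name in _V2_NAMES:
        write_v2(table, destination)
    else:
        raise ValueError(f"unknown target version {version!r} (use '1.0' or '2.1')")


def read(path, *, lenient: bool = False):
    """Read a BIOM file of either version, sniffing the version from
    content (the ``.biom`` extension is ambiguous by convention)."""
    try:
        with open(path, "rb") as fh:
            prefix = fh.read(1024)
    except OSError as exc:
        raise BiomFormatError(f"cannot read {path}: {exc}") from None
    version = sniff_version(prefix)
    if version == "v2":
        return read_v2(path)
    if version == "v1":
        with open(path, "rb") as fh:
            return read_v1(fh.read(), lenient=lenient)
    raise BiomFormatError(f"{path}: neither a BIOM 1.0 (JSON) nor 2.1 (HDF5) file")
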