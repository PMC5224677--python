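# biomlite

Read, validate, modify and write **Biological Observation Matrix (BIOM)**
tables — format version **1.0** (JSON text) and **2.1** (HDF5) — behind one
in-memory table object whose accessors do not care whether the matrix is
stored dense or sparse.

## The problem

Marker-gene and metagenomic community studies produce a central contingency
matrix: counts of each *observation* (OTU, taxon, gene) in each *sample*,
plus per-observation metadata (e.g. taxonomy) and per-sample metadata
(e.g. environment). The BIOM format standardizes this bundle, and most
ecology/metagenomics tools (QIIME, MG-RAST, phyloseq, Phinch, ...) exchange
data through it. Working with BIOM is still fiddly in practice:

* two on-disk versions exist — 1.0 is a JSON document, 2.1 an HDF5
  container — and tools emit either;
* the matrix payload may be **dense** (a full row-major grid) or **sparse**
  (only the nonzero `[row, col, value]` triples, 0-based);
* a document that drifts from the specification silently breaks
  interoperability downstream.

`biomlite` gives one `BiomTable` for all four combinations, validates every
document against the specification's invariants, converts losslessly
between versions and representations, and guards every mutation so an
invalid table cannot be produced by accident.

In BIOM 2.1 the matrix is stored twice as compressed sparse arrays
(`data` / `indices` / `indptr`): row-compressed (CSR) under
`observation/matrix` and column-compressed (CSC) under `sample/matrix`.
For a matrix `A` with `nnz` stored nonzeros, row `i`'s entries are
`data[indptr[i] : indptr[i+1]]` at columns `indices[indptr[i] : indptr[i+1]]`.
The reader decodes both encodings and refuses a container in which they
disagree.

## Worked example

```python
from biomlite import build_table, get_value, nnz, to_sparse, validate, write

table = build_table({
    "id": "My Biom",
    "matrix_type": "dense",
    "shape": [2, 2],
    "rows": [{"id": "row1", "metadata": {}},
             {"id": "row2", "metadata": {}}],
    "columns": [{"id": "col1", "metadata": {}},
                {"id": "col2", "metadata": {}}],
    "data": [[0, 1],
             [2, 3]],
})
print(table.shape)                          # (2, 2)
print(get_value(table, "row2", "col2"))     # 3
print(nnz(table))                           # 3
print(validate(table))                      # 0 errors, 0 warnings
print(to_sparse(table).data)                # [[0, 1, 1], [1, 0, 2], [1, 1, 3]]
table.id = []                               # raises BiomTypeError: id: must
                                            # be a string or None, got list
```

The constructor fills every omitted header field with a documented default
(`format`, `format_url`, `table_type`, timestamps, ...), so a partial field
map always yields a fully specification-conformant table. `(2, 2)` is the
observation-by-sample shape; `3` is both the count at (`row2`, `col2`) and,
separately, the number of nonzero entries; the sparse form lists exactly
those nonzeros as `[row, col, value]`.

Export and re-import, either version:

```python
write(table, "2.1", "example.biom")   # HDF5 container, CSR + CSC, gzip
write(table, "1.0", "example.json.biom")
```

## Command line

```bash
biomlite convert -i table.biom -o table.v1.biom --to 1.0
biomlite validate table.biom          # exit 0 iff zero errors
biomlite summarize table.biom --json
```

The input version is sniffed from content (HDF5 signature vs JSON object),
never from the file extension. Failure classes get distinct exit codes:
3 unreadable input, 4 unknown format, 5 validation failure, 6 write
failure.

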