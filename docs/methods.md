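# Methods

## The table model

A BIOM table couples a numeric (or text) observation-by-sample matrix with
two ordered axis lists and a small provenance header. `BiomTable` holds:

| field | type | default when omitted |
|---|---|---|
| `id` | text or `None` | `None` |
| `format` | text | `"Biological Observation Matrix 1.0.0"` |
| `format_url` | text | `http://biom-format.org` |
| `table_type` | text | `"OTU table"` |
| `generated_by` | text | `biomlite <version>` |
| `creation_date` | ISO 8601 text | now |
| `matrix_type` | `dense` \| `sparse` | `sparse` |
| `matrix_element_type` | `int` \| `float` \| `unicode` | inferred from data; `float` when empty |
| `shape` | `[n_rows, n_cols]` | inferred from `rows`/`columns`, else `[0, 0]` |
| `rows`, `columns` | lists of `{id, metadata}` | `[]` |
| `data` | grid or triple list | empty (a dense table defaults to a zero grid so the result is consistent) |
| `comment` | text or `None` | `None` |

Element-type inference: any string value ⇒ `unicode`; else any float ⇒
`float`; else `int`. An integer literal is accepted inside a `float`
matrix (JSON cannot distinguish `0` from `0.0`); the converse is an error.

Invariants (all checked by `validate`, which reports violations as data
rather than raising): axis lengths match `shape`; ids are unique per axis
and non-empty; a dense payload is exactly `n_rows` lists of `n_cols`
values; sparse triples are 0-based, in bounds, and free of duplicate
positions; every value conforms to the element type. Two checks are
deliberately warnings, not errors: an unrecognized `table_type` (producers
extend the vocabulary) and an explicitly stored zero in a sparse payload
(readers are liberal; our writers never emit one).

### Guarded mutation

Attribute assignment is validated at the point of mutation: a wrong-typed
value raises `BiomTypeError` naming the field, and a structural change
that would break an invariant (e.g. replacing `rows` with a list whose
length contradicts `shape`) is rolled back and raises
`BiomConsistencyError`. Nothing ever silently reshapes: growing a table
means supplying a consistent `rows`/`columns`/`shape`/`data` combination
together via the constructor. Setting `shape` directly is permitted only
when it is already consistent with the axes and payload — it is a label,
not a resize operation.

## Representations and conversion

Dense means a full row-major grid with explicit zeros; sparse means sorted
`[row, col, value]` triples with zeros omitted. The "zero" of a domain is
`0`, `0.0`, or `""` — an empty string plays the role of the absent value
in `unicode` tables, so a sparse unicode table cannot represent a stored
empty string (a deliberate limitation, matching "sparse means zero
omitted").

`to_dense`/`to_sparse` are pure functions preserving shape, element type
and the multiset of nonzero values; `to_sparse` is also the canonicalizer
(sorting by `(row, col)`, dropping explicit zeros), so one
dense→sparse→dense cycle is a fixed point. Numeric conversions ride on
`scipy.sparse` COO/CSR/CSC; unicode matrices use a small pure-Python CSR
builder because scipy has no string dtype.

## Serialization

**1.0 (JSON).** One UTF-8 object using the format's own key names
(`type`, `date` on disk ↔ `table_type`, `creation_date` in memory). The
data dialect follows `matrix_type`. Writers are canonical: triples sorted,
zeros dropped, `int` values emitted without a fractional part, floats in
shortest round-trip decimal (Python's `json` default). Unknown top-level
keys are preserved in a `passthrough` map and re-emitted, so extended
documents survive a round trip. Reading is strict by default (a
specification-violating document raises with the full report attached);
`lenient=True` loads what it can and returns `(table, report)`.

**2.1 (HDF5).** Root attributes `id`, `type`, `format-url`,
`format-version = (2, 1)`, `generated-by`, `creation-date`, `shape`,
`nnz`; groups `observation` and `sample`, each with an `ids` text dataset,
a `matrix` group holding the CSR (observation-oriented) or CSC
(sample-oriented) `data`/`indices`/`indptr` trio, and a `metadata` group
with one dataset per metadata key, each value JSON-encoded (`null` = key
absent for that entry). Matrix datasets are gzip-compressed by default;
index datasets are int64 regardless of table size (simplicity over
micro-optimization). `nnz` must equal the data length in *both* groups,
and the reader reconstructs both encodings and rejects containers in
which they disagree. A few choices worth stating:

* The in-memory `format` field and the `passthrough` map are carried as
  extra root attributes, and `comment` as an optional one, so a
  v1→v2→v1 cycle loses nothing; the on-disk version identity rests on the
  HDF5 signature and `format-version`, never on these provenance strings.
* An absent table `id` is stored as the empty string and read back as
  `None` (HDF5 attributes cannot be null).
* Because per-entry metadata is keyed by dataset, `metadata = None` and
  `metadata = {}` are indistinguishable after a 2.1 round trip (both read
  back `{}`), and an explicit `None` metadata *value* reads back as
  absent. Version 1.0 preserves both distinctions.

Version sniffing uses the fixed 8-byte HDF5 signature for 2.1 and a
leading `{` (after whitespace) for 1.0; everything else is `unknown`.
Reading dispatches on content, never on the `.biom` extension, which both
versions share by convention.

## Accessors

`get_value`, `get_row`, `get_column` address the matrix by axis id (the
stable key in BIOM workflows), backed by cached id→index maps that are
invalidated whenever an axis is reassigned; index-addressed variants
exist alongside. A position missing from a sparse payload reads as the
element type's zero. `get_metadata`/`set_metadata` accept either a full
axis-aligned sequence (overwrite; `None` clears the key) or an id→value
map (partial update). `nnz` counts nonzero entries in either
representation and ignores non-canonical explicit zeros.

## Synthetic fixtures

`generate_fixture(FixtureSpec)` emulates a small OTU table: ids
`OTU_0000...`/`Sample000...`, taxonomy-style observation metadata
(kingdom/genus strings plus a confidence score) and environment-style
sample metadata (habitat label, depth). Cells are independently nonzero
with probability `density`; values are uniform on 1..10 (`int`) or
(0, 1] rounded to 6 decimals (`float` — rounding keeps JSON and HDF5
decimal renderings identical). The creation date is fixed so generation
is a pure function of the spec; everything else derives from one
`numpy` generator seeded by `spec.seed`. Default shape parameters in the
tests (single tables of ~5×4 to 50×50 at densities 0.1–1.0) were chosen
as typical of small amplicon studies while keeping the exhaustive
accessor sweeps exact.

Corruption modes inject exactly one violation *after* construction, by
writing to private state so the guarded setters cannot intercept them:
`dup_row_id` (two observations share an id), `bad_shape` (header claims
one row too many), `oob_index` (a sparse triple beyond the last row),
`bad_id_type` (integer table id). They model real producer bugs only in
kind, not in frequency or co-occurrence: real broken files often carry
several interacting defects, encoding problems, or truncation, so a green
corruption sweep shows the validator's taxonomy is sound, not that every
wild file is diagnosable. Likewise the fixtures' metadata is small and
regular; they do not emulate very large tables, deeply nested metadata,
or the pre-1.0 dialects occasionally found in the wild.

## Numerical and degenerate-input notes

* All comparisons in round-trip checks are exact (`==`), never
  tolerance-based: both serializations are lossless for int64 and for
  float64 via shortest round-trip decimals, so exactness is attainable
  and anything less would hide bugs.
* Empty tables (`shape [0, 0]`), empty axes, all-zero matrices and
  density-1.0 matrices are all legal and covered; a zero-length HDF5
  dataset is written unchunked because gzip requires chunking.
* Ties never arise in sorting triples: positions are unique by invariant.

## Known limitations

* No streaming or partial reads: a table must fit in memory.
* No analytics (normalization, rarefaction, diversity) — downstream
  tools own those.
* The 2.1 metadata layout (JSON-per-value datasets) is self-describing
  and read back losslessly by this package, and the matrix/ids portions
  are interoperable with other BIOM readers (verified against
  Bioconductor's biomformat in the test suite), but other readers may
  surface our metadata values as JSON text rather than decoded objects.
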