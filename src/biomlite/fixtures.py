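"""Synthetic BIOM table generation for testing and demonstration.

Generates OTU-table-like fixtures of configurable shape and density,
with taxonomy-style observation metadata and environment-style sample
metadata, deterministically from a seed.  Corruption modes inject one
specific specification violation *after* construction (bypassing the
guarded setters), so that :func:`biomlite.model.validate` can be
exercised on realistic broken documents.

Values are drawn uniformly from 1..10 (int) or (0, 1] (float); each
cell is nonzero with probability ``density``.  The creation date is
fixed so that identical specs yield identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .convert import to_sparse
from .model import AxisEntry, BiomTable

CORRUPTIONS = ("none", "dup_row_id", "bad_shape", "oob_index", "bad_id_type")

_ENVS = ("soil", "gut", "seawater", "rhizosphere", "freshwater")
_GENERA = ("Bacillus", "Pseudomonas", "Streptomyces", "Lactobacillus", "Vibrio", "Nitrosomonas")

#: Fixed so generation is a pure function of the spec.
_FIXTURE_DATE = "2017-01-09T00:00:00"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic table.

    ``matrix_type`` selects the generated representation; it is not a
    corruption axis, just convenience for exercising both payloads.
    """

    n_rows: int
    n_cols: int
    density: float = 0.5
    element_type: str = "int"
    seed: int = 42
    corruption: str = "none"
    matrix_type: str = "sparse"

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("n_rows and n_cols must be positive")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError(f"density must be in [0, 1], got {self.density}")
        if self.element_type not in ("int", "float"):
            raise ValueError(f"element_type must be 'int' or 'float', got {self.element_type!r}")
        if self.corruption not in CORRUPTIONS:
            raise ValueError(f"corruption must be one of {CORRUPTIONS}, got {self.corruption!r}")
        if self.matrix_type not in ("dense", "sparse"):
            raise ValueError(f"matrix_type must be 'dense' or 'sparse', got {self.matrix_type!r}")
        if self.corruption == "dup_row_id" and self.n_rows < 2:
            raise ValueError("dup_row_id corruption needs n_rows >= 2")


def generate_fixture(spec: FixtureSpec) -> BiomTable:
    """Generate one table per ``spec``; deterministic given the seed.

    With ``corruption == "none"`` the result passes validation with
    zero errors; every other mode yields exactly one injected
    violation that validation must report.
    """
    rng = np.random.default_rng(spec.seed)
    n_r, n_c = spec.n_rows, spec.n_cols

    mask = rng.random((n_r, n_c)) < spec.density
    if spec.element_type == "int":
        values = rng.integers(1, 11, size=(n_r, n_c))
        grid = [
            [int(values[i, j]) if mask[i, j] else 0 for j in range(n_c)] for i in range(n_r)
        ]
    else:
        values = 1.0 - rng.random((n_r, n_c))  # uniform on (0, 1]
        grid = [
            [round(float(values[i, j]), 6) if mask[i, j] else 0.0 for j in range(n_c)]
            for i in range(n_r)
        ]

    rows = [
        AxisEntry(
            f"OTU_{i:04d}",
            {
                "taxonomy": ["k__Bacteria", f"g__{rng.choice(_GENERA)}"],
                "confidence": round(float(1.0 - rng.random() * 0.2), 4),
            },
        )
        for i in range(n_r)
    ]
    columns = [
        AxisEntry(
            f"Sample{j:03d}",
            {"environment": str(rng.choice(_ENVS)), "depth_cm": int(rng.integers(0, 100))},
        )
        for j in range(n_c)
    ]

    table = BiomTable(
        {
            "id": f"fixture-{spec.seed}-{n_r}x{n_c}",
            "table_type": "OTU table",
            "creation_date": _FIXTURE_DATE,
            "matrix_type": "dense",
            "matrix_element_type": spec.element_type,
            "shape": [n_r, n_c],
            "rows": rows,
            "columns": columns,
            "data": grid,
        }
    )
    if spec.matrix_type == "sparse" or spec.corruption == "oob_index":
        table = to_sparse(table)

    _corrupt(table, spec)
    return table


def _corrupt(table: BiomTable, spec: FixtureSpec) -> None:
    """Inject the requested violation directly into private state."""
    mode = spec.corruption
    if mode == "none":
        return
    if mode == "dup_row_id":
        table._rows[1].id = table._rows[0].id
    elif mode == "bad_shape":
        table._shape = (spec.n_rows + 1, spec.n_cols)
    elif mode == "oob_index":
        value = 1 if spec.element_type == "int" else 0.5
        table._data.append([spec.n_rows + 3, 0, value])
    elif mode == "bad_id_type":
        table._id = 42
    table._invalidate_caches()


def repair(table: BiomTable, spec: FixtureSpec) -> BiomTable:
    """Undo a fixture corruption: regenerate the same spec uncorrupted."""
    clean = replace(spec, corruption="none")
    fixed = generate_fixture(clean)
    if spec.corruption == "oob_index":
        fixed = to_sparse(fixed)
    return fixed
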