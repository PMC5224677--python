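import copy

import pytest

from biomlite import build_table

# The canonical 2x2 OTU-table construction example: two observations,
# two samples, dense counts [[0, 1], [2, 3]].
WORKED_EXAMPLE_FIELDS = {
    "id": "My Biom",
    "matrix_type": "dense",
    "shape": [2, 2],
    "rows": [
        {"id": "row1", "metadata": {}},
        {"id": "row2", "metadata": {}},
    ],
    "columns": [
        {"id": "col1", "metadata": {}},
        {"id": "col2", "metadata": {}},
    ],
    "data": [
        [0, 1],
        [2, 3],
    ],
}


@pytest.fixture
def worked_fields():
    return copy.deepcopy(WORKED_EXAMPLE_FIELDS)


@pytest.fixture
def worked_table(worked_fields):
    return build_table(worked_fields)
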