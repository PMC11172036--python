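import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sitelink as sl

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_alignment(rows, row_ids=None, mapped=True):
    """Build an Alignment from a list of equal-length strings."""
    grid = np.array([list(r) for r in rows], dtype="<U1")
    ids = row_ids or [f"sp{i}" for i in range(len(rows))]
    positions = list(range(1, grid.shape[1] + 1)) if mapped else None
    return sl.Alignment(row_ids=ids, residues=grid, column_positions=positions)


def column_alignment(*columns, row_ids=None):
    """Build an Alignment whose j-th column is the j-th character sequence."""
    grid = np.array([list(c) for c in columns], dtype="<U1").T
    ids = row_ids or [f"sp{i}" for i in range(grid.shape[0])]
    return sl.Alignment(
        row_ids=ids, residues=grid,
        column_positions=list(range(1, grid.shape[1] + 1)),
    )


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">Homo sapiens\nAC-DE\n>Mus musculus\nACGDE\n>Danio rerio\nAC.D-\n")
    return path
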