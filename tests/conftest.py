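import numpy as np
import pytest

from taxores.regions import Alignment
from taxores.taxonomy import AnnotatedSequence, Lineage


def make_lineage(o="Ord1", f="Fam1", g="Gen1", s="sp1"):
    return Lineage(o, f, g, s)


def make_records(rows, lineage=None):
    """Build AnnotatedSequences from id->residues pairs."""
    lineage = lineage or make_lineage()
    return [
        AnnotatedSequence(rid, f"ACC{idx:03d}", lineage, seq)
        for idx, (rid, seq) in enumerate(rows)
    ]


def make_alignment(seqs, lineage=None):
    """Alignment from a list of equal-length gapped strings."""
    rows = [(f"r{i}", s) for i, s in enumerate(seqs)]
    return Alignment(make_records(rows, lineage))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_alignment(rng):
    """60-column, 12-row random alignment with some gaps/ambiguities."""
    chars = np.array(list("ACGT"))
    mat = chars[rng.integers(0, 4, size=(12, 60))]
    gap_mask = rng.random((12, 60)) < 0.05
    mat[gap_mask] = "-"
    amb_mask = rng.random((12, 60)) < 0.02
    mat[amb_mask] = "N"
    return make_alignment(["".join(row) for row in mat])
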