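import numpy as np
import pytest

from ltrpopgen.io import AlignedLineage


@pytest.fixture
def tiny_alignment():
    """The hand-worked 3-element alignment: one variable column (col 2)."""
    return AlignedLineage(
        lineage_name="tiny",
        element_ids=["E1", "E2", "E3"],
        rows=["MKV-", "MRV-", "MKVL"],
    )


@pytest.fixture
def two_pop_alignment():
    """Two fully separated populations, 20+20 individuals, 50 loci.

    Population 1 is fixed for one residue per column, population 2 for
    another; no gaps.
    """
    rng = np.random.default_rng(1234)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    cols = []
    for _ in range(50):
        a, b = rng.choice(20, size=2, replace=False)
        cols.append((aa[a], aa[b]))
    rows = ["".join(c[0] for c in cols)] * 20 + ["".join(c[1] for c in cols)] * 20
    ids = [f"P1_{i}" for i in range(20)] + [f"P2_{i}" for i in range(20)]
    return AlignedLineage("two_pop", ids, rows)
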