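import numpy as np
import pandas as pd
import pytest

from karyotag.panel import Panel, TagSNP, default_registry


@pytest.fixture
def two_tag_panel() -> Panel:
    tags = [
        TagSNP("tagA", "2La", "2L", 20524058, "A", "G"),
        TagSNP("tagB", "2Rb", "2R", 19023925, "C", "T"),
    ]
    return Panel(tags)


@pytest.fixture
def small_panel() -> Panel:
    """Two tags per inversion across all seven inversion ids."""
    tags = []
    pos = 1000
    for inv_id, inv in default_registry().items():
        for i in range(2):
            tags.append(
                TagSNP(f"{inv_id}_t{i}", inv_id, inv.arm, pos, "A", "G")
            )
            pos += 500
    return Panel(tags)


def make_matrix(values, specimen_ids=None, snp_ids=None, species=None, codes=None):
    """Build a GenotypeMatrix from a nested list (None = missing)."""
    from karyotag.karyotype import GenotypeMatrix

    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in values]
    )
    n, m = arr.shape
    specimen_ids = specimen_ids or [f"S{i}" for i in range(1, n + 1)]
    snp_ids = snp_ids or [f"snp{j}" for j in range(1, m + 1)]
    specimens = pd.DataFrame(
        {
            "species": species if species is not None else ["gambiae"] * n,
            "numeric_code": pd.array(
                codes if codes is not None else range(1, n + 1), dtype="Int64"
            ),
        },
        index=pd.Index(specimen_ids, name="specimen_id"),
    )
    geno = pd.DataFrame(arr, index=specimens.index, columns=snp_ids)
    return GenotypeMatrix(geno, specimens)
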