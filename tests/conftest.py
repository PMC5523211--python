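import numpy as np
import pytest

from barcodegap import (
    LabeledAlignment,
    SpecimenRecord,
    SyntheticConfig,
    simulate_barcode_dataset,
)


def make_alignment(rows, species=None, roles=None, ids=None):
    """Build a LabeledAlignment from plain strings (test helper)."""
    n = len(rows)
    ids = ids or [f"s{i + 1}" for i in range(n)]
    species = species or ["spA"] * n
    roles = roles or ["ingroup"] * n
    records = tuple(
        SpecimenRecord(seq_id=i, species=sp, role=ro)
        for i, sp, ro in zip(ids, species, roles)
    )
    matrix = np.array([list(r.upper()) for r in rows], dtype="<U1")
    return LabeledAlignment(records=records, matrix=matrix)


def random_alignment(rng, n, L, missing_frac=0.1):
    """Random DNA alignment with a random missing mask, for oracle checks."""
    chars = np.array(list("ACGT"), dtype="<U1")
    m = chars[rng.integers(0, 4, size=(n, L))]
    mask = rng.random((n, L)) < missing_frac
    # keep at least one determined character per row
    for i in range(n):
        if mask[i].all():
            mask[i, rng.integers(0, L)] = False
    m[mask] = "-"
    # rows that went all-missing are impossible by construction above
    return make_alignment(["".join(r) for r in m])


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset (10 species, 44 ingroup + 4 outgroups)."""
    return simulate_barcode_dataset(SyntheticConfig(seed=11))


@pytest.fixture
def two_cluster_alignment():
    """Two clean 2-specimen clusters separated by many fixed differences."""
    a = "ACGT" * 25
    b = "TGCA" * 25
    return make_alignment(
        [a, a, b, b],
        species=["spA", "spA", "spB", "spB"],
        ids=["a1", "a2", "b1", "b2"],
    )
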