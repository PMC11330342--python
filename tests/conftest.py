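import numpy as np
import pytest

from miloc.datatypes import (
    AssociationMatrix,
    DiseaseDAG,
    EntityIndex,
    LabelMatrix,
    MIRNA_LOCALIZATIONS,
    MRNA_LOCALIZATIONS,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def mirna_index():
    return EntityIndex(("m1", "m2", "m3"), "mirna")


@pytest.fixture
def small_association(mirna_index):
    # rows r1=(1,0), r2=(1,0), r3=(0,1): the worked GIP-kernel example
    values = np.array([[1, 0], [1, 0], [0, 1]])
    return AssociationMatrix(
        mirna_index, EntityIndex(("d1", "d2"), "disease"), values
    )


@pytest.fixture
def chain_dag():
    # R -> B -> C
    return DiseaseDAG.from_edges([("R", "B"), ("B", "C")])


@pytest.fixture
def sibling_dag():
    # A and B under root R
    return DiseaseDAG.from_edges([("R", "A"), ("R", "B")])


def random_label_matrix(rng, index, kind="mirna"):
    labels = MIRNA_LOCALIZATIONS if kind == "mirna" else MRNA_LOCALIZATIONS
    values = (rng.random((len(index), len(labels))) < 0.4).astype(np.int8)
    values[values.sum(axis=1) == 0, 0] = 1
    return LabelMatrix(index, labels, values)
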