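import numpy as np
import pytest

from catmicro import CountTable, OutcomeSpec, PhylogeneticTree, TaxonomyTree


@pytest.fixture
def two_leaf_tree() -> PhylogeneticTree:
    return PhylogeneticTree.from_newick("(A:1,B:1):0;")


@pytest.fixture
def small_taxonomy() -> TaxonomyTree:
    return TaxonomyTree.from_lineages(
        {
            "A1": "k__K; p__P1; c__C1; o__O1; f__FamA; g__GenA1",
            "A2": "k__K; p__P1; c__C1; o__O1; f__FamA; g__GenA2",
            "B1": "k__K; p__P1; c__C1; o__O1; f__FamB; g__GenB1",
            "C1": "k__K; p__P2; c__C2; o__O2; f__FamC; g__GenC1",
        }
    )


@pytest.fixture
def small_table() -> CountTable:
    rng = np.random.default_rng(42)
    counts = rng.poisson(20, size=(6, 4)) + 1
    return CountTable(
        [f"s{i}" for i in range(6)], ["A1", "A2", "B1", "C1"], counts
    )


@pytest.fixture
def binary_outcome() -> OutcomeSpec:
    return OutcomeSpec(kind="binary", values=np.array([0, 0, 0, 1, 1, 1], dtype=float))
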