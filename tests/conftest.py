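from __future__ import annotations

import pandas as pd
import pytest

from ppiresilience.core import DisruptionTable, GeneTable, PPINetwork


@pytest.fixture
def path4() -> PPINetwork:
    return PPINetwork.from_edges([("a", "b"), ("b", "c"), ("c", "d")], name="P4")


@pytest.fixture
def star6() -> PPINetwork:
    """K_{1,5}: hub h with five leaves."""
    return PPINetwork.from_edges([("h", f"l{i}") for i in range(5)], name="star")


@pytest.fixture
def complete5() -> PPINetwork:
    edges = [(f"n{i}", f"n{j}") for i in range(5) for j in range(i + 1, 5)]
    return PPINetwork.from_edges(edges, name="K5")


@pytest.fixture
def complete10() -> PPINetwork:
    edges = [(f"n{i}", f"n{j}") for i in range(10) for j in range(i + 1, 10)]
    return PPINetwork.from_edges(edges, name="K10")


@pytest.fixture
def edgeless100() -> PPINetwork:
    return PPINetwork(frozenset(f"n{i}" for i in range(100)), frozenset(), name="E100")


@pytest.fixture
def small_genes() -> GeneTable:
    df = pd.DataFrame(
        {
            "gene": ["a", "b", "c", "d", "e"],
            "start": [1, 201, 401, 601, 990],
            "end": [100, 300, 500, 700, 10],
            "strand": ["+", "-", "+", "+", "-"],
            "essential": [True, False, False, False, False],
        }
    )
    return GeneTable.from_records(df, chromosome_length=1000)


@pytest.fixture
def toy_disruptions(small_genes) -> DisruptionTable:
    rows = [
        ("pop1", 5000, "pop1:5000:c1", "a", "nonsense_snp", None),
        ("pop1", 5000, "pop1:5000:c1", "b", "large_deletion", "blk1"),
        ("pop1", 5000, "pop1:5000:c1", "c", "large_deletion", "blk1"),
        ("pop1", 10000, "pop1:10000:c1", "a", "nonsense_snp", None),
        ("pop2", 5000, "pop2:5000:c1", "a", "small_indel", None),
        ("pop2", 10000, "pop2:10000:c1", "d", "mob_insertion", None),
    ]
    df = pd.DataFrame(
        rows,
        columns=["population", "generation", "clone", "gene", "mutation_class", "deletion_block"],
    )
    return DisruptionTable.from_frame(df, genes=small_genes)
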