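import math

import numpy as np
import pandas as pd
import pytest

import oncorestrict as orc


@pytest.fixture(scope="session")
def chain_graph():
    """Root -> A -> B -> C."""
    return orc.RestrictionGraph([("Root", "A"), ("A", "B"), ("B", "C")])


@pytest.fixture(scope="session")
def conjunction_graph():
    """A and B under Root; C requires both (a conjunction)."""
    return orc.RestrictionGraph(
        [("Root", "A"), ("Root", "B"), ("A", "C"), ("B", "C")]
    )


@pytest.fixture(scope="session")
def fixtures():
    return orc.fixture_graphs()


@pytest.fixture(scope="session")
def test_params():
    """Scaled-down McF_4 run parameters used throughout the suite."""
    return orc.ModelParams(
        model="McF_4", sh=math.inf, mutation_rate=1e-5, pop_threshold=5e4
    )


def random_dag_edges(n, rng):
    """Random cover-relation DAG on n labelled nodes (shared test helper)."""
    labels = [f"G{i}" for i in range(n)]
    edges = []
    for i, lab in enumerate(labels):
        parents = [labels[j] for j in range(i) if rng.random() < 0.4]
        for p in parents:
            edges.append((p, lab))
    return labels, edges
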