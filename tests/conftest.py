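import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from nichegrn.io import (ACTIVATION, BINDING, INHIBITION, TRANSCRIPTION,
                         Edge, ExpressionMatrix, PriorNetwork, ProbeMap,
                         SampleSheet)


@pytest.fixture
def toy_matrix():
    return ExpressionMatrix(
        feature_ids=["p1", "p2", "p3", "p4"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [[1.0, 2.0, 9.0, 8.0],
             [3.0, 2.0, 7.0, 9.0],
             [5.0, 4.0, 1.0, 2.0],
             [7.0, 6.0, 3.0, 1.0]]
        ),
        platform_tag="toy",
    )


@pytest.fixture
def toy_sheet():
    return SampleSheet(pd.DataFrame(
        {"sample_id": ["s1", "s2", "s3", "s4"],
         "region": ["stemA", "stemA", "diffA", "diffA"],
         "replicate": [1, 2, 1, 2]}
    ))


@pytest.fixture
def toy_probemap():
    return ProbeMap({"p1": "gA", "p2": "gA", "p3": "gB", "p4": "gC"})


@pytest.fixture
def two_cycle():
    return PriorNetwork((
        Edge("A", "B", TRANSCRIPTION, ACTIVATION),
        Edge("B", "A", TRANSCRIPTION, ACTIVATION),
    ))


def random_signed_network(rng, n_nodes, n_edges, n_unassigned=0):
    """A random simple signed digraph as (PriorNetwork, edge tuples)."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    pairs = [(s, t) for s in nodes for t in nodes if s != t]
    idx = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    signs = [ACTIVATION if rng.random() < 0.5 else INHIBITION for _ in idx]
    for j in list(rng.choice(len(idx), size=min(n_unassigned, len(idx)),
                             replace=False)):
        signs[j] = "unassigned"
    itypes = [BINDING if rng.random() < 0.3 else TRANSCRIPTION for _ in idx]
    edges = tuple(
        Edge(pairs[i][0], pairs[i][1], it, sg)
        for i, it, sg in zip(idx, itypes, signs)
    )
    return PriorNetwork(edges, frozenset(nodes))
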