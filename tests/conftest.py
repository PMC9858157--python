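"""Shared fixtures: small deterministic hypernetworks built in memory."""

from __future__ import annotations

import numpy as np
import pytest

from hyplink import AttributeHypernetwork, PlantedHypernetworkSpec, generate


def community_fixture() -> AttributeHypernetwork:
    """12 nodes in 4 triangle communities, 8 hyperedges (the 4 triangles
    plus one pair per community), 6 attributes (4 community indicators +
    2 within-community role markers), generic positive magnitudes."""
    edges = [frozenset(e) for e in
             [{0, 1, 2}, {3, 4, 5}, {6, 7, 8}, {9, 10, 11},
              {0, 1}, {3, 4}, {6, 7}, {9, 10}]]
    X = np.zeros((12, 6))
    for c in range(4):
        X[3 * c:3 * c + 3, c] = 1.0
    X[[0, 3, 6, 9], 4] = 1.0
    X[[1, 4, 7, 10], 5] = 1.0
    X *= np.random.default_rng(5).uniform(0.8, 1.2, size=X.shape)
    return AttributeHypernetwork.from_data(edges, X)


@pytest.fixture(scope="session")
def tiny_net() -> AttributeHypernetwork:
    return community_fixture()


@pytest.fixture(scope="session")
def small_net() -> AttributeHypernetwork:
    """A 24-node planted instance for oracle comparisons (m <= 30)."""
    spec = PlantedHypernetworkSpec(m=24, C=3, n=30, size_range=(2, 4), d=12,
                                   attrs_per_community=3, attr_noise=0.1,
                                   seed=11)
    net, _ = generate(spec)
    return net


@pytest.fixture(scope="session")
def benchmark_net() -> AttributeHypernetwork:
    """The default synthetic benchmark (generated once per session)."""
    net, _ = generate(PlantedHypernetworkSpec())
    return net
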