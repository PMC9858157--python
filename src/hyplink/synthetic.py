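"""Synthetic attribute hypernetworks with planted hyperlink structure.

The generator emulates the shape of coauthorship/citation/reaction
data: nodes split into communities, most hyperedges drawn within one
community (small collaboration groups), a minority drawn uniformly as
noise, and sparse bag-of-words-like attributes enriched per community.
An observed hyperedge is therefore predictable from both topology
(members share a community) and attributes (members share enriched
columns), which is exactly the signal the dual-channel model exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import AttributeHypernetwork

__all__ = ["PlantedHypernetworkSpec", "generate", "make_benchmark"]


@dataclass(frozen=True)
class PlantedHypernetworkSpec:
    """Parameters of the planted-community generator.

    Defaults give the standard benchmark: 300 nodes in 5 communities,
    400 hyperedges of size 2-5 (90% intra-community), 120 attribute
    columns of which 15 per community are enriched, 5% activation noise.
    """

    m: int = 300
    C: int = 5
    n: int = 400
    size_range: tuple[int, int] = (2, 5)
    p_intra: float = 0.9
    d: int = 120
    attrs_per_community: int = 15
    attr_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.m >= self.C >= 2):
            raise ValueError("need m >= C >= 2")
        if self.size_range[0] < 2 or self.size_range[1] < self.size_range[0]:
            raise ValueError("size_range must satisfy 2 <= min <= max")
        if not (0.0 <= self.p_intra <= 1.0 and 0.0 <= self.attr_noise <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.attrs_per_community * self.C > self.d:
            raise ValueError("more enriched columns than attribute dimensions")
        if self.size_range[1] > self.m // self.C:
            raise ValueError("hyperedge size exceeds community size")


def generate(spec: PlantedHypernetworkSpec
             ) -> tuple[AttributeHypernetwork, np.ndarray]:
    """Draw one instance; returns the hypernetwork and community labels.

    Every node is guaranteed at least one nonzero attribute (one of its
    community's enriched columns is forced on if noise left it empty).
    """
    rng = np.random.default_rng(spec.seed)
    communities = np.repeat(np.arange(spec.C), -(-spec.m // spec.C))[:spec.m]
    members_of = [np.flatnonzero(communities == c) for c in range(spec.C)]

    edges: list[frozenset[int]] = []
    lo, hi = spec.size_range
    while len(edges) < spec.n:
        size = int(rng.integers(lo, hi + 1))
        if rng.random() < spec.p_intra:
            pool = members_of[int(rng.integers(spec.C))]
        else:
            pool = np.arange(spec.m)
        edges.append(frozenset(rng.choice(pool, size=size,
                                          replace=False).tolist()))

    X = (rng.random((spec.m, spec.d)) < spec.attr_noise).astype(np.float64)
    apc = spec.attrs_per_community
    for c in range(spec.C):
        cols = np.arange(c * apc, (c + 1) * apc)
        on = rng.random((members_of[c].size, apc)) < (1.0 - spec.attr_noise)
        X[np.ix_(members_of[c], cols)] = on.astype(np.float64)
    empty = np.flatnonzero(X.sum(axis=1) == 0)
    for i in empty:
        cols = np.arange(communities[i] * apc, (communities[i] + 1) * apc)
        X[i, rng.choice(cols)] = 1.0
    # keep all d columns usable: an all-zero column has no degree
    for j in np.flatnonzero(X.sum(axis=0) == 0):
        X[rng.integers(spec.m), j] = 1.0

    net = AttributeHypernetwork.from_data(edges, X)
    return net, communities


def make_benchmark(spec: PlantedHypernetworkSpec, split_seed: int,
                   out_dir) -> tuple[AttributeHypernetwork, "SplitSpec"]:
    """Generate an instance, split it, and write the file bundle
    (edges.txt, attributes.tsv, split.tsv) round-trippable through the
    package readers."""
    from .io import write_hypernetwork, write_split
    from .training import split_edges

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    net, _ = generate(spec)
    split = split_edges(net.n, split_seed)
    write_hypernetwork(net, out_dir / "edges.txt", out_dir / "attributes.tsv")
    write_split(out_dir / "split.tsv", split)
    return net, split
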