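"""Data model for attribute hypernetworks.

An attribute hypernetwork couples a hypergraph (nodes, hyperedges that
join arbitrary-size node sets) with a nonnegative node-by-attribute
feature matrix ``X``.  Two incidence matrices describe it: the structure
incidence ``S`` (node x hyperedge membership) and the attribute
incidence ``H`` (the sparsity pattern of ``X``, treating each attribute
as a hyperedge over the nodes that carry it).  The diagonal degree
matrices ``Dv`` (node degrees, row sums of ``H``) and ``Da`` (attribute
degrees, column sums of ``H``) normalize the attribute-channel
convolution; both are stored as vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AttributeHypernetwork",
    "Neighborhood",
    "build_structure_incidence",
    "build_attribute_incidence",
    "degree_matrices",
    "derive_neighborhoods",
]


class ValidationError(ValueError):
    """Raised when an input violates a hypernetwork invariant."""


def build_structure_incidence(hyperedges: list[set[int]] | list[list[int]],
                              m: int) -> np.ndarray:
    """Binary m x n structure incidence matrix: S[i, j] = 1 iff node i in edge j.

    Each hyperedge must contain at least two distinct node ids in ``0..m-1``.
    """
    n = len(hyperedges)
    S = np.zeros((m, n), dtype=np.int8)
    for j, edge in enumerate(hyperedges):
        members = set(edge)
        if len(members) < 2:
            raise ValidationError(
                f"hyperedge {j} has {len(members)} distinct nodes; minimum is 2")
        for i in members:
            if not (0 <= i < m):
                raise ValidationError(
                    f"hyperedge {j} references node id {i} outside 0..{m - 1}")
            S[i, j] = 1
    return S


def build_attribute_incidence(X: np.ndarray) -> np.ndarray:
    """Binary incidence H with H[i, j] = 1 exactly where X[i, j] != 0."""
    X = np.asarray(X)
    if not np.all(np.isfinite(X)):
        raise ValidationError("attribute matrix contains NaN or Inf")
    return (X != 0).astype(np.int8)


def degree_matrices(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Node and attribute degree vectors (diagonals of Dv and Da).

    Every node must carry at least one attribute: the attribute-channel
    normalization uses ``Dv^(-1/2)``, which does not exist for a
    zero-degree node.  All-zero attribute columns are the caller's
    responsibility (see :meth:`AttributeHypernetwork.from_data`).
    """
    H = np.asarray(H)
    dv = H.sum(axis=1).astype(np.float64)
    da = H.sum(axis=0).astype(np.float64)
    zero_nodes = np.flatnonzero(dv == 0)
    if zero_nodes.size:
        raise ValidationError(
            f"node(s) {zero_nodes.tolist()} have no nonzero attribute; "
            "Dv^(-1/2) is undefined")
    return dv, da


@dataclass(frozen=True)
class Neighborhood:
    """Clique-expansion neighborhoods: j is a neighbor of i iff they share a
    hyperedge, plus a mandatory self-loop.  Stored both as per-node sorted
    lists and as flat (src, dst) pair arrays for vectorized attention."""

    neighbors: list[np.ndarray]
    src: np.ndarray = field(repr=False)
    dst: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.neighbors)


def derive_neighborhoods(S: np.ndarray) -> Neighborhood:
    """Neighborhoods from the structure incidence (self always included)."""
    S = np.asarray(S, dtype=np.float64)
    m = S.shape[0]
    co = S @ S.T
    neighbors = []
    for i in range(m):
        ids = np.flatnonzero(co[i] > 0)
        if i not in ids:
            ids = np.sort(np.append(ids, i))
        neighbors.append(ids.astype(np.intp))
    src = np.concatenate([np.full(len(ids), i, dtype=np.intp)
                          for i, ids in enumerate(neighbors)]) if m else np.empty(0, np.intp)
    dst = np.concatenate(neighbors) if m else np.empty(0, np.intp)
    return Neighborhood(neighbors=neighbors, src=src, dst=dst)


@dataclass
class AttributeHypernetwork:
    """An attribute hypernetwork with derived incidence and degree matrices."""

    hyperedges: list[frozenset[int]]
    X: np.ndarray
    S: np.ndarray
    H: np.ndarray
    dv: np.ndarray   # diagonal of Dv
    da: np.ndarray   # diagonal of Da
    node_labels: list[str] | None = None

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return len(self.hyperedges)

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_data(cls, hyperedges, X,
                  node_labels: list[str] | None = None) -> "AttributeHypernetwork":
        """Validate and derive S, H, Dv, Da from raw hyperedges and features.

        Duplicate node ids within a hyperedge are dropped (hyperedges are
        sets); all-zero attribute columns are removed with a warning since
        their degree-normalization is undefined.
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValidationError("attribute matrix must be 2-dimensional")
        if np.any(X < 0):
            raise ValidationError("attribute matrix must be nonnegative")
        m = X.shape[0]
        edges = [frozenset(e) for e in hyperedges]
        S = build_structure_incidence([set(e) for e in edges], m)
        H = build_attribute_incidence(X)
        empty_cols = np.flatnonzero(H.sum(axis=0) == 0)
        if empty_cols.size:
            warnings.warn(
                f"dropping {empty_cols.size} all-zero attribute column(s): "
                f"{empty_cols.tolist()[:10]}", stacklevel=2)
            keep = np.setdiff1d(np.arange(X.shape[1]), empty_cols)
            X = X[:, keep]
            H = H[:, keep]
        dv, da = degree_matrices(H)
        return cls(hyperedges=edges, X=X, S=S, H=H, dv=dv, da=da,
                   node_labels=node_labels)

    def neighborhoods(self) -> Neighborhood:
        return derive_neighborhoods(self.S)

    def edge_sets(self) -> set[frozenset[int]]:
        return set(self.hyperedges)
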