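"""Attribute encoder: two-layer node->attribute->node hypergraph convolution.

Each attribute column is treated as a hyperedge over the nodes that carry
it (incidence ``H``, the sparsity pattern of ``X``).  The first layer
aggregates degree-normalized node features into attribute embeddings,

    Y = H^T Dv^(-1/2) X W1                 (no nonlinearity),

and the second propagates them back to nodes,

    Z_AE = ReLU( Dv^(-1/2) H Da^(-1) Y W2 ),

so information flows between nodes through shared attributes.  ``Dv``
and ``Da`` are the node/attribute degree diagonals of ``H``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = ["AttributeEncoderParams", "init_attribute_params",
           "aggregate_to_attributes", "update_nodes", "encode_attributes"]


@dataclass
class AttributeEncoderParams:
    W1: Tensor  # d x d2 first-layer filter
    W2: Tensor  # d2 x d2 second-layer filter

    def tensors(self) -> dict[str, Tensor]:
        return {"ae.W1": self.W1, "ae.W2": self.W2}


def init_attribute_params(d: int, d2: int,
                          rng: np.random.Generator) -> AttributeEncoderParams:
    def glorot(fan_in, fan_out, shape):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(rng.uniform(-s, s, size=shape), requires_grad=True)

    return AttributeEncoderParams(W1=glorot(d, d2, (d, d2)),
                                  W2=glorot(d2, d2, (d2, d2)))


def _norm_in(H: np.ndarray, dv: np.ndarray) -> np.ndarray:
    """Constant d x m operator H^T Dv^(-1/2)."""
    return np.asarray(H, dtype=np.float64).T * (dv ** -0.5)


def _norm_out(H: np.ndarray, dv: np.ndarray, da: np.ndarray) -> np.ndarray:
    """Constant m x d operator Dv^(-1/2) H Da^(-1)."""
    if np.any(da <= 0):
        raise ValueError("attribute degree must be strictly positive")
    return (np.asarray(H, dtype=np.float64) * (1.0 / da)) * (dv ** -0.5)[:, None]


def aggregate_to_attributes(X, H, dv, params: AttributeEncoderParams) -> Tensor:
    """First layer: attribute embeddings ``Y = H^T Dv^(-1/2) X W1``."""
    dv = np.asarray(dv, dtype=np.float64)
    if np.any(dv <= 0):
        raise ValueError("node degree must be strictly positive")
    X = X if isinstance(X, Tensor) else Tensor(X)
    return Tensor(_norm_in(H, dv)) @ (X @ params.W1)


def update_nodes(Y: Tensor, H, dv, da, params: AttributeEncoderParams) -> Tensor:
    """Second layer: ``Z_AE = ReLU(Dv^(-1/2) H Da^(-1) Y W2)``."""
    A = _norm_out(H, np.asarray(dv, float), np.asarray(da, float))
    return ((Tensor(A) @ Y) @ params.W2).relu()


def encode_attributes(X, H, dv, da, params: AttributeEncoderParams,
                      *, dropout: float = 0.0,
                      rng: np.random.Generator | None = None,
                      train: bool = False) -> Tensor:
    """Both layers, with training-time dropout between them."""
    Y = aggregate_to_attributes(X, H, dv, params)
    if train and dropout > 0:
        mask = (rng.random(Y.shape) >= dropout) / (1.0 - dropout)
        Y = Y * Tensor(mask)
    return update_nodes(Y, H, dv, da, params)
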