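"""Structure encoder: attention-weighted neighbor aggregation.

Nodes are first projected through a nonlinear layer,
``Z~ = ReLU(X W_SE + b_SE)``.  Attention logits for each neighbor pair
(i, j) in the clique-expansion neighborhood use the standard
graph-attention composition

    omega_ij = LeakyReLU( a^T  W_att [z~_i || z~_j] ),

normalized by a softmax over each node's neighborhood, and the
structural embedding is the weighted neighbor sum
``Z_SE[i] = sum_j a_ij z~_j``.  Because the concatenation splits the
projection, the logit decomposes exactly into two per-node scalars
``(a^T W_l) z~_i + (a^T W_r) z~_j``, which is how it is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, segment_softmax, segment_sum
from .core import Neighborhood

__all__ = ["StructureEncoderParams", "init_structure_params",
           "project_features", "attention_weights", "attention_table",
           "aggregate", "encode_structure"]


@dataclass
class StructureEncoderParams:
    W_SE: Tensor   # d x d1 projection
    b_SE: Tensor   # d1 bias
    W_att: Tensor  # d_att x 2*d1 attention projection
    a: Tensor      # d_att attention vector

    def tensors(self) -> dict[str, Tensor]:
        return {"se.W_SE": self.W_SE, "se.b_SE": self.b_SE,
                "se.W_att": self.W_att, "se.a": self.a}


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> Tensor:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-s, s, size=shape), requires_grad=True)


def init_structure_params(d: int, d1: int, d_att: int,
                          rng: np.random.Generator) -> StructureEncoderParams:
    return StructureEncoderParams(
        W_SE=_glorot(rng, d, d1, (d, d1)),
        b_SE=Tensor(np.zeros(d1), requires_grad=True),
        W_att=_glorot(rng, 2 * d1, d_att, (d_att, 2 * d1)),
        a=_glorot(rng, d_att, 1, (d_att,)),
    )


def project_features(X, params: StructureEncoderParams) -> Tensor:
    """``Z~ = ReLU(X W_SE + b_SE)``; entrywise nonnegative."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    if X.shape[1] != params.W_SE.shape[0]:
        raise ValueError(
            f"feature dim {X.shape[1]} != projection rows {params.W_SE.shape[0]}")
    return (X @ params.W_SE + params.b_SE).relu()


def attention_weights(Zt: Tensor, nbh: Neighborhood,
                      params: StructureEncoderParams,
                      leaky_slope: float = 0.2,
                      uniform: bool = False) -> Tensor:
    """Softmax-normalized attention weights, flat over (nbh.src, nbh.dst).

    With ``uniform=True`` every neighbor of i receives 1/|N_i| (the
    node-attention ablation).
    """
    m = len(nbh)
    if uniform:
        counts = np.array([len(ids) for ids in nbh.neighbors], dtype=np.float64)
        return Tensor(1.0 / counts[nbh.src])
    d1 = Zt.shape[1]
    # a^T W_att [z_i || z_j]  ==  (a^T W_l) z_i + (a^T W_r) z_j
    c = (params.a @ params.W_att)          # 2*d1
    cl = c.gather(np.arange(d1))
    cr = c.gather(np.arange(d1, 2 * d1))
    logits = (Zt @ cl).gather(nbh.src) + (Zt @ cr).gather(nbh.dst)
    return segment_softmax(logits.leaky_relu(leaky_slope), nbh.src, m)


def attention_table(weights: Tensor | np.ndarray, nbh: Neighborhood) -> np.ndarray:
    """Dense m x m row-normalized weight table (zeros off-neighborhood)."""
    w = weights.data if isinstance(weights, Tensor) else np.asarray(weights)
    m = len(nbh)
    table = np.zeros((m, m))
    table[nbh.src, nbh.dst] = w
    return table


def aggregate(Zt: Tensor, nbh: Neighborhood, weights: Tensor) -> Tensor:
    """``Z_SE[i] = sum_{j in N_i} a_ij z~_j`` (a convex combination)."""
    m = len(nbh)
    contrib = weights.reshape(-1, 1) * Zt.gather(nbh.dst)
    return segment_sum(contrib, nbh.src, m)


def _dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    if rate <= 0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def encode_structure(X, nbh: Neighborhood, params: StructureEncoderParams,
                     *, leaky_slope: float = 0.2, uniform: bool = False,
                     dropout: float = 0.0,
                     rng: np.random.Generator | None = None,
                     train: bool = False) -> Tensor:
    """Full structure channel; dropout (training only) on the projected
    features and on the attention weights."""
    Zt = project_features(X, params)
    if train and dropout > 0:
        Zt = _dropout(Zt, dropout, rng)
    w = attention_weights(Zt, nbh, params, leaky_slope=leaky_slope,
                          uniform=uniform)
    if train and dropout > 0 and not uniform:
        w = _dropout(w, dropout, rng)
    return aggregate(Zt, nbh, w)
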