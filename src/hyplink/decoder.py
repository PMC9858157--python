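"""Fusion of the two channels, hyperedge-level attention pooling, scoring.

Node embeddings from the structure and attribute channels are fused by a
linear map on their concatenation, ``Z_v = W_FF [Z_SE || Z_AE]``.  A
hyperedge's embedding is an attention-weighted sum of its members'
fused embeddings: each member i receives a raw score
``w^T tanh(W_EA z_i)``, normalized by a softmax within the hyperedge.
The hyperedge score is a small MLP squashed to (0, 1):

    s(e) = sigmoid( u^T ReLU(W_SC z_e + b_SC) ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, segment_softmax, segment_sum

__all__ = ["DecoderParams", "init_decoder_params", "fuse",
           "member_arrays", "hyperedge_attention", "embed_hyperedge",
           "score", "score_edges"]


@dataclass
class DecoderParams:
    W_FF: Tensor   # dv x (d1 + d2) fusion
    W_EA: Tensor   # d_ea x dv hyperedge attention projection
    w: Tensor      # d_ea attention vector
    W_SC: Tensor   # de x dv scoring layer
    b_SC: Tensor   # de
    u: Tensor      # de final linear functional

    def tensors(self) -> dict[str, Tensor]:
        return {"dec.W_FF": self.W_FF, "dec.W_EA": self.W_EA, "dec.w": self.w,
                "dec.W_SC": self.W_SC, "dec.b_SC": self.b_SC, "dec.u": self.u}


def init_decoder_params(d_in: int, dv: int, d_ea: int, de: int,
                        rng: np.random.Generator) -> DecoderParams:
    def glorot(fan_in, fan_out, shape):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(rng.uniform(-s, s, size=shape), requires_grad=True)

    return DecoderParams(
        W_FF=glorot(d_in, dv, (dv, d_in)),
        W_EA=glorot(dv, d_ea, (d_ea, dv)),
        w=glorot(d_ea, 1, (d_ea,)),
        W_SC=glorot(dv, de, (de, dv)),
        b_SC=Tensor(np.zeros(de), requires_grad=True),
        u=glorot(de, 1, (de,)),
    )


def fuse(channels: list[Tensor], params: DecoderParams) -> Tensor:
    """``Z_v = W_FF [Z_SE || Z_AE]`` row-wise (order: structure, attribute).

    A single surviving channel (ablated model) is fused alone.
    """
    rows = {c.shape[0] for c in channels}
    if len(rows) != 1:
        raise ValueError(f"channel row counts differ: {sorted(rows)}")
    Z = channels[0] if len(channels) == 1 else concat(channels, axis=1)
    return Z @ params.W_FF.T


def member_arrays(edges) -> tuple[np.ndarray, np.ndarray]:
    """Flatten hyperedges into (member node ids, hyperedge index) arrays,
    members in ascending order within each edge."""
    mem, seg = [], []
    for k, e in enumerate(edges):
        ids = sorted(e)
        if not ids:
            raise ValueError(f"hyperedge {k} is empty")
        mem.extend(ids)
        seg.extend([k] * len(ids))
    return np.asarray(mem, dtype=np.intp), np.asarray(seg, dtype=np.intp)


def hyperedge_attention(Z_v: Tensor, mem: np.ndarray, seg: np.ndarray,
                        n_edges: int, params: DecoderParams,
                        uniform: bool = False) -> Tensor:
    """Member weights, flat over (mem, seg); each hyperedge's sum to 1."""
    if uniform:
        counts = np.bincount(seg, minlength=n_edges).astype(np.float64)
        return Tensor(1.0 / counts[seg])
    raw = (Z_v @ params.W_EA.T).tanh() @ params.w     # per node, shape (m,)
    return segment_softmax(raw.gather(mem), seg, n_edges)


def embed_hyperedge(Z_v: Tensor, mem: np.ndarray, seg: np.ndarray,
                    n_edges: int, weights: Tensor) -> Tensor:
    """``z_e = sum_{i in e} a_i z_i`` for every edge at once."""
    return segment_sum(weights.reshape(-1, 1) * Z_v.gather(mem), seg, n_edges)


_SCORE_LO = np.nextafter(0.0, 1.0)
_SCORE_HI = np.nextafter(1.0, 0.0)


def score(Z_e: Tensor, params: DecoderParams) -> Tensor:
    """Scalar score per hyperedge, strictly inside (0, 1).

    The sigmoid output is clamped away from exactly 0/1 so downstream
    ranking arithmetic keeps strict bounds even for saturated logits.
    """
    hidden = (Z_e @ params.W_SC.T + params.b_SC).relu()
    return (hidden @ params.u).sigmoid().clip(_SCORE_LO, _SCORE_HI)


def score_edges(Z_v: Tensor, edges, params: DecoderParams,
                uniform_attention: bool = False) -> Tensor:
    """Attention-pool and score a list of hyperedges."""
    mem, seg = member_arrays(edges)
    n_edges = len(edges)
    m = Z_v.shape[0]
    if mem.size and mem.max() >= m:
        raise ValueError(f"hyperedge references node {mem.max()} >= m={m}")
    a = hyperedge_attention(Z_v, mem, seg, n_edges, params,
                            uniform=uniform_attention)
    Z_e = embed_hyperedge(Z_v, mem, seg, n_edges, a)
    return score(Z_e, params)
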