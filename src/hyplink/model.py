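"""The full hyperlink-prediction model: dual-channel encoder + decoder.

The structure channel attends over clique-expansion neighborhoods; the
attribute channel convolves over the node-attribute incidence.  Fused
node embeddings are attention-pooled into hyperedge embeddings and
scored in (0, 1).  Ablation flags in :class:`~hyplink.config.ModelConfig`
switch off one channel or replace either attention with uniform weights.
"""

from __future__ import annotations

import numpy as np

from . import attributes as ae
from . import decoder as dec
from . import structure as se
from .autodiff import Tensor
from .config import ModelConfig
from .core import AttributeHypernetwork
from .io import load_checkpoint, save_checkpoint

__all__ = ["HyperlinkModel"]


class HyperlinkModel:
    """Scores candidate hyperedges of an attribute hypernetwork.

    Parameters are initialized with seeded Glorot-uniform draws; all
    forward passes are deterministic unless ``train=True`` (dropout).
    """

    def __init__(self, net: AttributeHypernetwork, config: ModelConfig | None = None,
                 seed: int = 0):
        self.net = net
        self.config = config or ModelConfig()
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        cfg = self.config
        self.nbh = net.neighborhoods()
        self._X = Tensor(net.X)

        self.se_params = None if cfg.no_structure else se.init_structure_params(
            net.d, cfg.d1, cfg.d_att, rng)
        self.ae_params = None if cfg.no_attribute else ae.init_attribute_params(
            net.d, cfg.d2, rng)
        d_in = (0 if cfg.no_structure else cfg.d1) + \
               (0 if cfg.no_attribute else cfg.d2)
        self.dec_params = dec.init_decoder_params(d_in, cfg.dv, cfg.d_ea,
                                                  cfg.de, rng)

    # -- parameters -----------------------------------------------------------

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        if self.se_params is not None:
            out.update(self.se_params.tensors())
        if self.ae_params is not None:
            out.update(self.ae_params.tensors())
        out.update(self.dec_params.tensors())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise ValueError(f"missing parameter(s) in state: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def save(self, path) -> None:
        cfg = {"model": self.config.__dict__, "seed": self.seed,
               "m": self.net.m, "d": self.net.d}
        save_checkpoint(path, self.parameters(), cfg)

    @classmethod
    def load(cls, path, net: AttributeHypernetwork) -> "HyperlinkModel":
        state, header = load_checkpoint(path)
        cfg = ModelConfig(**header["model"])
        if header["m"] != net.m or header["d"] != net.d:
            raise ValueError(
                f"checkpoint was trained on m={header['m']}, d={header['d']}; "
                f"network has m={net.m}, d={net.d}")
        model = cls(net, cfg, seed=header.get("seed", 0))
        model.load_state_dict(state)
        return model

    # -- forward --------------------------------------------------------------

    def node_embeddings(self, train: bool = False,
                        rng: np.random.Generator | None = None) -> Tensor:
        cfg, net = self.config, self.net
        channels: list[Tensor] = []
        if self.se_params is not None:
            channels.append(se.encode_structure(
                self._X, self.nbh, self.se_params,
                leaky_slope=cfg.leaky_slope, uniform=cfg.uniform_node_attention,
                dropout=cfg.dropout, rng=rng, train=train))
        if self.ae_params is not None:
            channels.append(ae.encode_attributes(
                self._X, net.H, net.dv, net.da, self.ae_params,
                dropout=cfg.dropout, rng=rng, train=train))
        return dec.fuse(channels, self.dec_params)

    def forward_scores(self, edges, train: bool = False,
                       rng: np.random.Generator | None = None) -> Tensor:
        """Differentiable scores for a list of hyperedges (node-id sets)."""
        Z_v = self.node_embeddings(train=train, rng=rng)
        return dec.score_edges(Z_v, edges, self.dec_params,
                               uniform_attention=self.config.uniform_edge_attention)

    def score_edges(self, edges) -> np.ndarray:
        """Inference-mode scores as a plain array (dropout disabled)."""
        return self.forward_scores(list(edges), train=False).data

    def export_attention(self, edge_ids=None) -> list[tuple[int, int, float]]:
        """Per-hyperedge member attention weights as
        (hyperedge id, node id, weight) rows; each hyperedge sums to 1."""
        n = self.net.n
        if edge_ids is None:
            edge_ids = range(n)
        edge_ids = list(edge_ids)
        for eid in edge_ids:
            if not 0 <= eid < n:
                raise ValueError(f"unknown hyperedge id {eid}")
        edges = [self.net.hyperedges[eid] for eid in edge_ids]
        Z_v = self.node_embeddings(train=False)
        mem, seg = dec.member_arrays(edges)
        a = dec.hyperedge_attention(Z_v, mem, seg, len(edges), self.dec_params,
                                    uniform=self.config.uniform_edge_attention)
        return [(edge_ids[s], int(v), float(w))
                for v, s, w in zip(mem, seg, a.data)]
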