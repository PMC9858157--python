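"""Training: negative hyperedge sampling, ranking loss, optimization loop.

Negatives are hard non-examples: for a positive hyperedge e of size s,
a negative keeps ``floor(s/2)`` members sampled from e and draws the
remaining ``s - floor(s/2)`` from outside, so size is matched and half
the membership is real.  The ranking loss pushes observed hyperedges
above sampled ones,

    L = (1/|E1|) sum_i softplus( mean_j s(e_j^-) - s(e_i^+) ),

evaluated per mini-batch (``loss_mode="paired"`` instead subtracts each
positive's own matched negative).  Optimization is Adam with early
stopping on validation AUC against a frozen validation negative set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .config import ModelConfig, TrainingConfig
from .core import AttributeHypernetwork
from .evaluation import auc
from .model import HyperlinkModel

__all__ = ["SplitSpec", "LossState", "sample_negative", "sample_negatives",
           "split_edges", "ranking_loss", "Adam", "train"]


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint 70/10/20 train/validation/test partition of hyperedge ids."""

    train_edges: np.ndarray
    val_edges: np.ndarray
    test_edges: np.ndarray
    seed: int


@dataclass
class LossState:
    """Per-epoch training loss and validation AUC traces."""

    loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_auc: float = float("nan")


def split_edges(n_edges: int, seed: int) -> SplitSpec:
    """Reproducible 70% train / 10% validation / 20% test split."""
    if n_edges < 10:
        raise ValueError(f"need at least 10 hyperedges to split, got {n_edges}")
    order = np.random.default_rng(seed).permutation(n_edges)
    n_test = int(round(0.2 * n_edges))
    n_val = int(round(0.1 * n_edges))
    return SplitSpec(train_edges=np.sort(order[n_test + n_val:]),
                     val_edges=np.sort(order[n_test:n_test + n_val]),
                     test_edges=np.sort(order[:n_test]),
                     seed=seed)


def sample_negative(edge: frozenset[int], m: int, rng: np.random.Generator,
                    observed: set[frozenset[int]] | None = None,
                    max_tries: int = 100) -> frozenset[int]:
    """One size-matched negative: floor(|e|/2) members kept from ``edge``,
    the rest drawn from outside it.  Resamples (up to ``max_tries``) if the
    candidate collides with an observed hyperedge."""
    edge = frozenset(edge)
    size = len(edge)
    if size < 2:
        raise ValueError("positive hyperedge must have >= 2 nodes")
    n_in = size // 2
    n_out = size - n_in
    outside = np.setdiff1d(np.arange(m), np.fromiter(edge, dtype=np.intp))
    if outside.size < n_out:
        raise ValueError(
            f"node universe of size {m} too small to sample {n_out} "
            f"nodes outside a hyperedge of size {size}")
    inside = np.fromiter(edge, dtype=np.intp)
    inside.sort()
    observed = observed or set()
    for _ in range(max_tries):
        kept = rng.choice(inside, size=n_in, replace=False)
        drawn = rng.choice(outside, size=n_out, replace=False)
        neg = frozenset(np.concatenate([kept, drawn]).tolist())
        if neg != edge and neg not in observed:
            return neg
    raise RuntimeError("could not sample a fresh negative hyperedge "
                       f"for {sorted(edge)} in {max_tries} tries")


def sample_negatives(edges, m: int, rng: np.random.Generator,
                     observed: set[frozenset[int]] | None = None,
                     per_positive: int = 1) -> list[frozenset[int]]:
    """Matched negatives, ``per_positive`` for each positive, in order."""
    return [sample_negative(e, m, rng, observed)
            for e in edges for _ in range(per_positive)]


def ranking_loss(scores_pos: Tensor, scores_neg: Tensor,
                 mode: str = "mean") -> Tensor:
    """Softplus ranking loss over a batch of positive/negative scores."""
    if scores_pos.data.size == 0 or scores_neg.data.size == 0:
        raise ValueError("empty score batch")
    if np.any(np.isnan(scores_pos.data)) or np.any(np.isnan(scores_neg.data)):
        raise ValueError("NaN scores in ranking loss")
    if mode == "mean":
        diff = scores_neg.mean() - scores_pos
    elif mode == "paired":
        if scores_pos.shape != scores_neg.shape:
            raise ValueError("paired mode needs matched batch sizes")
        diff = scores_neg - scores_pos
    else:
        raise ValueError(f"unknown loss mode {mode!r}")
    return diff.softplus().mean()


class Adam:
    """Adam optimizer over a named dict of tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(net: AttributeHypernetwork, split: SplitSpec,
          train_cfg: TrainingConfig | None = None,
          model_cfg: ModelConfig | None = None,
          model: HyperlinkModel | None = None) -> tuple[HyperlinkModel, LossState]:
    """Optimize the model on the training hyperedges.

    Each epoch resamples one negative per training positive, sweeps
    shuffled mini-batches, then evaluates AUC on the validation positives
    against a frozen validation negative set; the best-validation
    parameters are restored at the end.  Fully deterministic per seed.
    """
    train_cfg = train_cfg or TrainingConfig()
    rng = np.random.default_rng(train_cfg.seed)
    if model is None:
        model = HyperlinkModel(net, model_cfg, seed=int(rng.integers(2 ** 31)))
    observed = net.edge_sets()
    pos_train = [net.hyperedges[i] for i in split.train_edges]
    pos_val = [net.hyperedges[i] for i in split.val_edges]
    # frozen validation negatives for comparable epoch-to-epoch AUC
    val_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
    neg_val = sample_negatives(pos_val, net.m, val_rng, observed) if pos_val else []

    state = LossState()
    optimizer = Adam(model.parameters(), lr=train_cfg.learning_rate)
    best_state = model.state_dict()
    state.best_epoch = 0
    state.best_val_auc = -np.inf
    since_best = 0
    B = train_cfg.batch_size

    for epoch in range(train_cfg.max_epochs):
        negs = sample_negatives(pos_train, net.m, rng, observed,
                                per_positive=train_cfg.negatives_per_positive)
        order = rng.permutation(len(pos_train))
        drop_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
        epoch_loss = 0.0
        for start in range(0, len(order), B):
            idx = order[start:start + B]
            k = train_cfg.negatives_per_positive
            batch_pos = [pos_train[i] for i in idx]
            batch_neg = [negs[i * k + j] for i in idx for j in range(k)]
            scores = model.forward_scores(batch_pos + batch_neg, train=True,
                                          rng=drop_rng)
            s_pos = scores.gather(np.arange(len(batch_pos)))
            s_neg = scores.gather(np.arange(len(batch_pos), len(batch_pos)
                                            + len(batch_neg)))
            loss = ranking_loss(s_pos, s_neg, mode=train_cfg.loss_mode)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: loss={loss.data} at epoch {epoch}")
            model.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
        state.loss.append(epoch_loss / max(len(order), 1))

        if pos_val:
            s_pos = model.score_edges(pos_val)
            s_neg = model.score_edges(neg_val)
            val_auc = auc(s_pos, s_neg)
        else:
            val_auc = float("nan")
        state.val_auc.append(val_auc)
        if pos_val and val_auc > state.best_val_auc:
            state.best_val_auc = val_auc
            state.best_epoch = epoch
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if pos_val and since_best > train_cfg.patience:
                break

    if train_cfg.max_epochs > 0 and pos_val:
        model.load_state_dict(best_state)
    return model, state
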