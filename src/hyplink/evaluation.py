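"""Evaluation: AUC, recall within the top half of the ranking, baselines.

AUC is the probability that a random positive outscores a random
negative, ties counted 1/2 — computed exactly from rank statistics.
R@k takes k = ceil(L/2) where L is the number of truly missing
hyperedges and reports the fraction of them recovered in the top k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core import AttributeHypernetwork
from .model import HyperlinkModel

__all__ = ["EvalReport", "auc", "recall_at_k", "baseline_pairwise_score",
           "evaluate"]


@dataclass
class EvalReport:
    """Averaged evaluation metrics plus the per-edge score table of the
    last run (columns: edge key, score, label)."""

    auc: float
    r_at_k: float
    k: int
    n_pos: int
    n_neg: int
    seed: int
    n_runs: int
    scores: list[tuple[str, float, int]]

    def to_dict(self) -> dict:
        return {"auc": self.auc, "r_at_k": self.r_at_k, "k": self.k,
                "n_pos": self.n_pos, "n_neg": self.n_neg,
                "seed": self.seed, "n_runs": self.n_runs}


def auc(scores_pos, scores_neg) -> float:
    """Pairwise AUC with ties counted 1/2 (Mann-Whitney U / (N*M))."""
    pos = np.asarray(scores_pos, dtype=np.float64).ravel()
    neg = np.asarray(scores_neg, dtype=np.float64).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(np.concatenate([pos, neg]), method="average")
    u = ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def recall_at_k(scores, labels, L: int | None = None) -> tuple[float, int]:
    """R@k with k = ceil(L/2); ties broken by stable candidate order.

    ``labels`` are 1 for truly missing hyperedges, 0 otherwise; ``L``
    defaults to the number of positives in the candidate list.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.intp)
    if L is None:
        L = int(labels.sum())
    if L < 1:
        raise ValueError("need at least one true missing hyperedge")
    if labels.sum() < L:
        raise ValueError("candidate list does not contain all missing edges")
    k = (L + 1) // 2
    top = np.argsort(-scores, kind="stable")[:k]
    return float(labels[top].sum() / L), k


def baseline_pairwise_score(node_embeddings: np.ndarray, edge) -> float:
    """Mean-pairwise-similarity score for embedding-only baselines:
    sigmoid of the sum of inner products over unordered member pairs,
    divided by the hyperedge size |e| (not the pair count)."""
    ids = sorted(edge)
    if len(ids) < 2:
        raise ValueError("baseline score needs a hyperedge with >= 2 nodes")
    Z = np.asarray(node_embeddings, dtype=np.float64)[ids]
    gram = Z @ Z.T
    total = (gram.sum() - np.trace(gram)) / 2.0
    return float(1.0 / (1.0 + np.exp(-total / len(ids))))


def evaluate(model: HyperlinkModel, net: AttributeHypernetwork, split,
             seed: int = 0, n_runs: int = 1, neg_ratio: float = 1.0) -> EvalReport:
    """Score the held-out test hyperedges against sampled negatives.

    Negatives come from the training sampler (size-matched, half-inside)
    and never collide with any observed hyperedge.  AUC and R@k are
    averaged over ``n_runs`` independent negative resamplings.
    """
    from .training import sample_negatives  # local import avoids a cycle

    test_edges = [net.hyperedges[i] for i in split.test_edges]
    if not test_edges:
        raise ValueError("empty test set")
    rng = np.random.default_rng(seed)
    observed = net.edge_sets()
    L = len(test_edges)
    s_pos = model.score_edges(test_edges)
    aucs, recalls, k = [], [], 0
    for _ in range(n_runs):
        n_neg = max(1, int(round(neg_ratio * L)))
        per_pos = -(-n_neg // L)
        negs = sample_negatives(test_edges, net.m, rng, observed,
                                per_positive=per_pos)[:n_neg]
        s_neg = model.score_edges(negs)
        aucs.append(auc(s_pos, s_neg))
        r, k = recall_at_k(np.concatenate([s_pos, s_neg]),
                           np.concatenate([np.ones(L, dtype=np.intp),
                                           np.zeros(len(negs), dtype=np.intp)]),
                           L=L)
        recalls.append(r)
    table = [(",".join(map(str, sorted(e))), float(s), 1)
             for e, s in zip(test_edges, s_pos)]
    table += [(",".join(map(str, sorted(e))), float(s), 0)
              for e, s in zip(negs, s_neg)]
    return EvalReport(auc=float(np.mean(aucs)), r_at_k=float(np.mean(recalls)),
                      k=k, n_pos=L, n_neg=len(negs), seed=seed, n_runs=n_runs,
                      scores=table)
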