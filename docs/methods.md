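# Methods

## Problem and data model

`hyplink` treats hyperlink prediction as a set-ranking problem: given an
attribute hypernetwork `G = (V, E, X)` with part of `E` hidden, learn a
scoring function `s : 2^V → (0, 1)` so that true-but-unobserved
hyperedges outrank fabricated ones.  Hyperedges are node *sets*
(duplicates removed, minimum size 2); node ids are dense and 0-based,
with an id-mapping table at the I/O boundary for string labels.  Two
incidence matrices carry the structure: `S` (node × hyperedge) and `H`
(node × attribute, the sparsity pattern of `X`).  Degree matrices are
stored as vectors; the diagonal-matrix formulation is a contract, not a
storage format.  A node with no nonzero attribute is rejected at load
time because the attribute-channel normalization needs `Dv^(−1/2)`;
all-zero attribute columns are dropped with a warning (their `Da^(−1)`
is undefined) rather than rejected.

## Encoders

**Structure channel.**  Neighborhoods come from the clique expansion of
the hypergraph — two nodes are neighbors iff they co-occur in at least
one hyperedge — plus a mandatory self-loop so that a node appearing in
no hyperedge still aggregates its own features.  The attention logit
uses the standard graph-attention composition
`ω_ij = LeakyReLU(aᵀ W_att [z̃_i ∥ z̃_j])` (slope 0.2, configurable):
the concatenate-project-score order is kept while being dimensionally
sound, and because matrix–concatenation factorizes, the logit is
computed as a sum of two per-node scalars, `(aᵀW_l)z̃_i + (aᵀW_r)z̃_j`,
which is algebraically identical and linear-time.  A LeakyReLU rather
than ReLU precedes the softmax so logits cannot die en masse.  Dropout
(rate 0.5) is applied to the projected features and to the attention
weights during training only.

**Attribute channel.**  Attributes act as hyperedges over the nodes
carrying them: layer one aggregates degree-normalized node features into
attribute embeddings `Y = Hᵀ Dv^(−1/2) X W₁` (no nonlinearity — the
single activation sits after the second layer), layer two propagates
them back, `Z_AE = ReLU(Dv^(−1/2) H Da^(−1) Y W₂)`.  The first-layer
filter `W₁` mirrors the learned second-layer filter.  Dropout is applied
between the layers during training, symmetric with the structure
channel.  Nodes with identical attribute rows provably receive identical
`Z_AE` rows, and node/attribute permutations commute with the encoding —
both properties are exercised in tests.

## Decoder

Fused node embeddings `Z_v = W_FF [Z_SE ∥ Z_AE]` (structure first; the
order is arbitrary but frozen for checkpoint compatibility) are pooled
per candidate hyperedge by member-level attention
`α_i ∝ exp(wᵀ tanh(W_EA z_i))` and scored by a one-hidden-layer MLP
with a final learned linear functional and sigmoid,
`s(e) = σ(uᵀ ReLU(W_SC z_e + b_SC))`.  The extra functional `u`
collapses the hidden vector to the scalar the ranking loss requires; the
hidden width `de` defaults to 64.  The sigmoid output is clamped to the
largest open sub-interval of (0, 1) representable in float64 so strict
bounds survive saturated logits.

Defaults (width of each part): `d1 = d2 = 128` for the two channels,
fused width `dv = 128`, attention widths `d_att = d_ea = 128`.  These
mirror the regime in which the method was designed; the `sweep` command
retrains across widths to expose the dimension–quality trade-off.

## Training

For each observed hyperedge a size-matched negative is drawn each epoch:
`⌊|e|/2⌋` members kept (for odd sizes the majority comes from outside,
keeping negatives hard while honoring the half-and-half design), the
rest sampled uniformly outside `e`, resampling (≤100 tries) on collision
with any observed hyperedge.  The softplus ranking loss is evaluated per
mini-batch (default 64 positives plus their negatives); in the default
`mean` mode the inner term averages the batch negatives, the `paired`
mode subtracts each positive's own matched negative — both readings of
the objective are implemented because the formulation is ambiguous
between them, and they behave nearly identically in practice.
Optimization is Adam (lr 0.001).  Hyperedges are split 70/10/20 into
train/validation/test; validation negatives are sampled once and frozen
so epoch-to-epoch AUC is comparable, and the checkpoint with the best
validation AUC is restored at the end (patience 20 epochs).  Parameters
are initialized Glorot-uniform from a seeded generator; given a seed,
training is bitwise reproducible.

Gradients come from a compact reverse-mode autodiff engine written for
this package (`hyplink.autodiff`): dense matrix products, elementwise
nonlinearities, row gathers and segment reductions — exactly the
operator set the model needs.  Its correctness is pinned by central
finite-difference tests at both the operator level and the full-loss
level (10 random parameter entries, 1e−4 relative tolerance).

## Evaluation

AUC uses the tie-aware pairwise definition (ties count ½), computed
exactly via rank statistics.  R@k takes `k = ⌈L/2⌉` for `L` missing
hyperedges — "half of the missing" rounded up for odd `L` — over a
candidate pool of the test positives plus an equal number of sampled
negatives (the pool composition is configurable through `neg_ratio`);
ties are broken by stable candidate order.  Reported metrics average
over `n_runs` independent negative resamplings.  A mean-pairwise-
similarity baseline scorer is included for embedding-only baselines:
`σ((1/|e|) Σ_{i<j} x_iᵀx_j)` — note the division by `|e|`, not by the
pair count, which is kept as defined even though it mixes scales across
hyperedge sizes.

## Synthetic benchmark

The generator plants learnable hyperlink structure emulating
coauthorship-style data: `m = 300` nodes in `C = 5` equal communities;
`n = 400` hyperedges with sizes uniform on 2–5 (small collaboration
groups), drawn within a random community with probability
`p_intra = 0.9` and uniformly otherwise (noise); `d = 120` attributes of
which 15 per community are enriched (on with probability 0.95 for
members, 0.05 otherwise) and the rest fire at the 5% noise rate.  Every
node is guaranteed ≥1 nonzero attribute and every column ≥1 nonzero
entry.  These sizes train in about ten seconds per seed on one CPU while
leaving headroom between the null (AUC 0.5) and the ceiling set by the
10% noise hyperedges.  What passing tests on this benchmark show is that
the pipeline recovers planted community signal well above chance; they
do not show real-data performance — real bag-of-words features are far
higher-dimensional and nearly orthogonal per node, and real hyperedges
are heterogeneous in ways the planted model is not.

## Numerical and design notes

* Softplus is evaluated in the overflow-safe form
  `max(x,0) + log1p(exp(−|x|))`; softmaxes subtract per-segment maxima.
* The negative sampler's 100-try resample cap turns pathological
  universes (nearly all candidate sets observed) into a clear error.
* Ties in ranked candidate lists are resolved by stable original order,
  making R@k deterministic.
* Ablation variants are first-class configuration flags: drop either
  encoder channel, or replace either attention with uniform weights.

## Known limitations

* **Member attention is a global popularity score.**  The hyperedge-
  level attention weight of node *i* depends only on `z_i`, so within
  any candidate set the softmax ranks members by one global scalar.  A
  fabricated set containing one high-scoring member can pool to nearly
  the same embedding as a true hyperedge, which caps discrimination
  against half-overlap negatives; on the synthetic benchmark (where true
  hyperedges have homogeneous members) the uniform-pooling variant
  consistently outperforms learned member attention for exactly this
  reason, and the full model is not expected to dominate every ablation
  there.  Heterogeneous real data is the regime where member attention
  can pay off.
* **No tiny-sample memorization.**  Both encoders are smoothing
  operators (neighborhood averaging; attribute-mediated averaging), and
  single-layer graph attention cannot attend to "self" specifically
  (the query term is an additive constant that the softmax cancels).
  Together with the saturating sigmoid inside the ranking loss this
  means the model does not overfit arbitrary tiny instances to
  perfection the way an unconstrained network would; training AUC on a
  12-node fixture plateaus around 0.8–0.95 depending on seed.
* Weighted, directed and temporal hyperedges are out of scope, as are
  multi-head attention and deeper attribute convolutions.
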