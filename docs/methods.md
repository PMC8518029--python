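# Methods

## Model

The encoder stacks L higher-order graph convolution (HOGC) layers. With
Â = D^(−1/2)(A + I)D^(−1/2) the symmetrically normalized adjacency with
self-loops (D counts degrees after the self-loop is added), a layer over the
power set P = {0, 1, …, k} computes

    H^(l) = ‖_{j∈P} σ( Â^j H^(l−1) W_j^(l) ),

one weight matrix per power, blocks concatenated in ascending j. Â^0 is the
identity, so the j = 0 block is a per-node feed-forward transform; P = {1}
recovers a plain GCN layer and P = {1, 2} a direct-plus-skip layer, both of
which are asserted against independent dense implementations in the tests.
Powers are applied right-to-left as j iterated sparse–dense products, so Â^j
is never materialized; the memory contract is one |V| × d·|P| dense matrix
per layer.

Node features default to one-hot identity. The first layer then reduces to a
row lookup (Â^j I W = Â^j W), which the implementation uses so the |V| × |V|
identity is never built; a test asserts the lookup equals explicit identity
features.

The decoder fuses two embeddings with a learnable bilinear tensor
W_b ∈ R^{d_e × d* × d*}, e_ij = ELU(z_iᵀ W_b z_j + b), followed by a
two-layer head with ELU and a sigmoid, giving p_ij ∈ (0, 1). W_b is
unconstrained, so p_ij ≠ p_ji in general; pairs are stored and scored in
canonical (min, max) order, and an optional symmetrization (p_ij + p_ji)/2 is
off by default.

The whole model is NumPy/SciPy with hand-written analytic gradients in
float64. The backward pass is validated against central finite differences
(relative error < 1e−4 on randomly probed parameters) in both the unit and
acceptance suites.

## Defaults and why

| parameter | default | notes |
| --- | --- | --- |
| layers L | 2 | two rounds of neighborhood mixing |
| power set P | {0,1,2,3} (k = 3) | 3-hop mixing; k configurable per run |
| per-power width d | 32 | embedding width d* = d·|P| = 128 |
| edge dim d_e | 64 | bilinear edge-representation length |
| head hidden width | 32 | the head is only stated to be two-layered; width exposed |
| activation σ | ELU | the layer nonlinearity is otherwise unspecified; matches the decoder; ReLU/tanh switchable |
| dropout | 0.1 | applied to each layer input and to e_ij before the head |
| optimizer | Adam, lr 5e−4 | conventional β = (0.9, 0.999), ε = 1e−8 |
| batch size | 256 | balanced 1:1 positive:negative batches |
| epochs / patience | 50 / 10 | early stopping on validation AUPRC, best checkpoint restored |
| loss | mean BCE | mean rather than sum decouples the learning rate from batch size |

Weights are Xavier-uniform from a seeded generator (for the 3-D bilinear
tensor the fans are the two trailing d* dimensions); biases start at zero.
One master seed derives the split, negative-sampling, initialization and
shuffle seeds, so runs are bit-for-bit reproducible.

## Splits and negative sampling

Positive edges are shuffled by a seeded permutation and partitioned
train/validation/test with floor/floor/remainder sizes (default 7:1:2).
Negatives are drawn uniformly from the non-edge complement, excluding *all*
positive edges (train, validation and test) so no held-out positive can leak
into a negative pool. One pool is drawn per run and partitioned across the
three splits, making the per-split negative sets frozen and mutually
disjoint; per-epoch resampling of training negatives is available but off by
default. For bipartite networks, negatives are restricted to cross-type
pairs by default, since same-type pairs can never be positives there and
sampling them would make the task artificially easy (a flag exposes the
unrestricted mode). The message-passing adjacency is built from the training
positives only — validation and test edges influence neither Â nor the
embeddings.

The complement is enumerated exactly when the candidate space is small
(≤ 2·10⁶ pairs) or densely requested, otherwise seeded rejection sampling is
used; both paths are deterministic given the seed. The sampled pool keeps
its random draw order — partitioning a sorted pool across splits would give
each split a topologically biased negative set.

## Evaluation

AUROC uses the Mann–Whitney tie convention (half credit). AUPRC is average
precision with step interpolation; trapezoidal interpolation of the PR curve
overestimates and is deliberately not used. The Brier score is the mean
squared error between predicted probability and binary outcome. Reliability
tables use 10 equal-width bins by default, right-closed except the first,
empty bins omitted, reporting per-bin mean prediction, positive fraction and
count.

## Synthetic benchmarks

`generate_sbm` draws a stochastic block model (default n = 300, two
equal blocks, p_in = 0.08, p_out = 0.005; mean degree ≈ 12.7). Block
co-membership is recoverable from higher-order neighborhoods, which is
exactly the structure multi-hop mixing exploits. `generate_bipartite` draws
r-dimensional latent factors per node and connects cross-type pairs with
probability sigmoid(u·v + c), with c calibrated by bisection to a target
density.

**What the SBM benchmark can and cannot show.** Conditioned on block
membership, SBM edges are independent, so the Bayes-optimal scorer for a
held-out pair is the binary within/cross-block indicator. On the default
benchmark the test positives are ≈ 94% within-block while ≈ 48% of uniformly
sampled negatives are also within-block; the oracle AUROC is therefore only
≈ 0.73–0.75, and no model can beat it systematically. The acceptance script
computes this oracle at run time next to the model's score — the trained
model sits at the ceiling (e.g. mean AUROC 0.748 vs oracle 0.748 at seed 1)
with Brier ≈ 0.19 against a calibrated-oracle bound of ≈ 0.18. A passing
run on this generator demonstrates that the model extracts all the
topological signal the generator puts in; it does not demonstrate
performance on real interaction networks, which have hubs, degree
correlations and motif structure the SBM lacks (the length-3 path heuristic,
for instance, is far stronger on real protein networks than here).

At 10% training edges the benchmark keeps only ≈ 190 edges (mean degree
≈ 1.3), so both k = 0 and k = 3 models hover near chance; the comparison
k = 3 ≥ k = 0 still holds in the mean because identity features at k = 0
carry no topology at all.

## Numerical choices and degenerate inputs

* Probabilities are clamped to [1e−7, 1 − 1e−7] inside the loss (with a
  logged warning); the gradient uses the fused sigmoid-BCE form (p − y)/n
  and needs no clamp.
* A non-finite training loss aborts with a diagnostic rather than continuing.
* Isolated nodes get Â_ii = 1 (self-loop only); zero-degree intermediates
  contribute no length-3 path, so the L3 normalizer never divides by zero.
* Self-loop rows in input files are dropped with a warning; duplicate and
  reversed duplicate rows collapse to one undirected edge; node order is
  first appearance, so adjacency matrices are byte-reproducible.
* Heuristic rankings break score ties by canonical pair order for
  deterministic top-N lists.
* Validation AUPRC for early stopping is recomputed from restored parameters
  in a test to guarantee the best checkpoint really is the one returned.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic graphs of
60–300 nodes (≈ 0.4–2k edges); oracle-equivalence checks use exhaustive
enumeration on graphs up to 15 nodes. These sizes were chosen so every
quantity can be verified against brute-force references; the implementation
itself is sparse end-to-end and the training loop's cost per step is
dominated by the bilinear decoder (O(batch · d_e · d*²)).

## Known limitations

* Binary, undirected, simple graphs only — no edge weights, no multigraphs.
* Full-graph encoding per step; no neighbor-sampled minibatching, so |V| is
  limited by the |V| × d·|P| dense embedding matrices.
* No attention-style convolution and no inner-product decoder.
* The CLI stores the training edge list in the checkpoint for adjacency
  reconstruction; checkpoints for very large graphs are correspondingly
  large.
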