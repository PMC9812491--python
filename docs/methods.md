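# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical choices that turned out to matter.

## Similarities

Drug feature similarity is the Jaccard index per feature kind (chemical
substructure, target-protein domain, gene annotation). Two empty sets get
similarity 0 (no evidence), and the diagonal is always forced to 1. The
three per-kind matrices are combined by element-wise mean by default;
`mode="per_network"` returns them separately for pipelines that embed each
similarity network on its own.

Disease similarity is the Wang-style DAG semantic similarity. Each disease
carries the ancestor closure of its term in a MeSH-like hierarchy; the
semantic contribution decays by Δ per edge along the best upward path
(Δ = 0.5 by default, the conventional value; configurable). Contributions
are computed in topological order, so any acyclic input terminates; a cycle
raises with an offending edge named. Diseases with no DAG on file keep an
identity row so matrix shapes stay aligned with the association table.

## Heterogeneous network

Similarity blocks keep their continuous weights; degrees are therefore
weighted row sums. Self-loops are added as +I after assembly, so the
diagonal of A is 2 (similarity diagonals are already 1) — accepted as the
construction defines it rather than "corrected". Drugs occupy the first
N_r rows everywhere (features, embeddings, decoder).

By default, the cross-validation driver rebuilds the network each rotation
with the held-out test positives masked out of both M_h and X0, so no label
information can leak into the encoder. A `mask_test=False` flag reproduces
the protocol in which the encoder is pre-trained once on the full network
(see *Benchmarks* below for when each protocol is informative).

## Variational graph autoencoder

Two GCN layers; the hidden layer is shared by the mean and log-variance
heads. The printed formulation of this model family applies ReLU to the
mean and log-variance layers as well; a ReLU'd log σ cannot go negative,
which pins every variance at ≥ 1, so the second layer is linear by default
and `relu_moments=True` provides the literal variant. The latent width is
d1 (the mean/log-variance heads share it); defaults d0 = 128, d1 = 64 at
database scale.

Three numerical choices were load-bearing on graphs of a few hundred nodes;
all three were found by watching training collapse and diagnosing why:

1. **Sum-form ELBO gradients.** The loss report exposes a per-entry-averaged
   reconstruction term and a per-node-averaged KL (convenient, comparable
   scales), but the optimizer uses the gradients of the plain summed ELBO.
   If the averaged mixture is optimized instead, the KL's contraction rate
   on μ (∝ 1/N) exceeds the reconstruction term's escape rate from the
   all-probabilities-0.5 saddle (∝ λ/N²), and μ = 0 becomes a stable
   attractor: the latents provably collapse. With the sum form the
   recon:KL balance is the ELBO's own, and training escapes the saddle.
2. **LSUV-style init.** X0 is sparse and small in magnitude; random Glorot
   init leaves hidden pre-activations at ~1e-2 and the ReLU layer dies
   within tens of steps. After random init, W0 is rescaled for unit-variance
   hidden pre-activations, W1 for decoder logits of order 1
   (std(μ) ≈ 1/√d1), and W2 for log-variances near zero.
3. **Deterministic warm-up.** At σ ≈ 1 the latent noise across d1 dimensions
   saturates the inner-product decoder (logit noise std ≈ √d1) before μ has
   learned anything. The first `warmup` fraction of epochs (default 0.5)
   runs with ε = 0; sampling then resumes and σ adapts.

The reconstruction target is the weighted adjacency clip(A, 0, 1) as soft
targets (`target="weighted"`). The alternative of thresholding at A > 0 is
kept as an option but is a poor default: any nonzero similarity becomes a
full edge, so a fused similarity block with a small noise floor turns into a
near-all-ones target that pulls all same-type embeddings together and erases
the block structure the decoder should learn. Class imbalance is handled by
weighting the positive part of the cross-entropy by (#zeros/#ones).

Optimization is full-graph Adam (lr 0.01, 200 epochs by default), one
reparameterized sample per step; downstream consumers receive
inference-mode embeddings (x2 = μ).

## Pair classifier

A pair (r_i, d_j) is represented as the 2×d1 stack of its two embedding
rows with a one-cell zero ring. Defaults: three conv stages with filter
counts 16:32:48, first-stage filters 2×3 (spanning both rows), later stages
1×3, max-pool 1×2 each (ceil mode, truncated final window); FC
1024→1024→512 with dropout 0.1 after the first two; two-unit softmax with
the positive-class probability as the score. All geometry is configurable —
none of it is canonical, and the smaller profiles below change it.
Mini-batch Adam (batch 128, lr 1e-3), shuffling and dropout seeded; dropout
off at inference.

Both networks are numpy with hand-written backward passes (im2col
convolution, argmax-routed pooling, inverted dropout), each verified against
central finite differences at 1e-4 relative error. One caveat the gradient
checks surfaced: with zero-initialized biases and a zero-padded input, some
pre-activations sit *exactly* on the ReLU kink, where the derivative is
undefined and finite differences disagree with any chosen subgradient; the
checks therefore perturb biases off zero first.

## Evaluation protocol

Negatives are sampled once per experiment, uniformly without replacement
from unobserved cells, 1:1 with positives. Five-fold splits are seeded
shuffles with round-robin assignment; each rotation's test fold is scored by
a model trained only on the other four (fixed hyperparameters, no inner
tuning). Thresholded metrics use 0.5 (no canonical threshold exists for
this task); AUC is the Mann–Whitney rank form with ties counted 0.5; AUPR is
step-wise integration over tie-grouped thresholds. Averaging across
rotations is unweighted (fold sizes differ by at most one). Single-class
test folds yield NaN AUC/AUPR with a warning rather than a fabricated value.

## Synthetic generator

The generator emulates the three input families with one planted latent
clustering: drugs and diseases are assigned round-robin to `n_clusters`
groups; associations are Bernoulli(p_in) for matched drug/disease clusters
and Bernoulli(p_out) otherwise; same-cluster diseases hang off a shared
ancestor ladder (so DAG similarity is high within clusters and zero across);
and each drug carries most of a per-kind cluster signature plus noise
features. With ≥ 3 clusters, each feature kind shares one adjacent cluster
pair's signature (`kind_confusion`): no single kind resolves every cluster,
but the three kinds jointly do, so dropping kinds removes genuinely
complementary information instead of redundant copies — the property a
feature-ablation experiment needs to be measurable at all.

Defaults: 100 drugs, 80 diseases, 4 clusters, p_in = 0.3, p_out = 0.02
(the *easy* setting), 300-feature pools, 30-feature signatures, 80%
signature carriage, 6 noise features, DAG depth ≤ 4. The *sparse* setting
(p_in = 0.12, p_out = 0.01, overall density ≈ 3%) matches screened real
association tables more closely and is used for ablations.

What the generator does **not** emulate: real degree distributions (CTD is
heavy-tailed; the generator is exchangeable within clusters), feature-set
size heterogeneity, correlated similarity noise, and diseases that share
ancestors across clusters. Passing the synthetic benchmarks therefore
demonstrates that the machinery recovers planted multi-view cluster
structure end to end — not that any particular real-data AUC will be
matched.

## Benchmarks and their ceilings

Within a matched cluster, unobserved cells are exchangeable given the rest
of the data: no scorer can rank a masked held-out positive above a sampled
negative of the same cluster pair. On the easy setting this caps the
*masked* protocol at about AUC 0.82 and AUPR 0.785 (measured with the
cluster-posterior oracle over five seeds). Consequently:

* **Signal recovery** is benchmarked under the full-network protocol
  (`mask_test=False`, the standard pre-training protocol for this model
  family), where the pipeline reaches AUC/AUPR ≈ 0.84–0.87 on held-out
  folds — and under the masked protocol it operates close to the 0.82
  information ceiling (≈ 0.78–0.80).
* **The label-shuffled null** runs under the masked protocol and sits at
  AUC 0.47–0.53. (Under the full-network protocol the null drifts to
  ≈ 0.6 — shuffled "positives" enter the network the encoder sees, which is
  precisely the leakage signature that protocol admits.)
* **Feature ablation** runs under the masked protocol on the sparse
  setting, where generalization has to flow through the similarity blocks:
  training with all three kinds beats any single kind in 5-seed mean AUC.

The test suite and `scripts/acceptance.py` use a reduced profile sized for
these ~180-node benchmarks — encoder 64/32 for 60 epochs, classifier with 8
base filters, a 256/256/128 head and batch 128 for 25 epochs — which runs a
full 5-fold experiment in ~20 s on one CPU. Database-scale defaults remain
as stated above.

## Known limitations

* Full-graph training only; no mini-batched graph sampling (networks of up
  to a few thousand nodes fit comfortably; beyond that, an out-of-core
  encoder would be needed).
* The VGAE and CNN are trained separately, as the architecture prescribes;
  there is no joint fine-tuning.
* The latent-subspace fusion of the three drug similarities is realized as
  an element-wise mean; nothing in the construction pins down a unique
  projection, and the per-network mode is provided for the alternative
  reading.
* Negative "labels" are unobserved pairs, not verified non-associations —
  inherent to the task's data, and the reason AUPR under class rebalancing
  should be read comparatively, not absolutely.
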