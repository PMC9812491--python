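# drugrelink

Drug repositioning by link prediction on a drug–disease heterogeneous
network, with a variational graph autoencoder (VGAE) encoder and a
convolutional pair classifier.

## The problem

Finding new indications for approved drugs is far cheaper and faster than de
novo development. Computationally, the task is link prediction on a
bipartite drug–disease association graph, enriched with side information:
similar drugs tend to treat similar diseases. `drugrelink` implements a
complete pipeline for this task, for researchers who have

* per-drug feature sets of up to three kinds — chemical substructures
  (`che`), target-protein domains (`dom`), and gene annotations (`anno`);
* per-disease ancestor DAGs (MeSH-tree style term hierarchies);
* a table of known drug–disease associations;

all as plain delimited text. A fully seeded synthetic-data generator with
planted cluster structure is included, so the entire pipeline can be
exercised and validated without any external downloads.

## The model

**Similarities.** Drug similarity of each kind is the Jaccard index
J(A, B) = |A∩B| / |A∪B| between feature sets; the per-kind matrices are
fused by element-wise mean (or kept separate for per-network pipelines).
Disease similarity follows the Wang DAG-semantic construction: within a
disease's ancestor DAG, the disease itself contributes D_d(d) = 1 and every
other term s contributes D_d(s) = Δ · max over its children s′ of D_d(s′)
(default Δ = 0.5); two diseases are similar in proportion to the
contributions of shared terms,

    sim(d1, d2) = Σ_{s ∈ V1∩V2} (D_{d1}(s) + D_{d2}(s)) / (DV(d1) + DV(d2)).

**Network.** With drug similarity M_r, disease similarity M_d and the binary
association matrix M_rd, the heterogeneous adjacency and initial node
features are

    M_h = [[M_r, M_rd], [M_rdᵀ, M_d]],   A = M_h + I,
    X0  = [[0,   M_rd], [M_rdᵀ, 0  ]],

and A is symmetrically degree-normalized, Â = D^{-1/2} A D^{-1/2}.

**Encoder.** A two-layer GCN produces per-node Gaussian latents:
H = ReLU(Â X0 W0), μ = Â H W1, log σ = Â H W2, sampled via the
reparameterization trick z = μ + σ ⊙ ε. An inner-product decoder
reconstructs edge probabilities sigmoid(z_i·z_j), trained by the ELBO
(reconstruction cross-entropy + KL to N(0, I)) with Adam. Inference uses μ.

**Classifier.** Each candidate pair stacks its drug and disease embedding
rows into a 2×d matrix (zero-padded by one ring), passes three conv+max-pool
stages with filter counts n:2n:3n, then fully-connected layers
1024→1024→512 (dropout 0.1 after the first two) and a two-unit softmax; the
positive-class probability is the association score.

**Evaluation.** Negatives are sampled 1:1 from unobserved pairs; positives
and negatives are split into five folds; each rotation trains on four folds
and scores the held-out fold as an independent test set. Metrics: AUC,
AUPR, F1, accuracy, specificity, precision, recall. Everything — sampling,
folding, initialization, dropout — is driven by explicit seeds; reruns are
byte-identical.

The neural components are implemented in numpy with hand-written backward
passes and a hand-written Adam optimizer: at the few-hundred-node scale of
these networks this is fast, dependency-light, and lets the test suite
verify every gradient against finite differences.

## Worked example

```
$ drugrelink simulate --out demo/data --seed 1        # 100 drugs, 80 diseases, 4 clusters
$ cat > demo/config.yaml <<'YAML'
vgae: {d0: 64, d1: 32, epochs: 60}
cnn: {n_conv: 8, fc_sizes: [256, 256, 128], epochs: 25}
seed: 1
YAML
$ drugrelink evaluate --data demo/data --out demo/eval --config demo/config.yaml
auc=0.7978  aupr=0.7697  f1=0.7542  accuracy=0.7616  specificity=0.7848  precision=0.7743  recall=0.7385
```

Those are 5-fold means on independent test folds, with the test-fold
associations masked out of the network the encoder sees (the strict,
leakage-free protocol; see `docs/methods.md` for why its ceiling on this
generator is about 0.82). Training on all known associations and ranking
candidates for one disease:

```
$ drugrelink train --data demo/data --out demo/model --config demo/config.yaml
$ drugrelink predict --data demo/data --model demo/model --disease D0007 --top 5
R0083   0.908575
R0007   0.895310
R0087   0.884904
R0003   0.878911
R0071   0.868488
```

Disease `D0007` belongs to planted cluster 3 — and so do all five top-ranked
drugs (`demo/data/truth.tsv` records the planted assignments): the pipeline
recovers the planted structure.

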